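"""NIfTI I/O, preprocessing stand-ins, the training harness, and
interpretability export.

Preprocessing notes: bias correction and inter-sequence registration are
upstream responsibilities — sequences with mismatched grids/affines are
refused, never silently registered.  Intensity normalization is a
modal-window z-score stand-in for WhiteStripe (true WhiteStripe models the
T1 white-matter mode; here the dominant-tissue mode of *this* image is
used), and the returned parameters flag that deviation.
"""

from __future__ import annotations

import json
import platform
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from . import _nn as nn
from .metrics import ScoredPredictions, metrics_report, auc_rank
from .model import CVit3D, ModelConfig, SEQUENCE_ORDER, VolumeBatch


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    """One subject: stacked 5-channel volume + optional mask + geometry."""

    data: np.ndarray                  # [5, D, H, W]
    mask: np.ndarray | None
    affine: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def read_subject(paths: dict[str, str | Path],
                 mask_path: str | Path | None = None,
                 subject_id: str = "") -> Subject:
    """Load the five sequences (keys = sequence names, any order) and stack
    them canonically.  Grids and affines must match across files."""
    missing = set(SEQUENCE_ORDER) - set(paths)
    if missing:
        raise ValueError(f"missing sequences: {sorted(missing)}")
    imgs = {seq: nib.load(str(paths[seq])) for seq in SEQUENCE_ORDER}
    ref_seq = SEQUENCE_ORDER[0]
    ref = imgs[ref_seq]
    for seq, img in imgs.items():
        if img.shape != ref.shape:
            raise ValueError(
                f"grid mismatch: {paths[seq]} has shape {img.shape}, "
                f"expected {ref.shape} (from {paths[ref_seq]})")
        if not np.allclose(img.affine, ref.affine, atol=1e-5):
            raise ValueError(f"affine mismatch in {paths[seq]}")
    data = np.stack([np.asarray(imgs[s].dataobj, dtype=np.float32)
                     for s in SEQUENCE_ORDER])
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if mimg.shape != ref.shape:
            raise ValueError(f"grid mismatch: mask {mask_path} vs {ref.shape}")
        mask = (np.asarray(mimg.dataobj) > 0.5).astype(np.float32)
    return Subject(data=data, mask=mask, affine=ref.affine.copy(),
                   spacing=_spacing_from_affine(ref.affine),
                   subject_id=subject_id)


def write_subject(subject: Subject, out_dir: str | Path,
                  prefix: str = "") -> dict[str, Path]:
    """One NIfTI per sequence (+ mask), returning the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for i, seq in enumerate(SEQUENCE_ORDER):
        p = out_dir / f"{prefix}{seq}.nii.gz"
        nib.save(nib.Nifti1Image(subject.data[i], subject.affine), str(p))
        paths[seq] = p
    if subject.mask is not None:
        p = out_dir / f"{prefix}mask.nii.gz"
        arr = subject.mask[0] if subject.mask.ndim == 4 else subject.mask
        nib.save(nib.Nifti1Image(arr, subject.affine), str(p))
        paths["mask"] = p
    return paths


# ---------------------------------------------------------------------------
# preprocessing stand-ins
# ---------------------------------------------------------------------------

def resample_to_spacing(volume: np.ndarray, spacing: tuple[float, ...],
                        target: tuple[float, ...],
                        mode: str = "linear") -> np.ndarray:
    """Resample to ``target`` voxel spacing (mm).

    Output extent per axis is ceil(extent_mm / target_spacing); the world
    origin (centre of voxel 0) is preserved.  ``linear`` for intensities,
    ``nearest`` for masks.
    """
    volume = np.asarray(volume)
    if any(s <= 0 for s in target) or any(s <= 0 for s in spacing):
        raise ValueError("spacings must be positive")
    if min(volume.shape) == 0:
        raise ValueError("zero-extent axis")
    out_shape = tuple(int(np.ceil(e * s / t))
                      for e, s, t in zip(volume.shape, spacing, target))
    grids = np.meshgrid(*[np.arange(o) * t / s
                          for o, t, s in zip(out_shape, target, spacing)],
                        indexing="ij")
    order = {"linear": 1, "nearest": 0}[mode]
    out = ndimage.map_coordinates(volume.astype(float), np.stack(grids),
                                  order=order, mode="nearest")
    if mode == "nearest":
        out = out.astype(volume.dtype)
    return out


@dataclass
class NormalizationParams:
    mode_value: float
    window: tuple[float, float]
    mu: float
    sigma: float
    method: str = "modal-window-zscore (WhiteStripe stand-in)"


def normalize_intensity(volume: np.ndarray, window_frac: float = 0.05,
                        bins: int = 256) -> tuple[np.ndarray, NormalizationParams]:
    """Affine map v -> (v - mu_w) / sigma_w with mu_w, sigma_w computed in
    the modal-intensity window (mode +- ``window_frac`` of the full range).

    Affine-invariant: normalize(a*v + b) == normalize(v) for a > 0.
    """
    v = np.asarray(volume, dtype=float)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        raise ValueError("constant volume cannot be normalized")
    hist, edges = np.histogram(v, bins=bins, range=(vmin, vmax))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    half = window_frac * (vmax - vmin)
    lo, hi = mode - half, mode + half
    sel = v[(v >= lo) & (v <= hi)]
    mu = float(sel.mean())
    sigma = float(sel.std())
    if sigma == 0:
        warnings.warn("degenerate modal window; falling back to global stats")
        mu, sigma = float(v.mean()), float(v.std())
    return (v - mu) / sigma, NormalizationParams(mode, (lo, hi), mu, sigma)


def preprocess_batch(volumes: np.ndarray, method: str = "zscore") -> np.ndarray:
    """Bring every subject/channel to normalized intensity units.

    The network has no input normalization layers, so its contract is
    zero-centred unit-scale inputs.  ``zscore`` (default) standardizes each
    channel globally — the right conditioning for training.  ``modal``
    applies the WhiteStripe stand-in (:func:`normalize_intensity`), which
    calibrates against the dominant-tissue mode instead and can leave
    lesion intensities many window-SDs from zero.
    """
    volumes = np.asarray(volumes, dtype=np.float32)
    out = np.empty_like(volumes)
    for i in range(volumes.shape[0]):
        for c in range(volumes.shape[1]):
            v = volumes[i, c]
            if method == "zscore":
                sd = v.std()
                out[i, c] = (v - v.mean()) / sd if sd > 0 else 0.0
            elif method == "modal":
                try:
                    out[i, c], _ = normalize_intensity(v)
                except ValueError:
                    out[i, c] = 0.0
            else:
                raise ValueError(f"unknown preprocessing method {method!r}")
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def cosine_lr(epoch: int, total_epochs: int, base_lr: float = 1e-4) -> float:
    """base_lr * (1 + cos(pi * epoch / total)) / 2, annealing to 0."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError("epoch out of range")
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    base_lr: float = 1e-4
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.base_lr <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class RunLog:
    epochs: list[dict] = field(default_factory=list)
    environment: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"epochs": self.epochs, "environment": self.environment,
                           "config": self.config}, indent=2)


def train(model: CVit3D, train_batch: VolumeBatch,
          val_batch: VolumeBatch | None, config: TrainConfig
          ) -> tuple[dict[str, np.ndarray], RunLog]:
    """Adam + cosine-annealed LR + BCE-with-logits, fully seeded.

    Returns (best state dict, run log).  "Best" is highest validation AUC
    (final state when no validation set is given).  Aborts on NaN loss.
    """
    if train_batch.labels is None:
        raise ValueError("training batch must carry labels")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.base_lr)
    log = RunLog(
        environment={"python": platform.python_version(),
                     "numpy": np.__version__, "device": config.device},
        config={**asdict(config), "model": json.loads(model.config.to_json())},
    )
    n = len(train_batch)
    y = train_batch.labels.astype(np.float32).reshape(-1, 1)
    best_state = model.state_dict()
    best_auc = -np.inf
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.base_lr)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, _ = model.forward(
                VolumeBatch(train_batch.data[idx]), training=True, rng=rng)
            loss = nn.bce_with_logits(logits, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        scores = model.predict_proba(train_batch.data, config.batch_size)
        row["train_accuracy"] = float(
            ((scores >= 0.5).astype(int) == train_batch.labels).mean())
        if val_batch is not None and val_batch.labels is not None:
            vscores = model.predict_proba(val_batch.data, config.batch_size)
            row["val_auc"] = auc_rank(ScoredPredictions(vscores, val_batch.labels))
            if row["val_auc"] >= best_auc:
                best_auc = row["val_auc"]
                best_state = model.state_dict()
        else:
            best_state = model.state_dict()
        log.epochs.append(row)
    model.load_state_dict(best_state)
    return best_state, log


def evaluate(model: CVit3D, batch: VolumeBatch,
             threshold: float = 0.5, batch_size: int = 16) -> dict:
    """Metrics report (AUC, accuracy, precision, recall, F1, confusion, ROC);
    scores-only when the batch has no labels."""
    if len(batch) == 0:
        raise ValueError("cannot evaluate an empty set")
    scores = model.predict_proba(batch.data, batch_size)
    if batch.labels is None:
        return {"scores": scores.tolist()}
    rep = metrics_report(ScoredPredictions(scores, batch.labels), threshold)
    rep["scores"] = scores.tolist()
    return rep


# ---------------------------------------------------------------------------
# interpretability export
# ---------------------------------------------------------------------------

def export_interpretability(model: CVit3D, subject_data: np.ndarray,
                            out_dir: str | Path, subject_id: str = "subject",
                            affine: np.ndarray | None = None) -> dict:
    """Write the per-channel SE/gate weights (JSON) and the CLS attention of
    the final encoder layer, head-averaged, resampled to the input grid
    (NIfTI).  Returns the scalar bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = np.asarray(subject_data)
    if data.ndim == 4:
        data = data[None]
    logits, bundle = model.forward(VolumeBatch(data))
    grid = model.config.token_grid
    attn = bundle["attention"][-1]          # [B, h, T, T]
    cls_row = attn[0, :, 0, 1:].mean(axis=0)  # head-averaged CLS row
    cls_row = cls_row / cls_row.sum()
    attn_vol = cls_row.reshape(grid)
    zoom = [t / g for t, g in zip(model.config.input_shape, grid)]
    attn_full = ndimage.zoom(attn_vol, zoom, order=1)
    affine = np.eye(4) if affine is None else affine
    nii_path = out_dir / f"{subject_id}_cls_attention.nii.gz"
    nib.save(nib.Nifti1Image(attn_full.astype(np.float32), affine), str(nii_path))
    scalars = {
        "subject": subject_id,
        "probability_hg": float(1.0 / (1.0 + np.exp(-logits.data[0, 0]))),
        "se_weights": bundle["se_weights"][0].tolist(),
        "gates": bundle["gates"][0].tolist(),
        "gated_channels": bundle["gated_channels"],
        "gn_weights": [w[0].tolist() for w in bundle["gn_weights"]],
        "attention_grid": list(grid),
        "attention_nifti": nii_path.name,
    }
    (out_dir / f"{subject_id}_interpretability.json").write_text(
        json.dumps(scalars, indent=2))
    return scalars
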