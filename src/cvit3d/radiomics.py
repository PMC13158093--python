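"""Feature screening: first-order radiomics, chi-square univariate filter,
and LASSO (L1 logistic) multivariate selection with 5-fold cross-validation.

The screen mirrors the usual radiomics workflow: continuous features are
dichotomized at their median and tested against the binary grade with a 2x2
Pearson chi-square; survivors enter an L1-penalised logistic regression whose
regularisation strength is picked by cross-validated binomial deviance
(lambda.min rule); the nonzero coefficients at the optimum are the selected
signature, ranked by absolute coefficient.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

FIRST_ORDER_NAMES = (
    "mean", "variance", "skewness", "kurtosis", "energy", "entropy",
    "p10", "p90", "voxel_count", "volume_mm3",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """samples x features matrix with unique names and binary labels.

    Feature names follow ``<sequence>_<filter>_<class>_<name>`` so the
    sequence of origin can be tallied (e.g. ``ADC_original_firstorder_mean``).
    """

    X: np.ndarray
    names: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels).ravel().astype(int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.names):
            raise ValueError("names length does not match feature count")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("labels length does not match sample count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(float), list(df.columns), labels)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, m in zip(self.names, mask) if m]
        return FeatureTable(self.X[:, mask], names, self.labels)


@dataclass
class SelectionResult:
    """Chi-square screen + LASSO selection at the CV-optimal lambda."""

    chi2_mask: np.ndarray
    chi2_pvalues: np.ndarray
    feature_names: list[str]          # names entering the LASSO
    coef: np.ndarray                  # standardized-scale coefficients at lambda*
    intercept: float
    lambda_opt: float
    lambda_path: np.ndarray
    cv_deviance: np.ndarray           # mean held-out deviance per lambda
    n_nonzero_path: np.ndarray

    @property
    def selected(self) -> list[tuple[str, float]]:
        """Nonzero-coefficient features ranked by |coef| (name tie-break)."""
        items = [(n, float(c)) for n, c in zip(self.feature_names, self.coef)
                 if c != 0.0]
        return sorted(items, key=lambda t: (-abs(t[1]), t[0]))


# ---------------------------------------------------------------------------
# first-order extraction
# ---------------------------------------------------------------------------

def first_order_features(volume: np.ndarray, mask: np.ndarray,
                         voxel_volume: float = 1.0, bins: int = 32) -> dict[str, float]:
    """First-order statistics of the intensities inside a binary mask.

    Variance/skewness/kurtosis use population (n-denominator) moments;
    entropy uses a fixed ``bins``-bin histogram over the in-mask range.
    Degenerate (constant) regions report skewness/kurtosis 0 with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    vals = volume[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    mean = vals.mean()
    var = vals.var()  # population convention
    if var == 0:
        warnings.warn("constant region: skewness/kurtosis undefined, reported 0",
                      stacklevel=2)
        skew = kurt = 0.0
        entropy = 0.0
    else:
        sd = math.sqrt(var)
        skew = float(((vals - mean) ** 3).mean() / sd ** 3)
        kurt = float(((vals - mean) ** 4).mean() / sd ** 4)
        hist, _ = np.histogram(vals, bins=bins, range=(vals.min(), vals.max()))
        p = hist[hist > 0] / vals.size
        entropy = float(-(p * np.log2(p)).sum())
    return {
        "mean": float(mean),
        "variance": float(var),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((vals ** 2).sum()),
        "entropy": entropy,
        "p10": float(np.percentile(vals, 10)),
        "p90": float(np.percentile(vals, 90)),
        "voxel_count": float(vals.size),
        "volume_mm3": float(vals.size * voxel_volume),
    }


def extract_feature_table(volumes: np.ndarray, masks: np.ndarray,
                          labels: np.ndarray, sequences: tuple[str, ...],
                          voxel_volume: float = 1.0) -> FeatureTable:
    """First-order features per sequence for a stack of subjects.

    ``volumes``: [n, 5, D, H, W]; ``masks``: [n, 1, D, H, W] or [n, D, H, W].
    """
    volumes = np.asarray(volumes)
    masks = np.asarray(masks)
    if masks.ndim == volumes.ndim:
        masks = masks[:, 0]
    names = [f"{seq}_original_firstorder_{feat}"
             for seq in sequences for feat in FIRST_ORDER_NAMES]
    rows = []
    for i in range(volumes.shape[0]):
        row = []
        for c in range(volumes.shape[1]):
            feats = first_order_features(volumes[i, c], masks[i], voxel_volume)
            row.extend(feats[f] for f in FIRST_ORDER_NAMES)
        rows.append(row)
    return FeatureTable(np.array(rows), names, labels)


def sequence_of_origin(name: str) -> str:
    """Leading ``<sequence>_`` tag of a feature name."""
    return name.split("_", 1)[0]


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------

def chi2_filter(table: FeatureTable, alpha: float = 0.05,
                method: str = "median-chi2") -> tuple[np.ndarray, np.ndarray]:
    """Univariate screen of each feature against the binary label.

    ``median-chi2`` (default): dichotomize at the feature median, 2x2 Pearson
    chi-square without continuity correction.  ``anova``: one-way F-test on
    the raw values.  Constant features fail automatically (p = 1).
    Returns (pass mask, p-values).
    """
    y = table.labels.astype(bool)
    n, p = table.X.shape
    pvals = np.ones(p)
    const = table.X.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) excluded",
                      stacklevel=2)
    if method == "anova":
        for j in range(p):
            if const[j]:
                continue
            pvals[j] = stats.f_oneway(table.X[y, j], table.X[~y, j]).pvalue
    elif method == "median-chi2":
        med = np.median(table.X, axis=0)
        above = table.X > med                      # [n, p]
        a = (above & y[:, None]).sum(axis=0).astype(float)   # above, pos
        b = (above & ~y[:, None]).sum(axis=0).astype(float)  # above, neg
        c = (~above & y[:, None]).sum(axis=0).astype(float)
        d = (~above & ~y[:, None]).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = (a + b) * (c + d) * (a + c) * (b + d)
            stat = n * (a * d - b * c) ** 2 / denom
        ok = np.isfinite(stat) & ~const
        pvals[ok] = stats.chi2.sf(stat[ok], df=1)
    else:
        raise ValueError(f"unknown screen method {method!r}")
    pvals[const] = 1.0
    return pvals < alpha, pvals


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------

def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """glmnet-style objective (1/n) sum logloss + lam * ||w||_1."""
    n = len(y)
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam),
                             solver="liblinear", max_iter=2000, tol=1e-7,
                             random_state=0)  # liblinear CD order is randomized
    clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def lasso_select(table: FeatureTable, folds: int = 5, seed: int = 0,
                 n_lambda: int = 100, decades: float = 4.0,
                 chi2_mask: np.ndarray | None = None,
                 chi2_pvalues: np.ndarray | None = None) -> SelectionResult:
    """L1-penalised logistic path with K-fold CV; lambda.min rule.

    Features are standardized internally (zero mean, unit variance).  The
    grid runs from lambda_max (the smallest lambda shrinking every
    coefficient to zero) down ``decades`` decades in ``n_lambda`` log-spaced
    steps.  The CV criterion is held-out binomial deviance.
    """
    X, y = table.X, table.labels.astype(float)
    n, p = X.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"fewer samples ({n}) than folds ({folds})")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    lam_path = np.logspace(np.log10(lam_max), np.log10(lam_max) - decades,
                           n_lambda)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    fold_id[order] = np.arange(n) % folds
    cv_dev = np.zeros((folds, n_lambda))
    for f in range(folds):
        tr, te = fold_id != f, fold_id == f
        for j, lam in enumerate(lam_path):
            coef, b0 = _l1_logistic(Xs[tr], y[tr], lam)
            pte = 1.0 / (1.0 + np.exp(-(Xs[te] @ coef + b0)))
            cv_dev[f, j] = _deviance(y[te], pte)
    mean_dev = cv_dev.mean(axis=0)
    j_opt = int(np.argmin(mean_dev))
    lam_opt = float(lam_path[j_opt])
    nnz = np.zeros(n_lambda, dtype=int)
    coefs_opt = None
    for j, lam in enumerate(lam_path):
        coef, b0 = _l1_logistic(Xs, y, lam)
        nnz[j] = int(np.count_nonzero(coef))
        if j == j_opt:
            coefs_opt = (coef, b0)
    coef, b0 = coefs_opt
    if chi2_mask is None:
        chi2_mask = np.ones(p, dtype=bool)
    if chi2_pvalues is None:
        chi2_pvalues = np.zeros(p)
    return SelectionResult(
        chi2_mask=np.asarray(chi2_mask, dtype=bool),
        chi2_pvalues=np.asarray(chi2_pvalues, dtype=float),
        feature_names=list(table.names),
        coef=coef,
        intercept=b0,
        lambda_opt=lam_opt,
        lambda_path=lam_path,
        cv_deviance=mean_dev,
        n_nonzero_path=nnz,
    )


def screen_and_select(table: FeatureTable, alpha: float = 0.05,
                      folds: int = 5, seed: int = 0,
                      method: str = "median-chi2", **kwargs) -> SelectionResult:
    """Chi-square screen then LASSO on the survivors, so the selected set is
    by construction a subset of the chi-square pass set."""
    mask, pvals = chi2_filter(table, alpha=alpha, method=method)
    if not mask.any():
        raise ValueError("no feature passed the univariate screen")
    result = lasso_select(table.subset(mask), folds=folds, seed=seed, **kwargs)
    return SelectionResult(
        chi2_mask=mask,
        chi2_pvalues=pvals,
        feature_names=result.feature_names,
        coef=result.coef,
        intercept=result.intercept,
        lambda_opt=result.lambda_opt,
        lambda_path=result.lambda_path,
        cv_deviance=result.cv_deviance,
        n_nonzero_path=result.n_nonzero_path,
    )


def rank_features(result: SelectionResult, top_k: int | None = None
                  ) -> list[dict]:
    """Selected features by descending |coefficient| with per-sequence tags.

    Empty selection yields an empty list (not an error).
    """
    ranked = [{"name": n, "coef": c, "sequence": sequence_of_origin(n)}
              for n, c in result.selected]
    if top_k is not None:
        ranked = ranked[:top_k]
    return ranked


def sequence_tally(result: SelectionResult) -> dict[str, int]:
    """How many selected features originate from each MRI sequence."""
    tally: dict[str, int] = {}
    for n, _ in result.selected:
        seq = sequence_of_origin(n)
        tally[seq] = tally.get(seq, 0) + 1
    return tally
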