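"""Structural covariance networks by correlation analysis.

An SCN treats a morphometric index (gray-matter volume, cortical
thickness) measured ACROSS subjects as the "signal": two regions
covary if subjects with more tissue in one tend to have more in the
other.  This module builds the two standard SCN products:

* seed-to-brain maps -- one ROI signal correlated against every voxel
  or vertex, and
* ROI-wise matrices -- all pairwise correlations among a set of ROI
  signals, Pearson or partial (each pair controlling the remaining
  ROIs).

Nuisance covariates (typically total intracranial volume, TIV) are
removed by residualizing BOTH sides on [intercept, covariates] before
correlating; the correlation degrees of freedom drop by the covariate
count.  Parametric p-values use the exact Student-t transform
``t = r sqrt(df / (1 - r^2))``, two-tailed.  Maps are emitted
uncorrected, with optional Benjamini-Hochberg FDR as a post-hoc flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._glm import add_intercept, check_full_rank, corr_pvalues

__all__ = [
    "SCNResult",
    "residualize",
    "seed_to_brain_scn",
    "roi_scn_matrix",
    "fdr_bh",
    "StructuralCovariance",
]


@dataclass
class SCNResult:
    """Correlation estimates: per-feature vector or ROI x ROI matrix."""

    r: np.ndarray
    p: np.ndarray
    df: int
    method: str
    n_subjects: int
    covariate_names: list[str] = field(default_factory=list)
    kind: str = "seed_to_brain"  # or "roi_matrix"

    def fdr(self, alpha: float = 0.05) -> np.ndarray:
        """Benjamini-Hochberg adjusted p-values (same shape as ``p``)."""
        return fdr_bh(self.p)

    def summary(self) -> str:
        lines = [
            "Structural covariance network",
            "=" * 45,
            f"kind:            {self.kind}",
            f"method:          {self.method}",
            f"n subjects:      {self.n_subjects}",
            f"df:              {self.df}",
            f"covariates:      {', '.join(self.covariate_names) or 'none'}",
        ]
        if self.kind == "roi_matrix":
            lines.append(f"n ROIs:          {self.r.shape[0]}")
        else:
            lines += [
                f"n features:      {self.r.size}",
                f"r range:         [{np.nanmin(self.r):+.3f}, {np.nanmax(self.r):+.3f}]",
                f"p < 0.05:        {int(np.sum(self.p < 0.05))} features (uncorrected)",
            ]
        return "\n".join(lines)


def residualize(signals: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """Residuals of each column after OLS on [intercept, covariates].

    With no covariates this is plain column demeaning.  Raises on
    rank-deficient covariates or too few subjects (n must exceed the
    number of fitted parameters).
    """
    signals = np.asarray(signals, dtype=float)
    one_d = signals.ndim == 1
    if one_d:
        signals = signals[:, None]
    n = signals.shape[0]
    X = add_intercept(covariates, n)
    if n <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} subjects to residualize on {X.shape[1] - 1} covariate(s)")
    check_full_rank(X, "covariate matrix")
    beta, _, _, _ = np.linalg.lstsq(X, signals, rcond=None)
    resid = signals - X @ beta
    return resid[:, 0] if one_d else resid


def _pearson_vector(seed: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Pearson r of one centered seed against each centered target column.

    Zero-variance targets get r = 0 (flat voxels never abort a map)."""
    s = seed - seed.mean()
    T = targets - targets.mean(axis=0)
    s_ss = float(s @ s)
    if s_ss <= 0:
        raise ValueError("seed signal has zero variance")
    t_ss = np.einsum("nm,nm->m", T, T)
    flat = t_ss <= 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance target feature(s); r set to 0, p to 1")
    denom = np.sqrt(s_ss * np.where(flat, 1.0, t_ss))
    r = (s @ T) / denom
    r[flat] = 0.0
    return np.clip(r, -1.0, 1.0)


def seed_to_brain_scn(
    seed: np.ndarray,
    targets: np.ndarray,
    covariates: np.ndarray | None = None,
    method: str = "pearson",
    covariate_names: list[str] | None = None,
) -> SCNResult:
    """Correlate one seed signal against every feature column.

    ``targets`` is the subjects x features matrix (pass
    ``dataset.values``).  With nuisance covariates both seed and
    targets are residualized first and ``df = n - 2 - c``; for
    seed-to-brain maps the ``pearson`` and ``partial`` methods then
    coincide (the distinction matters for ROI-wise matrices).
    """
    if method not in ("pearson", "partial"):
        raise ValueError(f"unknown method: {method!r}")
    seed = np.asarray(seed, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    n = targets.shape[0]
    if seed.size != n:
        raise ValueError("seed length does not match the number of subjects")
    c = 0 if covariates is None else (1 if np.asarray(covariates).ndim == 1 else np.asarray(covariates).shape[1])
    df = n - 2 - c
    if df <= 0:
        raise ValueError(f"too few subjects (n={n}) for {c} covariate(s): df = {df}")
    if covariates is not None:
        seed = residualize(seed, covariates)
        targets = residualize(targets, covariates)
    r = _pearson_vector(seed, targets)
    p = corr_pvalues(r, df)  # flat targets have r = 0 hence p = 1
    return SCNResult(
        r=r, p=p, df=df, method=method, n_subjects=n,
        covariate_names=list(covariate_names or []), kind="seed_to_brain",
    )


def roi_scn_matrix(
    roi_signals: np.ndarray,
    covariates: np.ndarray | None = None,
    method: str = "pearson",
    covariate_names: list[str] | None = None,
) -> SCNResult:
    """All-pairs SCN over R ROI signals: R x R symmetric r and p.

    ``pearson`` correlates nuisance-residualized signals pairwise.
    ``partial`` additionally controls the remaining R-2 ROI signals for
    each pair, computed from the precision matrix of the residualized
    signals; this requires more subjects than ROIs (n > R + covariates),
    mirroring the rule that the participant count must exceed the ROI
    count.
    """
    if method not in ("pearson", "partial"):
        raise ValueError(f"unknown method: {method!r}")
    S = np.asarray(roi_signals, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValueError("roi_signals must be a subjects x R matrix with R >= 2")
    n, R = S.shape
    c = 0 if covariates is None else (1 if np.asarray(covariates).ndim == 1 else np.asarray(covariates).shape[1])
    if np.any(S.std(axis=0) == 0):
        raise ValueError("zero-variance ROI signal")

    S = residualize(S, covariates)
    if method == "pearson":
        df = n - 2 - c
        if df <= 0:
            raise ValueError("too few subjects for the requested covariates")
        r = np.corrcoef(S, rowvar=False)
    else:
        if n <= R + c:
            raise ValueError(
                f"partial ROI-wise SCN needs more participants than ROIs: "
                f"n = {n} <= R + covariates = {R + c}"
            )
        df = n - 2 - c - (R - 2)
        if df <= 0:
            raise ValueError("too few subjects for partial correlation at this ROI count")
        corr = np.corrcoef(S, rowvar=False)
        prec = np.linalg.inv(corr)
        d = np.sqrt(np.diag(prec))
        r = -prec / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    p = corr_pvalues(r, df)
    np.fill_diagonal(p, 0.0)
    return SCNResult(
        r=r, p=p, df=df, method=method, n_subjects=n,
        covariate_names=list(covariate_names or []), kind="roi_matrix",
    )


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, independent/PRDS)."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat)
    ranked = flat[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out.reshape(p.shape)


class StructuralCovariance:
    """SCN model: seed-to-brain map or ROI-wise matrix.

    Parameters
    ----------
    targets : array (n_subjects, n_features)
        Feature matrix (``dataset.values`` or stacked ROI signals).
    seed : array (n_subjects,), optional
        Seed ROI signal.  If omitted the model is ROI-wise over the
        target columns.
    covariates : array (n_subjects, c), optional
        Nuisance covariates (e.g. TIV) regressed out of both sides.
    method : {"pearson", "partial"}
    """

    def __init__(self, targets, seed=None, covariates=None, method="pearson", covariate_names=None):
        self.targets = np.asarray(targets, dtype=float)
        self.seed = None if seed is None else np.asarray(seed, dtype=float)
        self.covariates = covariates
        self.method = method
        self.covariate_names = list(covariate_names or [])

    @classmethod
    def from_dataset(cls, dataset, roi_spec=None, covariate_table=None, covariate_cols=(), **kw):
        """Build from a MorphDataset plus an ROI spec for the seed."""
        seed = None
        if roi_spec is not None:
            seed = dataset.extract_signal(roi_spec.resolve(dataset))
        cov = None
        names = list(covariate_cols)
        if covariate_table is not None and names:
            cov = covariate_table.align_to(dataset).columns(names)
        return cls(dataset.values, seed=seed, covariates=cov, covariate_names=names, **kw)

    def fit(self) -> SCNResult:
        if self.seed is not None:
            return seed_to_brain_scn(
                self.seed, self.targets, self.covariates, self.method, self.covariate_names
            )
        return roi_scn_matrix(self.targets, self.covariates, self.method, self.covariate_names)
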