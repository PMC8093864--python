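"""Moderation analysis of structural covariance (MOD-SCN).

Tests whether a clinical variable (age, symptom score, disease
duration) changes the strength of the seed-target covariance.  For a
seed signal X, target signal Y and clinical moderator C the model is

    Y = b0 + b1 X + b2 C + b3 (X * C) + b4.. nuisance + e

fit by ordinary least squares.  The interaction coefficient b3 carries
the moderation effect: its two-tailed Student-t test asks whether the
X-Y covariance slope shifts with the clinical variable.  X and C are
mean-centered before forming the product, which leaves b3 and its test
unchanged but makes the lower-order coefficients interpretable and
reduces collinearity.  One moderator per fit; an intercept is always
included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._glm import ols

__all__ = ["ModulationFit", "modulation_fit", "modulation_map", "modulation_matrix", "ModulationSCN"]

_B3 = 3  # column of the X*C interaction in [1, X, C, X*C, nuisance]


@dataclass
class ModulationFit:
    """OLS moderation fit; ``beta3``/``t3``/``p3`` test the interaction."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    term_names: list[str] = field(default_factory=list)

    @property
    def beta3(self) -> float:
        return float(self.params[_B3])

    @property
    def t3(self) -> float:
        return float(self.tvalues[_B3])

    @property
    def p3(self) -> float:
        return float(self.pvalues[_B3])

    def summary(self) -> str:
        lines = [
            "Moderation of structural covariance (OLS)",
            "=" * 48,
            f"df resid: {self.df_resid}",
            f"{'term':<16}{'coef':>10}{'SE':>10}{'t':>10}{'p':>12}",
        ]
        for name, b, se, t, p in zip(self.term_names, self.params, self.bse, self.tvalues, self.pvalues):
            lines.append(f"{name:<16}{b:>10.4f}{se:>10.4f}{t:>10.3f}{p:>12.4g}")
        lines.append(f"moderation (x:clinical): beta3={self.beta3:+.4f}, t={self.t3:.3f}, p={self.p3:.4g}")
        return "\n".join(lines)


def _modulation_design(x: np.ndarray, clinical: np.ndarray, nuisance: np.ndarray | None):
    x = np.asarray(x, dtype=float)
    c = np.asarray(clinical, dtype=float)
    n = x.size
    if c.size != n:
        raise ValueError("clinical variable length does not match the subjects")
    if np.ptp(c) == 0:
        raise ValueError("clinical variable is constant")
    if np.ptp(x) == 0:
        raise ValueError("seed signal is constant")
    xc = x - x.mean()
    cc = c - c.mean()
    cols = [np.ones(n), xc, cc, xc * cc]
    names = ["intercept", "x", "clinical", "x:clinical"]
    if nuisance is not None:
        N = np.asarray(nuisance, dtype=float)
        if N.ndim == 1:
            N = N[:, None]
        if N.shape[0] != n:
            raise ValueError("nuisance rows do not match the subjects")
        cols.append(N)
        names += [f"nuisance{i}" for i in range(N.shape[1])]
    return np.column_stack(cols), names


def modulation_fit(
    x: np.ndarray,
    y: np.ndarray,
    clinical: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> ModulationFit:
    """Fit the moderation GLM for one seed-target pair."""
    X, names = _modulation_design(x, clinical, nuisance)
    fit = ols(X, np.asarray(y, dtype=float))
    return ModulationFit(
        params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
        pvalues=fit.pvalues, df_resid=fit.df_resid, term_names=names,
    )


def modulation_map(
    seed: np.ndarray,
    targets: np.ndarray,
    clinical: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Independent per-feature moderation fits (vectorized over targets).

    Returns ``{"beta3": ..., "t3": ..., "p3": ..., "df_resid": int}``.
    """
    T = np.asarray(targets, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    X, _ = _modulation_design(seed, clinical, nuisance)
    fit = ols(X, T)
    return {
        "beta3": fit.params[_B3],
        "t3": fit.tvalues[_B3],
        "p3": fit.pvalues[_B3],
        "df_resid": fit.df_resid,
    }


def modulation_matrix(
    roi_signals: np.ndarray,
    clinical: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Asymmetric R x R moderation matrices: entry (i, j) is the fit with
    seed ROI_i and target ROI_j, so the upper triangle holds seed-to-target
    effects and the lower triangle target-to-seed."""
    S = np.asarray(roi_signals, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValueError("roi_signals must be subjects x R with R >= 2")
    R = S.shape[1]
    beta3 = np.zeros((R, R))
    t3 = np.zeros((R, R))
    p3 = np.ones((R, R))
    for i in range(R):
        m = modulation_map(S[:, i], S, clinical, nuisance)
        beta3[i], t3[i], p3[i] = m["beta3"], m["t3"], m["p3"]
    np.fill_diagonal(beta3, 0.0)
    np.fill_diagonal(t3, 0.0)
    np.fill_diagonal(p3, 1.0)
    return {"beta3": beta3, "t3": t3, "p3": p3}


@dataclass
class ModulationSCNResult:
    beta3: np.ndarray
    t3: np.ndarray
    p3: np.ndarray
    n_subjects: int
    clinical_name: str | None
    kind: str = "seed_to_brain"
    df_resid: int | None = None

    def summary(self) -> str:
        lines = [
            "Moderation of structural covariance",
            "=" * 45,
            f"kind:          {self.kind}",
            f"moderator:     {self.clinical_name or 'clinical'}",
            f"n subjects:    {self.n_subjects}",
        ]
        if self.kind == "seed_to_brain":
            lines += [
                f"beta3 range:   [{self.beta3.min():+.3f}, {self.beta3.max():+.3f}]",
                f"p3 < 0.05:     {int(np.sum(self.p3 < 0.05))} features (uncorrected)",
            ]
        return "\n".join(lines)


class ModulationSCN:
    """Moderation model: seed-to-brain map or asymmetric ROI matrix.

    Omit ``seed`` for ROI-wise moderation over the target columns.
    """

    def __init__(self, targets, clinical, seed=None, nuisance=None, clinical_name=None):
        self.targets = np.asarray(targets, dtype=float)
        self.clinical = np.asarray(clinical, dtype=float)
        self.seed = None if seed is None else np.asarray(seed, dtype=float)
        self.nuisance = nuisance
        self.clinical_name = clinical_name

    def fit(self) -> ModulationSCNResult:
        n = self.targets.shape[0]
        if self.seed is not None:
            m = modulation_map(self.seed, self.targets, self.clinical, self.nuisance)
            return ModulationSCNResult(
                beta3=np.atleast_1d(m["beta3"]), t3=np.atleast_1d(m["t3"]),
                p3=np.atleast_1d(m["p3"]), n_subjects=n,
                clinical_name=self.clinical_name, kind="seed_to_brain",
                df_resid=m["df_resid"],
            )
        m = modulation_matrix(self.targets, self.clinical, self.nuisance)
        return ModulationSCNResult(
            beta3=m["beta3"], t3=m["t3"], p3=m["p3"], n_subjects=n,
            clinical_name=self.clinical_name, kind="roi_matrix",
        )
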