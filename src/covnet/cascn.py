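"""Causal structural covariance networks (cross-sectional Granger causality).

Subjects are sorted by a sequential clinical variable (disease duration,
age, ...) so that the across-subject morphometric signal becomes a
pseudo-time-series; lagged regression along that order then asks whether
the seed region's past "predicts" the target region's present, i.e.
whether atrophy or growth appears to propagate from seed to target along
the clinical sequence.

Two Granger-causality formulations are provided:

* residual-based -- compare the restricted autoregression
  ``Y_n = b0 + beta Y_{n-k} + eps`` against the full model
  ``Y_n = b0 + alpha X_{n-k} + beta' Y_{n-k} + delta``; the causality
  statistic is ``F_{x->y} = ln(var_eps / var_delta)``, positive when the
  lagged seed improves prediction of the target (eps > delta).
* coefficient-based -- the lagged cross-coefficient ``alpha`` in the
  full model is the causal measure.

eps and delta enter as residual VARIANCES (mean squared residuals of
the two fits, same divisor, so the full model can never appear worse).
All regressions include an intercept.  Significance comes from an
order-permutation test: the subject order is shuffled jointly for both
signals (the null is "no sequence effect", not "no covariance"), the
statistic recomputed, and a normal distribution fitted to the permuted
null yields z and p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scn import residualize

__all__ = [
    "GCAFit",
    "PermutationP",
    "order_subjects",
    "residual_gca",
    "coefficient_gca",
    "gca_statistic",
    "gca_permutation_p",
    "cascn_map",
    "cascn_matrix",
    "CausalSCN",
    "CaSCNResult",
]


@dataclass
class GCAFit:
    """Restricted/full lagged fits for one ordered (x, y) pair."""

    alpha: float
    beta_restricted: float
    beta_full: float
    var_eps: float
    var_delta: float
    F: float
    k: int
    n_eff: int
    alpha_se: float = float("nan")

    @property
    def statistic(self) -> dict[str, float]:
        return {"residual": self.F, "coefficient": self.alpha}

    def summary(self) -> str:
        return (
            f"GCA fit (lag k={self.k}, n_eff={self.n_eff})\n"
            f"  alpha (lagged cross-coefficient): {self.alpha:+.4f} (SE {self.alpha_se:.4f})\n"
            f"  beta restricted / full:           {self.beta_restricted:+.4f} / {self.beta_full:+.4f}\n"
            f"  residual variance eps / delta:    {self.var_eps:.6g} / {self.var_delta:.6g}\n"
            f"  F = ln(eps/delta):                {self.F:.4f}"
        )


@dataclass
class PermutationP:
    """Normal-fit p from an order-permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    p_empirical: float
    n_perm: int
    rng_seed: int | None


def order_subjects(dataset, covariate_table, seq_column: str):
    """Sort subjects ascending by a sequence covariate (stable on ties).

    Returns (sorted dataset, sorted covariate table, sorted sequence
    values).  Ties keep the original input order.
    """
    cov = covariate_table.align_to(dataset)
    seq = cov.column(seq_column)
    order = np.argsort(seq, kind="stable")
    ds = dataset.subset_subjects(order)
    from .data import CovariateTable

    cov_sorted = CovariateTable(
        cov.df.iloc[order].reset_index(drop=True),
        subject_col=cov.subject_col,
        group_col=cov.group_col,
    )
    return ds, cov_sorted, seq[order]


def _check_lag(n: int, k: int) -> None:
    if k < 1:
        raise ValueError("lag k must be a positive integer")
    if k >= n / 4:
        raise ValueError(f"lag k={k} too large for {n} ordered subjects (need k < n/4)")
    if n < 2 * k + 3:
        raise ValueError(f"need at least 2k+3 = {2 * k + 3} ordered subjects, got {n}")


def _lagged(x: np.ndarray, y: np.ndarray, k: int):
    y_t = y[k:]
    y_lag = y[:-k]
    x_lag = x[:-k]
    return y_t, y_lag, x_lag


def _fit_pair(x: np.ndarray, y: np.ndarray, k: int) -> GCAFit:
    y_t, y_lag, x_lag = _lagged(x, y, k)
    n_eff = y_t.size
    Xr = np.column_stack([np.ones(n_eff), y_lag])
    Xf = np.column_stack([np.ones(n_eff), x_lag, y_lag])
    if np.ptp(y_lag) == 0:
        raise ValueError("degenerate design: constant lagged target")
    if np.ptp(x_lag) == 0:
        raise ValueError("degenerate design: constant lagged seed")
    br, _, _, _ = np.linalg.lstsq(Xr, y_t, rcond=None)
    bf, _, _, _ = np.linalg.lstsq(Xf, y_t, rcond=None)
    resid_r = y_t - Xr @ br
    resid_f = y_t - Xf @ bf
    var_eps = float(resid_r @ resid_r) / n_eff
    var_delta = float(resid_f @ resid_f) / n_eff
    if var_delta <= 0:
        F = np.inf if var_eps > 0 else 0.0
    else:
        F = float(np.log(var_eps / var_delta))
    df = n_eff - 3
    if df > 0 and var_delta > 0:
        sigma2 = float(resid_f @ resid_f) / df
        alpha_se = float(np.sqrt(sigma2 * np.linalg.pinv(Xf.T @ Xf)[1, 1]))
    else:
        alpha_se = float("nan")
    return GCAFit(
        alpha=float(bf[1]),
        beta_restricted=float(br[1]),
        beta_full=float(bf[2]),
        var_eps=var_eps,
        var_delta=var_delta,
        F=F,
        k=k,
        n_eff=n_eff,
        alpha_se=alpha_se,
    )


def residual_gca(x: np.ndarray, y: np.ndarray, k: int = 1) -> GCAFit:
    """Residual-based GCA of the ordered pair: F = ln(var_eps/var_delta)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    _check_lag(x.size, k)
    return _fit_pair(x, y, k)


def coefficient_gca(x: np.ndarray, y: np.ndarray, k: int = 1) -> GCAFit:
    """Coefficient-based GCA: the lagged cross-coefficient alpha in
    ``Y_n = b0 + alpha X_{n-k} + beta Y_{n-k} + eps`` is the causal measure."""
    return residual_gca(x, y, k)


def gca_statistic(x: np.ndarray, y: np.ndarray, k: int = 1, method: str = "residual") -> float:
    fit = residual_gca(x, y, k)
    if method == "residual":
        return fit.F
    if method == "coefficient":
        return fit.alpha
    raise ValueError(f"unknown GCA method: {method!r}")


def _batched_gca_stats(xs: np.ndarray, ys: np.ndarray, k: int, method: str) -> np.ndarray:
    """Statistic for each of P ordered (x, y) rows at once.

    xs, ys: (P, N).  Solves the batched 2- and 3-column normal
    equations, which keeps thousand-permutation nulls in milliseconds.
    """
    P, N = xs.shape
    y_t = ys[:, k:]
    y_lag = ys[:, :-k]
    x_lag = xs[:, :-k]
    n_eff = N - k
    ones = np.ones((P, n_eff))
    Xf = np.stack([ones, x_lag, y_lag], axis=2)  # (P, n, 3)
    XtX = np.einsum("pni,pnj->pij", Xf, Xf)
    Xty = np.einsum("pni,pn->pi", Xf, y_t)
    # pinv tolerates exactly collinear pairs (e.g. target == seed), matching
    # the minimum-norm lstsq solution of the per-pair path
    bf = np.einsum("pij,pj->pi", np.linalg.pinv(XtX), Xty)
    if method == "coefficient":
        return bf[:, 1]
    resid_f = y_t - np.einsum("pni,pi->pn", Xf, bf)
    ssr_f = np.einsum("pn,pn->p", resid_f, resid_f)
    Xr = Xf[:, :, [0, 2]]
    XtXr = np.einsum("pni,pnj->pij", Xr, Xr)
    Xtyr = np.einsum("pni,pn->pi", Xr, y_t)
    br = np.einsum("pij,pj->pi", np.linalg.pinv(XtXr), Xtyr)
    resid_r = y_t - np.einsum("pni,pi->pn", Xr, br)
    ssr_r = np.einsum("pn,pn->p", resid_r, resid_r)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(ssr_r, np.finfo(float).tiny) / np.maximum(ssr_f, np.finfo(float).tiny))


def gca_permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 1,
    method: str = "residual",
    n_perm: int = 1000,
    rng_seed: int | None = None,
    tails: str = "two",
) -> PermutationP:
    """Order-permutation significance of a GCA statistic.

    The subject order is shuffled jointly for x and y (preserving the
    cross-sectional pairing), the statistic recomputed ``n_perm`` times,
    and p read from the normal fit z = (obs - mean)/sd of the null.
    An empirical-rank p is also reported for diagnostics.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if method not in ("residual", "coefficient"):
        raise ValueError(f"unknown GCA method: {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_lag(x.size, k)
    obs = gca_statistic(x, y, k, method)

    rng = np.random.default_rng(rng_seed)
    N = x.size
    perms = np.argsort(rng.random((n_perm, N)), axis=1)
    null = _batched_gca_stats(x[perms], y[perms], k, method)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd <= 0:
        raise ValueError("degenerate permutation null (sd = 0)")
    z = (obs - null_mean) / null_sd
    if tails == "two":
        p = float(2.0 * stats.norm.sf(abs(z)))
        p_emp = float((np.sum(np.abs(null - null_mean) >= abs(obs - null_mean)) + 1) / (n_perm + 1))
    elif tails == "one":
        p = float(stats.norm.sf(z))
        p_emp = float((np.sum(null >= obs) + 1) / (n_perm + 1))
    else:
        raise ValueError("tails must be 'two' or 'one'")
    return PermutationP(
        observed=float(obs), null_mean=null_mean, null_sd=null_sd,
        z=float(z), p=min(p, 1.0), p_empirical=p_emp, n_perm=n_perm, rng_seed=rng_seed,
    )


def cascn_map(
    seed: np.ndarray,
    targets: np.ndarray,
    k: int = 1,
    method: str = "residual",
) -> dict[str, np.ndarray]:
    """Bidirectional seed-to-brain causal map over ordered subjects.

    Returns ``{"out": stat(X->Y), "in": stat(Y->X)}`` per target
    feature, where X is the seed; for the residual variant the
    statistic is F, for the coefficient variant alpha.
    """
    seed = np.asarray(seed, dtype=float)
    T = np.asarray(targets, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if seed.size != T.shape[0]:
        raise ValueError("seed length must match the number of ordered subjects")
    _check_lag(seed.size, k)
    if method not in ("residual", "coefficient"):
        raise ValueError(f"unknown GCA method: {method!r}")
    m = T.shape[1]
    seeds = np.broadcast_to(seed, (m, seed.size))
    ys = T.T
    out = _batched_gca_stats(seeds, ys, k, method)
    inward = _batched_gca_stats(ys, seeds, k, method)
    return {"out": out, "in": inward}


def cascn_matrix(roi_signals: np.ndarray, k: int = 1, method: str = "residual") -> np.ndarray:
    """Asymmetric R x R causal matrix: entry (i, j) = statistic for ROI_i -> ROI_j."""
    S = np.asarray(roi_signals, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValueError("roi_signals must be subjects x R with R >= 2")
    R = S.shape[1]
    M = np.zeros((R, R))
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            M[i, j] = gca_statistic(S[:, i], S[:, j], k, method)
    return M


@dataclass
class CaSCNResult:
    """Fitted causal SCN: bidirectional maps or an asymmetric matrix."""

    statistic_out: np.ndarray
    statistic_in: np.ndarray | None
    method: str
    k: int
    n_subjects: int
    seq_column: str | None = None
    kind: str = "seed_to_brain"
    p_out: np.ndarray | None = None
    p_in: np.ndarray | None = None
    n_perm: int = 0
    rng_seed: int | None = None

    def summary(self) -> str:
        stat_name = "F = ln(eps/delta)" if self.method == "residual" else "alpha"
        lines = [
            "Causal structural covariance network",
            "=" * 45,
            f"kind:            {self.kind}",
            f"GCA variant:     {self.method} ({stat_name})",
            f"lag k:           {self.k}",
            f"ordered by:      {self.seq_column or 'caller-supplied order'}",
            f"n subjects:      {self.n_subjects}",
        ]
        if self.n_perm:
            lines.append(f"permutations:    {self.n_perm} (seed {self.rng_seed})")
        if self.kind == "seed_to_brain":
            lines.append(f"out-statistic range: [{self.statistic_out.min():+.3f}, {self.statistic_out.max():+.3f}]")
        return "\n".join(lines)


class CausalSCN:
    """Causal SCN model over subjects ordered by a clinical sequence.

    Parameters
    ----------
    targets : array (n, m)
        Feature matrix already sorted by the sequence variable (use
        :func:`order_subjects`), or unsorted together with ``seq``.
    seed : array (n,), optional
        Seed signal; omit for ROI-wise (targets are ROI signals).
    seq : array (n,), optional
        Sequence values; if given, rows are stably sorted ascending.
    covariates : array, optional
        Nuisance covariates residualized out before ordering/GCA.
    """

    def __init__(self, targets, seed=None, seq=None, covariates=None,
                 method="residual", k=1, seq_column=None):
        T = np.asarray(targets, dtype=float)
        if T.ndim == 1:
            T = T[:, None]
        s = None if seed is None else np.asarray(seed, dtype=float)
        if covariates is not None:
            T = residualize(T, covariates)
            if s is not None:
                s = residualize(s, covariates)
        if seq is not None:
            order = np.argsort(np.asarray(seq, dtype=float), kind="stable")
            T = T[order]
            if s is not None:
                s = s[order]
        self.targets = T
        self.seed = s
        self.method = method
        self.k = int(k)
        self.seq_column = seq_column

    def fit(self, n_perm: int = 0, rng_seed: int | None = None) -> CaSCNResult:
        n = self.targets.shape[0]
        if self.seed is not None:
            maps = cascn_map(self.seed, self.targets, self.k, self.method)
            res = CaSCNResult(
                statistic_out=maps["out"], statistic_in=maps["in"],
                method=self.method, k=self.k, n_subjects=n,
                seq_column=self.seq_column, kind="seed_to_brain",
            )
            if n_perm:
                p_out = np.empty(self.targets.shape[1])
                p_in = np.empty(self.targets.shape[1])
                for j in range(self.targets.shape[1]):
                    seed_j = None if rng_seed is None else rng_seed + j
                    p_out[j] = gca_permutation_p(self.seed, self.targets[:, j], self.k,
                                                 self.method, n_perm, seed_j).p
                    p_in[j] = gca_permutation_p(self.targets[:, j], self.seed, self.k,
                                                self.method, n_perm, seed_j).p
                res.p_out, res.p_in, res.n_perm, res.rng_seed = p_out, p_in, n_perm, rng_seed
            return res
        M = cascn_matrix(self.targets, self.k, self.method)
        res = CaSCNResult(
            statistic_out=M, statistic_in=None, method=self.method, k=self.k,
            n_subjects=n, seq_column=self.seq_column, kind="roi_matrix",
        )
        if n_perm:
            R = M.shape[0]
            P = np.ones((R, R))
            for i in range(R):
                for j in range(R):
                    if i != j:
                        seed_ij = None if rng_seed is None else rng_seed + i * R + j
                        P[i, j] = gca_permutation_p(self.targets[:, i], self.targets[:, j],
                                                    self.k, self.method, n_perm, seed_ij).p
            res.p_out, res.n_perm, res.rng_seed = P, n_perm, rng_seed
        return res
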