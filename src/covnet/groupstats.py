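"""Two-group comparison engines for covariance connectivity.

Two procedures, each restricted to exactly two groups:

* subject-regrouping permutation test -- compute any connectivity
  index I on each group, take Delta = I_A - I_B, then repeatedly
  shuffle the group labels (preserving group sizes), recompute Delta',
  and fit a normal distribution to the permuted null; significance is
  the two-tailed normal tail of z = (Delta - mean')/sd'.  An
  empirical-rank p is carried along for diagnostics.  Works for any
  statistic (seed-target r, GCA values, winner-take-all counts).

* interaction-contrast GLMs -- for SCN, fit
  ``Y = b0 + bg G + bx X + bgx (G*X) + nuisance`` and test the
  group difference in covariance slope (bgx); for MOD-SCN, fit the
  full three-way model and test the Group x X x Clinical coefficient,
  i.e. whether the moderation effect itself differs between groups.

Plus the pooled-variance two-sample t from summary statistics used to
describe demographic balance between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from ._glm import ols

__all__ = [
    "GroupPermResult",
    "InteractionFit",
    "permutation_group_test",
    "scn_group_interaction",
    "modscn_group_interaction",
    "two_sample_t_from_summary",
    "GroupPermutationTest",
]


@dataclass
class GroupPermResult:
    """Observed group difference with its permutation-null normal fit."""

    delta_obs: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    p_empirical: np.ndarray
    n_perm: int
    rng_seed: int | None
    group_levels: tuple[str, str] | None = None

    def summary(self) -> str:
        d = np.atleast_1d(self.delta_obs)
        lines = [
            "Subject-regrouping permutation test",
            "=" * 45,
            f"groups (A - B):  {self.group_levels or '(A, B)'}",
            f"permutations:    {self.n_perm} (seed {self.rng_seed})",
            f"n statistics:    {d.size}",
        ]
        if d.size == 1:
            lines += [
                f"Delta observed:  {float(d[0]):+.4f}",
                f"null mean (sd):  {float(np.atleast_1d(self.null_mean)[0]):+.4f} "
                f"({float(np.atleast_1d(self.null_sd)[0]):.4f})",
                f"z, p (normal):   {float(np.atleast_1d(self.z)[0]):+.3f}, "
                f"{float(np.atleast_1d(self.p)[0]):.4g}",
                f"p (empirical):   {float(np.atleast_1d(self.p_empirical)[0]):.4g}",
            ]
        else:
            lines.append(f"p < 0.05:        {int(np.sum(np.atleast_1d(self.p) < 0.05))} (normal fit)")
        return "\n".join(lines)


def _split_groups(groups: Sequence) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    g = np.asarray([str(v) for v in groups])
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    idx_a = np.flatnonzero(g == levels[0])
    idx_b = np.flatnonzero(g == levels[1])
    return idx_a, idx_b, (levels[0], levels[1])


def permutation_group_test(
    statistic_fn: Callable[[np.ndarray], float | np.ndarray],
    groups: Sequence,
    n_perm: int = 1000,
    rng_seed: int | None = None,
    tails: str = "two",
) -> GroupPermResult:
    """Permutation test of Delta = I(A) - I(B) for any group index I.

    ``statistic_fn`` receives an array of subject row indices and
    returns a scalar or a per-feature vector.  Group labels are
    shuffled preserving group sizes; covariates and data stay fixed
    (the null is exchangeability of group membership).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    idx_a, idx_b, levels = _split_groups(groups)
    delta_obs = np.asarray(statistic_fn(idx_a), dtype=float) - np.asarray(statistic_fn(idx_b), dtype=float)

    rng = np.random.default_rng(rng_seed)
    pool = np.concatenate([idx_a, idx_b])
    n_a = idx_a.size
    null = np.empty((n_perm,) + delta_obs.shape)
    for i in range(n_perm):
        perm = rng.permutation(pool)
        null[i] = np.asarray(statistic_fn(perm[:n_a]), dtype=float) - np.asarray(
            statistic_fn(perm[n_a:]), dtype=float
        )
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    degenerate = null_sd <= 0
    if np.any(degenerate):
        if delta_obs.ndim == 0:
            raise ValueError("degenerate permutation null (sd = 0)")
        # per-feature statistics: flag constant components instead of aborting
        import warnings

        warnings.warn(
            f"{int(np.sum(degenerate))} statistic component(s) constant under "
            "permutation; their normal-fit z/p are NaN"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, np.nan, (delta_obs - null_mean) / np.where(degenerate, 1.0, null_sd))
    if tails == "two":
        p = 2.0 * stats.norm.sf(np.abs(z))
        p_emp = (np.sum(np.abs(null - null_mean) >= np.abs(delta_obs - null_mean), axis=0) + 1) / (n_perm + 1)
    elif tails == "one":
        p = stats.norm.sf(z)
        p_emp = (np.sum(null >= delta_obs, axis=0) + 1) / (n_perm + 1)
    else:
        raise ValueError("tails must be 'two' or 'one'")
    return GroupPermResult(
        delta_obs=delta_obs, null_mean=null_mean, null_sd=null_sd,
        z=z, p=np.minimum(p, 1.0), p_empirical=p_emp,
        n_perm=n_perm, rng_seed=rng_seed, group_levels=levels,
    )


@dataclass
class InteractionFit:
    """Interaction-contrast GLM: the contrast is the group difference."""

    params: np.ndarray
    bse: np.ndarray
    contrast: float
    t: float
    p: float
    df_resid: int
    contrast_name: str
    term_names: list[str] = field(default_factory=list)
    group_levels: tuple[str, str] | None = None

    def summary(self) -> str:
        lines = [
            "Interaction-contrast GLM (two groups)",
            "=" * 48,
            f"groups:         {self.group_levels or '(A, B)'}",
            f"df resid:       {self.df_resid}",
            f"{'term':<20}{'coef':>10}{'SE':>10}",
        ]
        for name, b, se in zip(self.term_names, self.params, self.bse):
            lines.append(f"{name:<20}{b:>10.4f}{se:>10.4f}")
        lines.append(
            f"contrast {self.contrast_name}: {self.contrast:+.4f}, t = {self.t:.3f}, p = {self.p:.4g}"
        )
        return "\n".join(lines)


def _group_indicator(groups: Sequence) -> tuple[np.ndarray, tuple[str, str]]:
    idx_a, idx_b, levels = _split_groups(groups)
    g = np.zeros(idx_a.size + idx_b.size)
    full = np.asarray([str(v) for v in groups])
    g = (full == levels[1]).astype(float)
    if idx_a.size < 3 or idx_b.size < 3:
        raise ValueError("each group needs at least 3 subjects")
    return g, levels


def scn_group_interaction(
    x: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    nuisance: np.ndarray | None = None,
) -> InteractionFit:
    """Test whether the seed-target covariance slope differs between groups.

    Fits the full-rank model ``Y = b0 + bg G + bx X + bgx (G*X) +
    nuisance`` with G an indicator of the second (lexicographically
    later) group; the contrast ``bgx`` equals slope(group B) -
    slope(group A).  Relabeling the groups flips its sign, not its
    |t| or p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g, levels = _group_indicator(groups)
    for lev, mask in ((levels[0], g == 0), (levels[1], g == 1)):
        if np.ptp(x[mask]) == 0:
            raise ValueError(f"group {lev!r} has zero seed variance")
    xc = x - x.mean()
    cols = [np.ones(x.size), g, xc, g * xc]
    names = ["intercept", "group", "x", "group:x"]
    if nuisance is not None:
        N = np.asarray(nuisance, dtype=float)
        N = N[:, None] if N.ndim == 1 else N
        cols.append(N)
        names += [f"nuisance{i}" for i in range(N.shape[1])]
    X = np.column_stack(cols)
    fit = ols(X, y)
    return InteractionFit(
        params=fit.params, bse=fit.bse, contrast=float(fit.params[3]),
        t=float(fit.tvalues[3]), p=float(fit.pvalues[3]), df_resid=fit.df_resid,
        contrast_name="group:x (slope difference)", term_names=names, group_levels=levels,
    )


def modscn_group_interaction(
    x: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    clinical: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> InteractionFit:
    """Test whether the moderation effect differs between groups.

    Full three-way model on centered X and clinical C:
    ``Y ~ G + X + C + G:X + G:C + X:C + G:X:C + nuisance``; the
    three-way coefficient is the between-group difference in the
    moderation slope.  The clinical variable must vary within each
    group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(clinical, dtype=float)
    g, levels = _group_indicator(groups)
    for lev, mask in ((levels[0], g == 0), (levels[1], g == 1)):
        if np.ptp(c[mask]) == 0:
            raise ValueError(f"clinical variable is constant within group {lev!r}")
    xc = x - x.mean()
    cc = c - c.mean()
    cols = [np.ones(x.size), g, xc, cc, g * xc, g * cc, xc * cc, g * xc * cc]
    names = ["intercept", "group", "x", "clinical", "group:x", "group:clinical",
             "x:clinical", "group:x:clinical"]
    if nuisance is not None:
        N = np.asarray(nuisance, dtype=float)
        N = N[:, None] if N.ndim == 1 else N
        cols.append(N)
        names += [f"nuisance{i}" for i in range(N.shape[1])]
    X = np.column_stack(cols)
    fit = ols(X, y)
    return InteractionFit(
        params=fit.params, bse=fit.bse, contrast=float(fit.params[7]),
        t=float(fit.tvalues[7]), p=float(fit.pvalues[7]), df_resid=fit.df_resid,
        contrast_name="group:x:clinical (moderation difference)",
        term_names=names, group_levels=levels,
    )


def two_sample_t_from_summary(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries (pooled variance by default).

    Returns (t, p, df) with a two-tailed Student reference.  The pooled
    form uses df = n1 + n2 - 2; ``welch=True`` switches to the
    Welch-Satterthwaite approximation.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2, sd2**2
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = n1 + n2 - 2
    t = (mean1 - mean2) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df)


class GroupPermutationTest:
    """Model-style wrapper over :func:`permutation_group_test`."""

    def __init__(self, statistic_fn: Callable[[np.ndarray], float | np.ndarray],
                 groups: Sequence, tails: str = "two"):
        self.statistic_fn = statistic_fn
        self.groups = groups
        self.tails = tails

    def fit(self, n_perm: int = 1000, rng_seed: int | None = None) -> GroupPermResult:
        return permutation_group_test(self.statistic_fn, self.groups, n_perm, rng_seed, self.tails)
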