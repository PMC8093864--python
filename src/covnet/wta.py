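"""Winner-take-all cortex-subcortex covariance labeling (WTA-CSSCN).

Each voxel of a subcortical structure (cerebellum, thalamus, striatum,
...) is assigned to the cortical parcel whose across-subject
morphometric signal correlates most strongly with that voxel's signal.
The resulting label map is a covariance-driven parcellation of the
subcortex, and per-parcel voxel counts ("connectivity numbers") can be
compared between two groups with the subject-regrouping permutation
test.

The interface is generalized: any "part A" parcel-signal matrix against
any "part B" voxel set is accepted (e.g. thalamic parcels against the
cerebellum).  Labeling uses the signed correlation argmax with no
significance threshold (an optional minimum-r mask is off by default);
ties go to the lowest parcel index and are logged.  Volume-based data
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import MorphDataset
from .groupstats import GroupPermResult, permutation_group_test
from .scn import residualize

__all__ = ["WTAResult", "wta_label", "wta_counts", "wta_group_compare", "WinnerTakeAll"]

logger = logging.getLogger(__name__)


@dataclass
class WTAResult:
    """Per-voxel winning parcel, winning correlation, per-parcel counts."""

    labels: np.ndarray          # winning parcel id per subcortex voxel
    rmax: np.ndarray            # the winning correlation
    parcels: np.ndarray         # ordered parcel ids
    counts: dict[int, int] = field(default_factory=dict)
    n_subjects: int = 0

    def summary(self) -> str:
        lines = [
            "Winner-take-all cortex-subcortex covariance",
            "=" * 48,
            f"n subjects:        {self.n_subjects}",
            f"subcortex voxels:  {self.labels.size}",
            f"parcels:           {list(self.parcels)}",
            "per-parcel voxel counts:",
        ]
        for pid in self.parcels:
            lines.append(f"  parcel {pid}: {self.counts.get(int(pid), 0)}")
        return "\n".join(lines)


def _as_matrix(subcortex) -> np.ndarray:
    if isinstance(subcortex, MorphDataset):
        return subcortex.values
    return np.asarray(subcortex, dtype=float)


def _standardize(M: np.ndarray, what: str, error_on_flat: bool) -> np.ndarray:
    Z = M - M.mean(axis=0)
    sd = Z.std(axis=0)
    flat = sd == 0
    if flat.any():
        if error_on_flat:
            raise ValueError(f"zero-variance {what} signal(s) at columns {np.flatnonzero(flat)[:5]}")
        sd = np.where(flat, 1.0, sd)
    return Z / sd


def wta_label(
    cortex_signals: np.ndarray,
    subcortex,
    covariates: np.ndarray | None = None,
    parcel_ids: np.ndarray | None = None,
    min_r: float | None = None,
) -> WTAResult:
    """Label every subcortex voxel by the best-correlating parcel.

    ``cortex_signals`` is subjects x P (P >= 2 parcel mean signals);
    ``subcortex`` is a MorphDataset or subjects x V matrix.  Nuisance
    covariates are residualized out of both sides first.  The winner is
    the argmax of the signed Pearson r; exact ties go to the lowest
    parcel index (logged).  ``min_r`` (off by default) relabels voxels
    whose winning r falls below the threshold as 0 / "unassigned".
    """
    C = np.asarray(cortex_signals, dtype=float)
    V = _as_matrix(subcortex)
    if C.ndim != 2 or C.shape[1] < 2:
        raise ValueError("cortex_signals must be subjects x P with P >= 2 parcels")
    if V.shape[0] != C.shape[0]:
        raise ValueError("cortex and subcortex subjects are not aligned")
    n = C.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects to correlate")
    P = C.shape[1]
    parcels = np.arange(1, P + 1) if parcel_ids is None else np.asarray(parcel_ids)
    if parcels.size != P:
        raise ValueError("parcel_ids length must match the number of parcels")

    if covariates is not None:
        C = residualize(C, covariates)
        V = residualize(V, covariates)
    Zc = _standardize(C, "parcel", error_on_flat=True)
    Zv = _standardize(V, "voxel", error_on_flat=False)
    R = (Zc.T @ Zv) / n  # P x V matrix of Pearson r

    win = np.argmax(R, axis=0)  # ties -> lowest index
    rmax = R[win, np.arange(R.shape[1])]
    ties = (R == rmax).sum(axis=0) > 1
    if ties.any():
        logger.info("WTA ties at %d voxel(s): %s", int(ties.sum()), np.flatnonzero(ties)[:10])
    labels = parcels[win]
    if min_r is not None:
        labels = np.where(rmax >= min_r, labels, 0)

    counts = {int(pid): int(np.sum(labels == pid)) for pid in parcels}
    if min_r is not None:
        counts[0] = int(np.sum(labels == 0))
    return WTAResult(labels=labels, rmax=rmax, parcels=parcels, counts=counts, n_subjects=n)


def wta_counts(result: WTAResult) -> dict[int, int]:
    """Per-parcel voxel counts (zero for unrepresented parcels)."""
    return {int(pid): int(np.sum(result.labels == pid)) for pid in result.parcels}


def wta_group_compare(
    cortex_signals: np.ndarray,
    subcortex,
    groups,
    covariates: np.ndarray | None = None,
    parcel_ids: np.ndarray | None = None,
    n_perm: int = 1000,
    rng_seed: int | None = None,
    statistic: str = "count",
) -> GroupPermResult:
    """Permutation comparison of per-parcel connectivity numbers.

    Winner-take-all labeling is recomputed on each group's subjects
    (and on every label shuffle); the per-parcel statistic is the voxel
    count difference, or the count proportion with
    ``statistic="proportion"``.
    """
    C = np.asarray(cortex_signals, dtype=float)
    V = _as_matrix(subcortex)
    P = C.shape[1]
    parcels = np.arange(1, P + 1) if parcel_ids is None else np.asarray(parcel_ids)
    if statistic not in ("count", "proportion"):
        raise ValueError("statistic must be 'count' or 'proportion'")
    scale = V.shape[1] if statistic == "proportion" else 1.0

    def counts_for(idx: np.ndarray) -> np.ndarray:
        cov = None if covariates is None else np.asarray(covariates)[idx]
        res = wta_label(C[idx], V[idx], covariates=cov, parcel_ids=parcels)
        return np.array([res.counts[int(pid)] for pid in parcels], dtype=float) / scale

    out = permutation_group_test(counts_for, groups, n_perm=n_perm, rng_seed=rng_seed)
    return out


class WinnerTakeAll:
    """WTA model over aligned cortex parcel signals and subcortex voxels."""

    def __init__(self, cortex_signals, subcortex, covariates=None, parcel_ids=None, min_r=None):
        self.cortex_signals = np.asarray(cortex_signals, dtype=float)
        self.subcortex = subcortex
        self.covariates = covariates
        self.parcel_ids = parcel_ids
        self.min_r = min_r

    def fit(self) -> WTAResult:
        return wta_label(self.cortex_signals, self.subcortex, self.covariates,
                         self.parcel_ids, self.min_r)

    def compare_groups(self, groups, n_perm: int = 1000, rng_seed: int | None = None,
                       statistic: str = "count") -> GroupPermResult:
        return wta_group_compare(self.cortex_signals, self.subcortex, groups,
                                 self.covariates, self.parcel_ids, n_perm, rng_seed, statistic)
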