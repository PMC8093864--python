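"""Synthetic morphometric fixtures with planted, known structure.

Every estimator in the package has a generator here that plants the
effect it is supposed to recover: latent-factor covariance blocks for
SCN, a lagged causal chain along a synthetic clinical sequence for
CaSCN, a clinical-moderated covariance slope for MOD-SCN, parcel-driven
voxel blocks for the winner-take-all labeling, and a two-group cohort
whose age summaries match the demo cohort's printed values exactly.

Generators are pure functions of their parameters and ``rng_seed``:
the same call is bit-identical across runs.  Volume fixtures use a
small grid (default 12x12x12 at 2 mm, ~1000 mask voxels) so whole
pipelines including thousand-permutation runs finish in minutes.
Ground truth (block memberships, planted coefficients, closed-form
correlations) is returned as a JSON-serializable dict so tests never
re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .data import CovariateTable, MorphDataset, SpaceInfo

__all__ = [
    "SynthSpec",
    "volume_space",
    "gen_covariance_dataset",
    "gen_group_covariance_signals",
    "gen_causal_pair",
    "gen_causal_dataset",
    "gen_modulation_signals",
    "gen_modulation_dataset",
    "gen_wta_signals",
    "gen_wta_dataset",
    "gen_demo_cohort",
    "save_volume_dataset",
]


@dataclass
class SynthSpec:
    """Shared fixture parameters.

    Defaults are the package's standard test-bed conditions: 60
    subjects split into two balanced groups, a 12x12x12 grid at 2 mm
    with a ~1000-voxel interior mask, moderate factor loadings against
    unit-variance noise, and a TIV nuisance channel.
    """

    n_subjects: int = 60
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 2.0
    noise_sd: float = 0.6
    loading: float = 0.8
    tiv_loading: float = 0.3
    rng_seed: int = 0
    group_labels: tuple[str, str] = ("female", "male")


def volume_space(grid_shape=(12, 12, 12), voxel_size_mm=2.0) -> SpaceInfo:
    """Small MNI-like volume space: isotropic voxels, origin at the grid
    center, mask = interior voxels (one-voxel border excluded)."""
    shape = tuple(int(s) for s in grid_shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    return SpaceInfo(kind="volume", grid_shape=shape, affine=affine,
                     mask_indices=np.flatnonzero(mask.ravel()))


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i:03d}" for i in range(n)]


def _covariate_frame(n: int, rng: np.random.Generator, labels=("female", "male"),
                     seq: np.ndarray | None = None) -> pd.DataFrame:
    half = n // 2
    group = [labels[0]] * half + [labels[1]] * (n - half)
    df = pd.DataFrame(
        {
            "subject_id": _subject_ids(n),
            "group": group,
            "age": np.round(rng.uniform(20, 46, size=n), 1),
            "tiv": np.round(rng.normal(1500.0, 120.0, size=n), 1),
        }
    )
    if seq is not None:
        df["duration"] = seq
    return df


def gen_covariance_dataset(spec: SynthSpec | None = None, n_blocks: int = 3,
                           block_size: int = 40, rng_seed: int | None = None):
    """Volume dataset with latent-factor covariance blocks.

    Each block's voxels load on one latent factor: value = 1 +
    loading*z_block + tiv_loading*z_tiv + noise.  The closed-form
    within-block correlation implied by the factor model is stored in
    the truth record.  Returns (MorphDataset, CovariateTable, truth).
    """
    spec = spec or SynthSpec()
    seed = spec.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    space = volume_space(spec.grid_shape, spec.voxel_size_mm)
    n, m = spec.n_subjects, space.n_features
    if n_blocks * block_size > m:
        raise ValueError("blocks exceed the mask size")

    cov_df = _covariate_frame(n, rng, spec.group_labels)
    tiv_z = (cov_df["tiv"].to_numpy() - cov_df["tiv"].mean()) / cov_df["tiv"].std(ddof=1)

    factors = rng.standard_normal((n, n_blocks))
    values = 1.0 + spec.noise_sd * rng.standard_normal((n, m))
    values += spec.tiv_loading * tiv_z[:, None]
    block_assign = np.full(m, -1, dtype=int)
    for b in range(n_blocks):
        cols = slice(b * block_size, (b + 1) * block_size)
        block_assign[cols] = b
        values[:, cols] += spec.loading * factors[:, b][:, None]

    signal_var = spec.loading**2 + spec.tiv_loading**2 + spec.noise_sd**2
    truth = {
        "kind": "covariance",
        "rng_seed": int(seed),
        "n_blocks": n_blocks,
        "block_size": block_size,
        "block_assign": block_assign.tolist(),
        "loading": spec.loading,
        "noise_sd": spec.noise_sd,
        "tiv_loading": spec.tiv_loading,
        "within_block_r": (spec.loading**2 + spec.tiv_loading**2) / signal_var,
        "within_block_r_tiv_removed": spec.loading**2 / (spec.loading**2 + spec.noise_sd**2),
    }
    ds = MorphDataset(values=values, subject_ids=_subject_ids(n), space=space, feature_kind="voxel")
    return ds, CovariateTable(cov_df), truth


def gen_group_covariance_signals(n_a: int = 30, n_b: int = 30, r_a: float = 0.8,
                                 r_b: float = 0.0, rng_seed: int = 0,
                                 labels=("A", "B")):
    """Seed/target signal pair whose correlation differs by group.

    Within each group, target = r*seed + sqrt(1-r^2)*noise with unit
    normals, so the population correlation is exactly r.  Returns
    (x, y, group_labels).
    """
    rng = np.random.default_rng(rng_seed)
    xs, ys, gs = [], [], []
    for n, r, lab in ((n_a, r_a, labels[0]), (n_b, r_b, labels[1])):
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y = r * x + np.sqrt(max(1.0 - r * r, 0.0)) * e
        xs.append(x)
        ys.append(y)
        gs += [lab] * n
    return np.concatenate(xs), np.concatenate(ys), np.asarray(gs)


def gen_causal_pair(n: int = 200, k: int = 1, coef: float = 0.5, ar: float = 0.8,
                    noise_sd: float = 0.1, rng_seed: int = 0):
    """Ordered (x, y) with a planted lag-k causal link x -> y.

    x is unit white noise; y_n = ar*y_{n-k} + coef*x_{n-k} +
    noise_sd*e_n along the order.  ``coef=0`` gives the null.
    """
    rng = np.random.default_rng(rng_seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = np.zeros(n)
    y[:k] = e[:k]
    for t in range(k, n):
        y[t] = ar * y[t - k] + coef * x[t - k] + noise_sd * e[t]
    return x, y


def gen_causal_dataset(spec: SynthSpec | None = None, k: int = 1, coef: float = 0.6,
                       ar: float = 0.5, block_size: int = 30,
                       signal_noise_sd: float = 0.15, rng_seed: int | None = None):
    """Volume dataset ordered by a synthetic 'duration' with a causal chain.

    Three voxel blocks: a source (seed) block, a target block whose
    latent follows the lagged source, and an independent control block.
    Subjects come pre-sorted by the strictly increasing duration.
    Returns (MorphDataset, CovariateTable, truth).
    """
    spec = spec or SynthSpec(n_subjects=120, noise_sd=0.15)
    seed = spec.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    space = volume_space(spec.grid_shape, spec.voxel_size_mm)
    n, m = spec.n_subjects, space.n_features
    if 3 * block_size > m:
        raise ValueError("blocks exceed the mask size")

    duration = np.sort(rng.uniform(0.0, 20.0, size=n))
    duration += np.arange(n) * 1e-6  # strictly increasing
    source, target = gen_causal_pair(n, k=k, coef=coef, ar=ar, noise_sd=0.1,
                                     rng_seed=int(rng.integers(2**31 - 1)))
    control = rng.standard_normal(n)

    values = 1.0 + spec.noise_sd * rng.standard_normal((n, m))
    latents = {"source": source, "target": target, "control": control}
    blocks = {}
    for b, (name, lat) in enumerate(latents.items()):
        cols = np.arange(b * block_size, (b + 1) * block_size)
        blocks[name] = cols.tolist()
        values[:, cols] += lat[:, None] + signal_noise_sd * rng.standard_normal((n, cols.size))

    cov_df = _covariate_frame(n, rng, spec.group_labels, seq=np.round(duration, 4))
    truth = {
        "kind": "causal",
        "rng_seed": int(seed),
        "k": k,
        "coef": coef,
        "ar": ar,
        "blocks": blocks,
        "seq_column": "duration",
    }
    ds = MorphDataset(values=values, subject_ids=_subject_ids(n), space=space, feature_kind="voxel")
    return ds, CovariateTable(cov_df), truth


def gen_modulation_signals(n: int = 200, b0: float = 0.2, b3: float = 0.8,
                           noise_sd: float = 0.1, rng_seed: int = 0):
    """Seed, target and clinical vectors with a planted moderation slope.

    y = x*(b0 + b3*clinical) + noise, clinical ~ U(0, 1)."""
    rng = np.random.default_rng(rng_seed)
    x = rng.standard_normal(n)
    clinical = rng.uniform(0.0, 1.0, size=n)
    y = x * (b0 + b3 * clinical) + noise_sd * rng.standard_normal(n)
    return x, y, clinical


def gen_modulation_dataset(spec: SynthSpec | None = None, b0: float = 0.2, b3: float = 0.8,
                           block_size: int = 30, signal_noise_sd: float = 0.1,
                           rng_seed: int | None = None):
    """Volume dataset with one clinically-moderated target block.

    Seed-block voxels follow the seed latent; moderated-block voxels
    follow y = x*(b0 + b3*clinical); the rest of the mask is noise.
    Returns (MorphDataset, CovariateTable with a 'clinical' column, truth).
    """
    spec = spec or SynthSpec(n_subjects=100, noise_sd=0.3)
    seed = spec.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    space = volume_space(spec.grid_shape, spec.voxel_size_mm)
    n, m = spec.n_subjects, space.n_features
    x, y, clinical = gen_modulation_signals(n, b0, b3, noise_sd=0.1,
                                            rng_seed=int(rng.integers(2**31 - 1)))
    values = 1.0 + spec.noise_sd * rng.standard_normal((n, m))
    seed_cols = np.arange(0, block_size)
    target_cols = np.arange(block_size, 2 * block_size)
    values[:, seed_cols] += x[:, None] + signal_noise_sd * rng.standard_normal((n, block_size))
    values[:, target_cols] += y[:, None] + signal_noise_sd * rng.standard_normal((n, block_size))

    cov_df = _covariate_frame(n, rng, spec.group_labels)
    cov_df["clinical"] = clinical
    truth = {
        "kind": "modulation",
        "rng_seed": int(seed),
        "b0": b0,
        "b3": b3,
        "seed_block": seed_cols.tolist(),
        "target_block": target_cols.tolist(),
        "clinical_column": "clinical",
    }
    ds = MorphDataset(values=values, subject_ids=_subject_ids(n), space=space, feature_kind="voxel")
    return ds, CovariateTable(cov_df), truth


def gen_wta_signals(n_subjects: int = 50, n_parcels: int = 5, voxels_per_block: int = 12,
                    noise_sd: float = 0.3, parcel_noise_sd: float = 0.05,
                    rewire: dict[int, int] | None = None, rng_seed: int = 0):
    """Parcel signals and subcortex voxel matrix with planted block->parcel structure.

    Block b's voxels follow parcel b's latent (plus noise); ``rewire``
    maps block index -> generating parcel index to plant group
    differences.  Returns (cortex_signals, voxel_matrix, truth) with
    truth["voxel_parcel"] the 1-based generating parcel per voxel.
    """
    rng = np.random.default_rng(rng_seed)
    latents = rng.standard_normal((n_subjects, n_parcels))
    cortex = latents + parcel_noise_sd * rng.standard_normal((n_subjects, n_parcels))
    rewire = rewire or {}
    gen_parcel = np.empty(n_parcels * voxels_per_block, dtype=int)
    V = np.empty((n_subjects, gen_parcel.size))
    for b in range(n_parcels):
        src = rewire.get(b, b)
        cols = slice(b * voxels_per_block, (b + 1) * voxels_per_block)
        gen_parcel[cols] = src + 1
        V[:, cols] = latents[:, src][:, None] + noise_sd * rng.standard_normal(
            (n_subjects, voxels_per_block)
        )
    truth = {
        "kind": "wta",
        "rng_seed": int(rng_seed),
        "n_parcels": n_parcels,
        "voxels_per_block": voxels_per_block,
        "noise_sd": noise_sd,
        "rewire": {str(k): int(v) for k, v in rewire.items()},
        "voxel_parcel": gen_parcel.tolist(),
    }
    return cortex, V, truth


def gen_wta_dataset(n_a: int = 25, n_b: int = 25, n_parcels: int = 5,
                    voxels_per_block: int = 12, noise_sd: float = 0.3,
                    rewire_a: dict[int, int] | None = None,
                    rewire_b: dict[int, int] | None = None,
                    rng_seed: int = 0, group_labels=("female", "male")):
    """Two-group WTA fixture: stacked parcel signals + subcortex voxels.

    Groups draw independent latents; per-group rewiring maps plant
    count differences.  Returns (cortex_signals, voxel_matrix, groups,
    truth)."""
    ca, va, ta = gen_wta_signals(n_a, n_parcels, voxels_per_block, noise_sd,
                                 rewire=rewire_a, rng_seed=rng_seed)
    cb, vb, tb = gen_wta_signals(n_b, n_parcels, voxels_per_block, noise_sd,
                                 rewire=rewire_b, rng_seed=rng_seed + 1)
    cortex = np.vstack([ca, cb])
    voxels = np.vstack([va, vb])
    groups = np.asarray([group_labels[0]] * n_a + [group_labels[1]] * n_b)
    truth = {
        "kind": "wta_groups",
        "rng_seed": int(rng_seed),
        "group_labels": list(group_labels),
        "truth_a": ta,
        "truth_b": tb,
    }
    return cortex, voxels, groups, truth


def gen_demo_cohort(n1: int = 28, mean1: float = 25.82, sd1: float = 6.59,
                    n2: int = 24, mean2: float = 27.5, sd2: float = 7.09,
                    rng_seed: int = 0, labels=("female", "male")) -> CovariateTable:
    """Two-group cohort whose per-group age mean and SD are matched exactly.

    Ages are drawn normal then affinely standardized so the sample
    moments (ddof=1) equal the requested summaries to machine
    precision; the pooled two-sample t on the table therefore
    reproduces the summary-statistic t.
    """
    rng = np.random.default_rng(rng_seed)
    ages, group = [], []
    for n, mean, sd, lab in ((n1, mean1, sd1, labels[0]), (n2, mean2, sd2, labels[1])):
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
        ages.append(mean + sd * z)
        group += [lab] * n
    df = pd.DataFrame(
        {
            "subject_id": _subject_ids(n1 + n2),
            "group": group,
            "age": np.concatenate(ages),
        }
    )
    return CovariateTable(df)


def save_volume_dataset(dataset: MorphDataset, outdir: str | Path,
                        prefix: str = "sub") -> dict:
    """Write one NIfTI per subject plus the mask; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    space = dataset.space
    if space.kind != "volume":
        raise ValueError("save_volume_dataset requires volume data")
    paths = []
    for i, sid in enumerate(dataset.subject_ids):
        grid = np.zeros(int(np.prod(space.grid_shape)))
        grid[space.mask_indices] = dataset.values[i]
        p = outdir / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(grid.reshape(space.grid_shape), space.affine), str(p))
        paths.append(str(p))
    mask_grid = np.zeros(int(np.prod(space.grid_shape)), dtype=np.uint8)
    mask_grid[space.mask_indices] = 1
    mask_path = outdir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(mask_grid.reshape(space.grid_shape), space.affine), str(mask_path))
    return {"images": paths, "mask": str(mask_path), "subject_ids": dataset.subject_ids}
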