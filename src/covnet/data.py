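"""Domain containers and I/O for morphometric datasets.

Everything downstream operates on a :class:`MorphDataset`: a subjects x
features matrix of a morphometric index (gray-matter volume per voxel,
cortical thickness per vertex, or ROI means) together with the spatial
metadata needed to map feature columns back onto the brain.  Volume data
live on a shared 3D grid with an affine voxel->mm map and an explicit
binary mask; surface data are per-vertex values on a FreeSurfer mesh.

Readers accept NIfTI images (via nibabel), FreeSurfer per-vertex
morphometry files (curv format and 1xV .mgh/.mgz), delimited-text
covariate tables, and four ROI definition modes: an MNI sphere, a label
image, a numeric matrix file (delimited text or simple MAT), and an
ASCII index list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SpaceInfo",
    "MorphDataset",
    "CovariateTable",
    "ROISpec",
    "load_volume_dataset",
    "load_surface_dataset",
    "resolve_roi",
    "extract_signal",
    "make_mask",
    "write_stat_map",
    "read_matrix_file",
]


@dataclass(frozen=True)
class SpaceInfo:
    """Spatial metadata tying feature columns to voxels or vertices.

    kind
        ``"volume"`` (3D grid + affine + mask), ``"surface"`` (vertex
        count + hemisphere tag) or ``"none"`` (bare ROI matrices).
    grid_shape, affine, mask_indices
        Volume only: grid dimensions, invertible 4x4 voxel->mm map, and
        strictly increasing linear (C-order) indices of in-mask voxels.
        Feature column ``j`` is the voxel ``mask_indices[j]``.
    n_vertices, hemisphere
        Surface only.
    """

    kind: str = "none"
    grid_shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None
    mask_indices: np.ndarray | None = None
    n_vertices: int | None = None
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("volume", "surface", "none"):
            raise ValueError(f"unknown space kind: {self.kind!r}")
        if self.kind == "volume":
            if self.grid_shape is None or self.affine is None or self.mask_indices is None:
                raise ValueError("volume space requires grid_shape, affine and mask_indices")
            affine = np.asarray(self.affine, dtype=float)
            if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
                raise ValueError("affine must be an invertible 4x4 matrix")
            idx = np.asarray(self.mask_indices, dtype=np.intp)
            if idx.ndim != 1 or idx.size == 0:
                raise ValueError("mask_indices must be a non-empty 1D index array")
            if np.any(np.diff(idx) <= 0):
                raise ValueError("mask_indices must be strictly increasing")
            if idx[0] < 0 or idx[-1] >= int(np.prod(self.grid_shape)):
                raise ValueError("mask_indices out of grid range")
            object.__setattr__(self, "affine", affine)
            object.__setattr__(self, "mask_indices", idx)
            object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        if self.kind == "surface" and (self.n_vertices is None or self.n_vertices <= 0):
            raise ValueError("surface space requires a positive n_vertices")

    @property
    def n_features(self) -> int:
        if self.kind == "volume":
            return int(self.mask_indices.size)
        if self.kind == "surface":
            return int(self.n_vertices)
        raise ValueError("featureless space")

    def voxel_coordinates_mm(self) -> np.ndarray:
        """World-mm coordinates of each in-mask voxel center (volume only)."""
        if self.kind != "volume":
            raise ValueError("voxel coordinates require a volume space")
        ijk = np.column_stack(np.unravel_index(self.mask_indices, self.grid_shape))
        return nib.affines.apply_affine(self.affine, ijk)


@dataclass
class MorphDataset:
    """Subjects x features morphometric value matrix with space metadata."""

    values: np.ndarray
    subject_ids: list[str]
    space: SpaceInfo = field(default_factory=SpaceInfo)
    feature_kind: str = "roi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D subjects x features matrix")
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must match the number of rows")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if self.feature_kind not in ("voxel", "vertex", "roi"):
            raise ValueError(f"unknown feature_kind: {self.feature_kind!r}")
        if self.space.kind != "none" and self.space.n_features != self.values.shape[1]:
            raise ValueError("space metadata does not match the number of feature columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def extract_signal(self, indices: Sequence[int] | np.ndarray) -> np.ndarray:
        return extract_signal(self, indices)

    def subset_subjects(self, rows: Sequence[int] | np.ndarray) -> "MorphDataset":
        rows = np.asarray(rows, dtype=np.intp)
        return MorphDataset(
            values=self.values[rows],
            subject_ids=[self.subject_ids[i] for i in rows],
            space=self.space,
            feature_kind=self.feature_kind,
        )


class CovariateTable:
    """Per-subject covariates: id, optional two-level group, real columns.

    Thin wrapper over a pandas DataFrame that guarantees one row per
    subject and supports reordering to match any MorphDataset.
    """

    def __init__(self, df: pd.DataFrame, subject_col: str = "subject_id", group_col: str | None = "group"):
        df = df.copy()
        if subject_col not in df.columns:
            raise ValueError(f"missing subject column {subject_col!r}")
        df[subject_col] = df[subject_col].astype(str)
        if df[subject_col].duplicated().any():
            raise ValueError("duplicate subject ids in covariate table")
        self.df = df
        self.subject_col = subject_col
        self.group_col = group_col if (group_col and group_col in df.columns) else None

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "CovariateTable":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df, **kwargs)

    def align_to(self, dataset: MorphDataset) -> "CovariateTable":
        """Reorder rows to the dataset's subject order; error on missing ids."""
        indexed = self.df.set_index(self.subject_col)
        missing = [s for s in dataset.subject_ids if s not in indexed.index]
        if missing:
            raise ValueError(f"covariate table is missing subjects: {missing[:5]}")
        out = indexed.loc[dataset.subject_ids].reset_index()
        return CovariateTable(out, subject_col=self.subject_col, group_col=self.group_col)

    def column(self, name: str) -> np.ndarray:
        vals = np.asarray(self.df[name], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"covariate {name!r} contains non-finite values")
        return vals

    def columns(self, names: Sequence[str]) -> np.ndarray:
        """Stack named covariates into a subjects x c design block."""
        if not names:
            return np.empty((len(self.df), 0))
        return np.column_stack([self.column(n) for n in names])

    def group_labels(self, name: str | None = None) -> np.ndarray:
        name = name or self.group_col
        if name is None:
            raise ValueError("no group column available")
        return np.asarray(self.df[name].astype(str))

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ROISpec:
    """One of four ROI definition modes, resolved against a dataset.

    ``mni_sphere``  -- center (mm, world coordinates) + radius (mm);
    ``label_image`` -- path to an integer label image + label value(s);
    ``matrix_file`` -- numeric matrix file; a 1D vector is an index list,
    a 2D matrix is interpreted as precomputed subjects x ROI signals
    (see :func:`read_matrix_file`);
    ``ascii_list``  -- explicit 0-based feature indices (inline or file).
    """

    mode: str
    center: tuple[float, float, float] | None = None
    radius: float | None = None
    path: str | None = None
    labels: tuple[int, ...] | None = None
    indices: tuple[int, ...] | None = None

    @classmethod
    def mni_sphere(cls, center: Sequence[float], radius: float) -> "ROISpec":
        if radius <= 0:
            raise ValueError("radius must be positive")
        return cls(mode="mni_sphere", center=tuple(float(c) for c in center), radius=float(radius))

    @classmethod
    def label_image(cls, path: str | Path, labels: int | Sequence[int]) -> "ROISpec":
        labs = (int(labels),) if np.isscalar(labels) else tuple(int(v) for v in labels)
        return cls(mode="label_image", path=str(path), labels=labs)

    @classmethod
    def matrix_file(cls, path: str | Path) -> "ROISpec":
        return cls(mode="matrix_file", path=str(path))

    @classmethod
    def ascii_list(cls, source: str | Path | Sequence[int]) -> "ROISpec":
        if isinstance(source, (str, Path)):
            idx = np.loadtxt(source, dtype=int, ndmin=1)
        else:
            idx = np.asarray(list(source), dtype=int)
        return cls(mode="ascii_list", indices=tuple(int(i) for i in idx))

    def resolve(self, dataset: MorphDataset) -> np.ndarray:
        return resolve_roi(self, dataset)


def _default_subject_id(path: str | Path) -> str:
    """Filename with image extensions stripped (sub-000.nii.gz -> sub-000)."""
    name = Path(str(path)).name
    for suffix in (".nii.gz", ".mgz.gz", ".nii", ".mgh", ".mgz", ".curv", ".thickness"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def _load_images(paths: Iterable[str | Path]):
    imgs = [nib.load(str(p)) for p in paths]
    if not imgs:
        raise ValueError("no input images")
    shape, affine = imgs[0].shape, imgs[0].affine
    for p, img in zip(paths, imgs):
        if img.shape != shape:
            raise ValueError(f"grid shape mismatch in {p}: {img.shape} vs {shape}")
        if not np.allclose(img.affine, affine, atol=1e-4):
            raise ValueError(f"affine mismatch in {p}")
    return imgs, shape, np.asarray(affine, dtype=float)


def load_volume_dataset(
    image_paths: Sequence[str | Path],
    mask: str | Path | nib.Nifti1Image | None = None,
    subject_ids: Sequence[str] | None = None,
    on_nonfinite: str = "error",
) -> MorphDataset:
    """Load per-subject 3D NIfTI maps into a subjects x voxels matrix.

    All images must share grid shape and affine.  If ``mask`` is None it
    is inferred as the voxels nonzero (and finite) in every subject.
    ``on_nonfinite`` is ``"error"`` (default) or ``"drop"`` (listwise
    removal of subjects with non-finite in-mask values).
    """
    imgs, shape, affine = _load_images(image_paths)
    data = np.stack([np.asarray(img.dataobj, dtype=float).ravel() for img in imgs])

    if mask is None:
        finite = np.all(np.isfinite(data), axis=0)
        mask_flat = finite & np.all(np.where(np.isfinite(data), data, 0.0) != 0, axis=0)
    else:
        mimg = mask if isinstance(mask, nib.spatialimages.SpatialImage) else nib.load(str(mask))
        if mimg.shape != shape:
            raise ValueError(f"mask grid {mimg.shape} does not match image grid {shape}")
        if not np.allclose(mimg.affine, affine, atol=1e-4):
            raise ValueError("mask affine does not match image affine")
        mask_flat = np.asarray(mimg.dataobj).ravel() != 0
    mask_indices = np.flatnonzero(mask_flat)
    if mask_indices.size == 0:
        raise ValueError("mask is empty")

    values = data[:, mask_indices]
    if subject_ids is None:
        subject_ids = [_default_subject_id(p) for p in image_paths]
    subject_ids = [str(s) for s in subject_ids]

    bad = ~np.all(np.isfinite(values), axis=1)
    if bad.any():
        if on_nonfinite == "drop":
            warnings.warn(f"dropping {int(bad.sum())} subject(s) with non-finite in-mask values")
            keep = ~bad
            values = values[keep]
            subject_ids = [s for s, k in zip(subject_ids, keep) if k]
        else:
            names = [s for s, b in zip(subject_ids, bad) if b]
            raise ValueError(f"non-finite in-mask values in subjects: {names[:5]}")

    space = SpaceInfo(kind="volume", grid_shape=shape, affine=affine, mask_indices=mask_indices)
    return MorphDataset(values=values, subject_ids=list(subject_ids), space=space, feature_kind="voxel")


def _read_surface_file(path: str | Path) -> np.ndarray:
    p = str(path)
    if p.endswith((".mgh", ".mgz")):
        arr = np.asarray(nib.load(p).dataobj, dtype=float).squeeze()
        if arr.ndim != 1:
            raise ValueError(f"{p}: expected a 1 x V per-vertex file")
        return arr
    if p.endswith((".txt", ".tsv", ".csv", ".asc")):
        return np.loadtxt(p, dtype=float, ndmin=1)
    # FreeSurfer curv-format morphometry (thickness, area, curv ...)
    return np.asarray(nib.freesurfer.read_morph_data(p), dtype=float)


def load_surface_dataset(
    morph_paths: Sequence[str | Path],
    subject_ids: Sequence[str] | None = None,
    hemisphere: str | None = None,
    on_nonfinite: str = "error",
) -> MorphDataset:
    """Load per-subject FreeSurfer per-vertex morphometry into subjects x vertices."""
    vecs = [_read_surface_file(p) for p in morph_paths]
    if not vecs:
        raise ValueError("no input surface files")
    n_vertices = vecs[0].size
    for p, v in zip(morph_paths, vecs):
        if v.size != n_vertices:
            raise ValueError(f"vertex count mismatch in {p}: {v.size} vs {n_vertices}")
    values = np.stack(vecs)
    if subject_ids is None:
        subject_ids = [_default_subject_id(p) for p in morph_paths]
    subject_ids = [str(s) for s in subject_ids]
    bad = ~np.all(np.isfinite(values), axis=1)
    if bad.any():
        if on_nonfinite == "drop":
            warnings.warn(f"dropping {int(bad.sum())} subject(s) with non-finite vertex values")
            keep = ~bad
            values = values[keep]
            subject_ids = [s for s, k in zip(subject_ids, keep) if k]
        else:
            raise ValueError("non-finite vertex values; pass on_nonfinite='drop' to remove subjects")
    space = SpaceInfo(kind="surface", n_vertices=int(n_vertices), hemisphere=hemisphere)
    return MorphDataset(values=values, subject_ids=list(subject_ids), space=space, feature_kind="vertex")


def read_matrix_file(path: str | Path) -> np.ndarray:
    """Read a numeric matrix from delimited text or a simple MAT file.

    MAT files must contain a single numeric array (the first
    non-metadata variable is taken).
    """
    p = str(path)
    if p.endswith(".mat"):
        from scipy.io import loadmat

        content = loadmat(p)
        arrays = [v for k, v in content.items() if not k.startswith("__")]
        if not arrays:
            raise ValueError(f"{p}: no numeric variable found")
        return np.asarray(arrays[0], dtype=float)
    return np.loadtxt(p, dtype=float, ndmin=1)


def resolve_roi(spec: ROISpec, dataset: MorphDataset) -> np.ndarray:
    """Resolve an ROI definition into 0-based feature-column indices.

    ``mni_sphere`` keeps every in-mask voxel whose center lies within
    ``radius`` mm (inclusive, Euclidean) of the world-space center;
    ``label_image`` keeps in-mask voxels carrying any requested label;
    ``ascii_list`` and 1D ``matrix_file`` payloads are explicit indices.
    """
    if spec.mode == "mni_sphere":
        if dataset.space.kind != "volume":
            raise ValueError("mni_sphere ROIs require a volume dataset")
        coords = dataset.space.voxel_coordinates_mm()
        dist = np.linalg.norm(coords - np.asarray(spec.center, dtype=float), axis=1)
        idx = np.flatnonzero(dist <= spec.radius)
    elif spec.mode == "label_image":
        if dataset.space.kind != "volume":
            raise ValueError("label_image ROIs require a volume dataset")
        limg = nib.load(spec.path)
        if tuple(limg.shape) != dataset.space.grid_shape:
            raise ValueError("label image grid does not match dataset grid")
        flat = np.asarray(limg.dataobj).ravel()[dataset.space.mask_indices]
        present = set(np.unique(flat).astype(int).tolist())
        absent = [v for v in spec.labels if v not in present]
        if absent:
            raise ValueError(f"label value(s) {absent} not present inside the mask")
        idx = np.flatnonzero(np.isin(flat.astype(int), spec.labels))
    elif spec.mode == "ascii_list":
        idx = np.asarray(spec.indices, dtype=np.intp)
    elif spec.mode == "matrix_file":
        arr = read_matrix_file(spec.path)
        if arr.ndim != 1:
            raise ValueError(
                "matrix_file resolves to indices only for 1D payloads; "
                "2D matrices are precomputed ROI signals (use read_matrix_file)"
            )
        idx = arr.astype(np.intp)
    else:
        raise ValueError(f"unknown ROI mode: {spec.mode!r}")

    if idx.size == 0:
        raise ValueError(f"ROI spec {spec.mode!r} resolves to an empty feature set")
    if idx.min() < 0 or idx.max() >= dataset.n_features:
        raise ValueError("ROI indices out of range for this dataset")
    return idx


def roi_signals_from_label_image(
    dataset: MorphDataset, path: str | Path, labels: Sequence[int] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Mean signal per label of a parcellation image: (subjects x R, label ids).

    With ``labels=None`` every nonzero label present inside the mask is
    used, in ascending order.
    """
    if dataset.space.kind != "volume":
        raise ValueError("label-image ROI signals require a volume dataset")
    limg = nib.load(str(path))
    if tuple(limg.shape) != dataset.space.grid_shape:
        raise ValueError("label image grid does not match dataset grid")
    flat = np.asarray(limg.dataobj).ravel()[dataset.space.mask_indices].astype(int)
    if labels is None:
        labels = [int(v) for v in np.unique(flat) if v != 0]
    if not labels:
        raise ValueError("no labels found inside the mask")
    signals = np.column_stack(
        [extract_signal(dataset, np.flatnonzero(flat == v)) for v in labels]
    )
    return signals, list(labels)


def extract_signal(dataset: MorphDataset, indices: Sequence[int] | np.ndarray) -> np.ndarray:
    """Per-subject mean of the selected feature columns (the 'ROI signal')."""
    idx = np.asarray(indices, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("empty index set")
    if idx.min() < 0 or idx.max() >= dataset.n_features:
        raise ValueError("indices out of range")
    return dataset.values[:, idx].mean(axis=1)


def make_mask(
    images: Sequence[str | Path | nib.Nifti1Image] | MorphDataset,
    rule: str = "all_nonzero",
    threshold: float | None = None,
) -> nib.Nifti1Image:
    """Build a binary analysis mask from a stack of subject images.

    ``all_nonzero`` keeps voxels nonzero in every subject; ``threshold``
    keeps voxels whose across-subject mean exceeds ``threshold``.
    """
    if isinstance(images, MorphDataset):
        if images.space.kind != "volume":
            raise ValueError("make_mask requires volume data")
        shape, affine = images.space.grid_shape, images.space.affine
        data = np.zeros((images.n_subjects, int(np.prod(shape))))
        data[:, images.space.mask_indices] = images.values
    else:
        imgs = [p if isinstance(p, nib.spatialimages.SpatialImage) else nib.load(str(p)) for p in images]
        if not imgs:
            raise ValueError("no input images")
        shape, affine = imgs[0].shape, np.asarray(imgs[0].affine, dtype=float)
        for img in imgs:
            if img.shape != shape or not np.allclose(img.affine, affine, atol=1e-4):
                raise ValueError("mask inputs must share grid and affine")
        data = np.stack([np.asarray(img.dataobj, dtype=float).ravel() for img in imgs])

    if rule == "all_nonzero":
        keep = np.all((data != 0) & np.isfinite(data), axis=0)
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold value")
        keep = np.nanmean(data, axis=0) > threshold
    else:
        raise ValueError(f"unknown mask rule: {rule!r}")
    if not keep.any():
        raise ValueError("mask is empty under the requested rule")
    return nib.Nifti1Image(keep.reshape(shape).astype(np.uint8), affine)


def write_stat_map(values: np.ndarray, space: SpaceInfo, path: str | Path) -> None:
    """Write a per-feature statistic to disk in the space's native format.

    Volume: NIfTI with values scattered onto mask voxels, zero
    elsewhere.  Surface: FreeSurfer curv (or plain text for .txt/.tsv).
    Featureless/ROI: delimited text.
    """
    values = np.asarray(values, dtype=float).ravel()
    path = str(path)
    if space.kind == "volume":
        if values.size != space.n_features:
            raise ValueError("value vector length does not match the mask size")
        grid = np.zeros(int(np.prod(space.grid_shape)))
        grid[space.mask_indices] = values
        nib.save(nib.Nifti1Image(grid.reshape(space.grid_shape), space.affine), path)
    elif space.kind == "surface":
        if values.size != space.n_features:
            raise ValueError("value vector length does not match the vertex count")
        if path.endswith((".txt", ".tsv", ".csv")):
            np.savetxt(path, values)
        else:
            nib.freesurfer.write_morph_data(path, values)
    else:
        np.savetxt(path, values, delimiter="\t")
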