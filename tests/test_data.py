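"""I/O layer: volume/surface loading, ROI resolution, masks, round-trips."""

import nibabel as nib
import numpy as np
import pytest

from covnet import data, synth
from covnet.data import (
    CovariateTable,
    MorphDataset,
    ROISpec,
    SpaceInfo,
    extract_signal,
    load_surface_dataset,
    load_volume_dataset,
    make_mask,
    resolve_roi,
    write_stat_map,
)


def _write_volumes(tmp_path, arrays, affine=None, prefix="img"):
    affine = np.eye(4) if affine is None else affine
    paths = []
    for i, a in enumerate(arrays):
        p = tmp_path / f"{prefix}{i}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(a, dtype=float), affine), str(p))
        paths.append(str(p))
    return paths


class TestVolumeLoading:
    def test_masked_matrix_is_direct_indexing(self, tmp_path, rng):
        arrays = rng.uniform(0.5, 2.0, size=(3, 4, 4, 4))
        paths = _write_volumes(tmp_path, arrays)
        mask = np.zeros((4, 4, 4))
        mask.ravel()[[1, 5, 9, 12, 20, 33, 40, 47, 55, 60]] = 1
        mpath = tmp_path / "mask.nii.gz"
        nib.save(nib.Nifti1Image(mask, np.eye(4)), str(mpath))
        ds = load_volume_dataset(paths, mask=mpath)
        assert ds.values.shape == (3, 10)
        for i in range(3):
            np.testing.assert_array_equal(ds.values[i], arrays[i].ravel()[mask.ravel() != 0])

    def test_inferred_mask_equals_all_nonzero_bruteforce(self, tmp_path, rng):
        arrays = rng.uniform(0.0, 1.0, size=(3, 5, 5, 5))
        arrays[arrays < 0.3] = 0.0
        paths = _write_volumes(tmp_path, arrays)
        ds = load_volume_dataset(paths, mask=None)
        brute = np.flatnonzero(np.all(arrays.reshape(3, -1) != 0, axis=0))
        np.testing.assert_array_equal(ds.space.mask_indices, brute)

    def test_affine_mismatch_rejected(self, tmp_path, rng):
        a = rng.uniform(1, 2, size=(4, 4, 4))
        p1 = _write_volumes(tmp_path, [a], prefix="a")[0]
        aff2 = np.diag([2.0, 2.0, 2.0, 1.0])
        p2 = _write_volumes(tmp_path, [a], affine=aff2, prefix="b")[0]
        with pytest.raises(ValueError, match="affine"):
            load_volume_dataset([p1, p2])

    def test_nonfinite_error_and_drop(self, tmp_path, rng):
        arrays = rng.uniform(1, 2, size=(3, 3, 3, 3))
        arrays[1, 0, 0, 0] = np.nan
        paths = _write_volumes(tmp_path, arrays)
        mask = np.ones((3, 3, 3))
        mpath = tmp_path / "m.nii.gz"
        nib.save(nib.Nifti1Image(mask, np.eye(4)), str(mpath))
        with pytest.raises(ValueError, match="non-finite"):
            load_volume_dataset(paths, mask=mpath)
        with pytest.warns(UserWarning, match="dropping"):
            ds = load_volume_dataset(paths, mask=mpath, on_nonfinite="drop")
        assert ds.n_subjects == 2

    def test_file_order_permutation_permutes_rows(self, tmp_path, rng):
        arrays = rng.uniform(1, 2, size=(4, 3, 3, 3))
        paths = _write_volumes(tmp_path, arrays)
        ids = [f"s{i}" for i in range(4)]
        ds = load_volume_dataset(paths, subject_ids=ids)
        perm = [2, 0, 3, 1]
        ds2 = load_volume_dataset([paths[i] for i in perm], subject_ids=[ids[i] for i in perm])
        np.testing.assert_array_equal(ds2.values, ds.values[perm])
        assert ds2.subject_ids == [ids[i] for i in perm]


class TestSurfaceLoading:
    def test_curv_roundtrip_matrix(self, tmp_path, rng):
        vals = rng.standard_normal((4, 100)).astype(np.float32)
        paths = []
        for i in range(4):
            p = tmp_path / f"s{i}.thickness"
            nib.freesurfer.write_morph_data(str(p), vals[i])
            paths.append(str(p))
        ds = load_surface_dataset(paths)
        assert ds.values.shape == (4, 100)
        assert ds.feature_kind == "vertex"
        np.testing.assert_allclose(ds.values, vals, rtol=1e-6)

    def test_single_subject_loadable(self, tmp_path, rng):
        p = tmp_path / "one.thickness"
        nib.freesurfer.write_morph_data(str(p), rng.standard_normal(100).astype(np.float32))
        ds = load_surface_dataset([p])
        assert ds.values.shape == (1, 100)

    def test_vertex_count_mismatch_rejected(self, tmp_path, rng):
        p1 = tmp_path / "a.thickness"
        p2 = tmp_path / "b.thickness"
        nib.freesurfer.write_morph_data(str(p1), rng.standard_normal(100).astype(np.float32))
        nib.freesurfer.write_morph_data(str(p2), rng.standard_normal(99).astype(np.float32))
        with pytest.raises(ValueError, match="vertex count"):
            load_surface_dataset([p1, p2])


class TestROIResolution:
    def test_sphere_single_voxel_at_center(self):
        space = synth.volume_space((12, 12, 12), 2.0)
        ds = MorphDataset(np.ones((3, space.n_features)), ["a", "b", "c"], space, "voxel")
        center = space.voxel_coordinates_mm()[50]
        idx = resolve_roi(ROISpec.mni_sphere(center, radius=1.0), ds)
        np.testing.assert_array_equal(idx, [50])

    def test_sphere_matches_bruteforce_distance_scan(self):
        # the demo seed: center (0, -53, 30), 10 mm radius, 2 mm grid
        space = SpaceInfo(
            kind="volume",
            grid_shape=(20, 20, 20),
            affine=np.array([[2, 0, 0, -20], [0, 2, 0, -72], [0, 0, 2, 12], [0, 0, 0, 1.0]]),
            mask_indices=np.arange(20**3),
        )
        ds = MorphDataset(np.ones((3, space.n_features)), list("abc"), space, "voxel")
        idx = resolve_roi(ROISpec.mni_sphere((0.0, -53.0, 30.0), 10.0), ds)
        coords = space.voxel_coordinates_mm()
        brute = np.flatnonzero(
            np.sqrt(((coords - np.array([0.0, -53.0, 30.0])) ** 2).sum(1)) <= 10.0
        )
        np.testing.assert_array_equal(idx, brute)
        assert idx.size > 1

    def test_label_image_roi_and_absent_label(self, tmp_path):
        space = synth.volume_space((8, 8, 8), 2.0)
        ds = MorphDataset(np.ones((3, space.n_features)), list("abc"), space, "voxel")
        labels = np.zeros(8**3)
        labels[space.mask_indices[:5]] = 7
        lpath = tmp_path / "labels.nii.gz"
        nib.save(nib.Nifti1Image(labels.reshape(8, 8, 8), space.affine), str(lpath))
        idx = resolve_roi(ROISpec.label_image(lpath, 7), ds)
        np.testing.assert_array_equal(idx, np.arange(5))
        with pytest.raises(ValueError, match="not present"):
            resolve_roi(ROISpec.label_image(lpath, 99), ds)

    def test_ascii_and_matrix_index_modes(self, tmp_path):
        ds = MorphDataset(np.arange(30.0).reshape(3, 10), list("abc"), feature_kind="roi")
        np.savetxt(tmp_path / "idx.txt", [1, 4, 7], fmt="%d")
        idx = resolve_roi(ROISpec.ascii_list(tmp_path / "idx.txt"), ds)
        np.testing.assert_array_equal(idx, [1, 4, 7])
        np.savetxt(tmp_path / "idx2.txt", [0, 9], fmt="%d")
        idx2 = resolve_roi(ROISpec.matrix_file(tmp_path / "idx2.txt"), ds)
        np.testing.assert_array_equal(idx2, [0, 9])
        with pytest.raises(ValueError, match="out of range"):
            resolve_roi(ROISpec.ascii_list([50]), ds)


class TestSignalsAndMasks:
    def test_extract_signal_identity_and_means(self, rng):
        ds = MorphDataset(
            np.column_stack([np.ones(5), np.full(5, 3.0), rng.standard_normal(5)]),
            [f"s{i}" for i in range(5)],
        )
        np.testing.assert_array_equal(extract_signal(ds, [2]), ds.values[:, 2])
        np.testing.assert_array_equal(extract_signal(ds, [0, 1]), np.full(5, 2.0))

    def test_extract_signal_matches_loop_oracle(self, rng):
        vals = rng.standard_normal((5, 8))
        ds = MorphDataset(vals, [f"s{i}" for i in range(5)])
        idx = [1, 4, 6]
        expected = np.array([np.mean([vals[i, j] for j in idx]) for i in range(5)])
        np.testing.assert_allclose(extract_signal(ds, idx), expected, atol=1e-14)

    def test_make_mask_all_nonzero_and_disjoint_support(self, tmp_path):
        a = np.zeros((3, 3, 3))
        a[0, :, :] = 1.0
        b = np.zeros((3, 3, 3))
        b[2, :, :] = 1.0
        pa, pb = _write_volumes(tmp_path, [a, b])
        m = make_mask([pa])
        np.testing.assert_array_equal(np.asarray(m.dataobj) != 0, a != 0)
        with pytest.raises(ValueError, match="empty"):
            make_mask([pa, pb])

    def test_make_mask_threshold_matches_bruteforce(self, tmp_path, rng):
        arrays = rng.uniform(0, 1, size=(4, 4, 4, 4))
        paths = _write_volumes(tmp_path, arrays)
        m = make_mask(paths, rule="threshold", threshold=0.4)
        brute = arrays.mean(axis=0) > 0.4
        np.testing.assert_array_equal(np.asarray(m.dataobj) != 0, brute)


class TestStatMapRoundtrip:
    def test_volume_roundtrip_identical_at_mask(self, tmp_path, rng):
        space = synth.volume_space((10, 10, 10), 2.0)
        vals = rng.standard_normal(space.n_features)
        p = tmp_path / "map.nii.gz"
        write_stat_map(vals, space, p)
        back = np.asarray(nib.load(str(p)).dataobj).ravel()[space.mask_indices]
        np.testing.assert_allclose(back, vals, atol=1e-12)
        outside = np.asarray(nib.load(str(p)).dataobj).ravel()
        outside[space.mask_indices] = 0
        assert np.all(outside == 0)

    def test_roi_text_roundtrip(self, tmp_path, rng):
        space = SpaceInfo(kind="none")
        vals = rng.standard_normal(7)
        p = tmp_path / "roi.tsv"
        write_stat_map(vals, space, p)
        np.testing.assert_allclose(np.loadtxt(p), vals, atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        space = synth.volume_space((8, 8, 8), 2.0)
        with pytest.raises(ValueError, match="length"):
            write_stat_map(np.zeros(3), space, "unused.nii.gz")


class TestCovariateTable:
    def test_alignment_tracks_subject_order(self, rng):
        import pandas as pd

        df = pd.DataFrame({"subject_id": ["a", "b", "c"], "tiv": [1.0, 2.0, 3.0]})
        table = CovariateTable(df)
        ds = MorphDataset(rng.standard_normal((3, 4)), ["c", "a", "b"])
        aligned = table.align_to(ds)
        np.testing.assert_array_equal(aligned.column("tiv"), [3.0, 1.0, 2.0])

    def test_missing_subject_rejected(self, rng):
        import pandas as pd

        table = CovariateTable(pd.DataFrame({"subject_id": ["a"], "tiv": [1.0]}))
        ds = MorphDataset(rng.standard_normal((3, 2)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="missing subjects"):
            table.align_to(ds)


def test_mat_mode_reads_simple_mat(tmp_path):
    from scipy.io import savemat

    M = np.arange(12.0).reshape(4, 3)
    savemat(tmp_path / "sig.mat", {"signals": M})
    np.testing.assert_array_equal(data.read_matrix_file(tmp_path / "sig.mat"), M)
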