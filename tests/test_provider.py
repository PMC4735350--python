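import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from grouppca import (
    BrainMask,
    DataMatrix,
    apply_mask,
    center_columns,
    common_mask,
    make_provider,
    subject_mask,
)
from grouppca.provider import load_matrix


class TestSubjectMask:
    def test_threshold_at_mean(self):
        vol = np.zeros((5, 1, 1, 1))
        vol[:, 0, 0, 0] = [1, 2, 3, 4, 10]  # mean 4
        mask = subject_mask(vol)
        assert mask.flags[:, 0, 0].tolist() == [False, False, False, True, True]

    def test_constant_volume_keeps_everything(self):
        vol = np.full((3, 3, 3, 2), 7.0)
        assert subject_mask(vol).n_voxels == 27

    def test_and_across_timepoints_brute_force(self, rng):
        vol = rng.gamma(2.0, size=(4, 5, 3, 4))
        mask = subject_mask(vol)
        expected = np.ones(vol.shape[:3], dtype=bool)
        for ti in range(vol.shape[3]):
            expected &= vol[..., ti] >= vol[..., ti].mean()
        assert np.array_equal(mask.flags, expected)

    def test_disjoint_timepoint_masks_give_empty_subject_mask(self):
        # time point 0 keeps only the first half, time point 1 only the second
        vol = np.ones((4, 1, 1, 2))
        vol[:2, 0, 0, 0] = 10.0
        vol[2:, 0, 0, 1] = 10.0
        mask = subject_mask(vol)
        assert mask.n_voxels == 0
        with pytest.raises(ValueError, match="empty common mask"):
            common_mask([mask])

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="degenerate volume"):
            subject_mask(np.zeros((2, 2, 2, 1)))

    def test_nan_rejected(self):
        vol = np.ones((2, 2, 2, 1))
        vol[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            subject_mask(vol)


class TestCommonMask:
    def test_identity_for_single_mask(self, rng):
        m = BrainMask(rng.random((3, 4, 2)) > 0.3)
        out = common_mask([m])
        assert np.array_equal(out.flags, m.flags)

    def test_shape_mismatch_rejected(self):
        a = BrainMask(np.ones((2, 2, 2), dtype=bool))
        b = BrainMask(np.ones((3, 2, 2), dtype=bool))
        with pytest.raises(ValueError, match="mismatch"):
            common_mask([a, b])

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_conjunction_matches_brute_force(self, data):
        flags = data.draw(
            st.lists(
                arrays(bool, (4, 4, 4), elements=st.booleans()), min_size=1, max_size=5
            )
        )
        masks = [BrainMask(f) for f in flags]
        expected = np.logical_and.reduce(flags)
        if not expected.any():
            with pytest.raises(ValueError, match="empty common mask"):
                common_mask(masks)
        else:
            assert np.array_equal(common_mask(masks).flags, expected)


class TestCentering:
    def test_simple_column(self):
        m = center_columns(DataMatrix(np.array([[1.0], [2.0], [3.0]])))
        assert np.allclose(m.values.ravel(), [-1, 0, 1])
        assert m.centered

    def test_idempotent(self, rng):
        m = center_columns(DataMatrix(rng.normal(size=(50, 7))))
        again = center_columns(m)
        assert np.allclose(m.values, again.values, atol=1e-12)
        assert np.all(np.abs(m.values.mean(axis=0)) < 1e-12)

    def test_rejects_nonfinite(self):
        bad = np.ones((3, 2))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            DataMatrix(bad)

    def test_rejects_single_row(self):
        with pytest.raises(ValueError, match="2 rows"):
            center_columns(DataMatrix(np.ones((1, 3))))


class TestApplyMask:
    def test_column_major_voxel_order(self):
        vol = np.arange(24, dtype=float).reshape(2, 3, 2, 2, order="F") + 1
        mask = BrainMask(np.ones((2, 3, 2), dtype=bool))
        dm = apply_mask(vol[..., :2], mask)
        # column-major linearization means the matrix equals the F-ravel
        assert np.array_equal(dm.values[:, 0], vol[..., 0].ravel(order="F"))


class TestGroupProvider:
    def test_stacked_geometry(self, rng):
        mats = [rng.normal(size=(100, 10)) for _ in range(3)]
        prov = make_provider(mats, mode="stacked")
        assert (prov.v, prov.M, prov.p, prov.total_cols) == (100, 3, 10, 30)
        assert prov.stacked_matrix().shape == (100, 30)

    def test_unstacked_counts_one_load_per_subject_per_pass(self, rng):
        mats = [rng.normal(size=(40, 5)) for _ in range(3)]
        prov = make_provider(mats, mode="unstacked")
        assert prov.dataloads == 0
        got = [Yi.copy() for _, Yi in prov.iter_subjects()]
        assert prov.dataloads == 3
        for a, b in zip(got, mats):
            assert np.array_equal(a, b)

    def test_iterating_twice_is_bit_identical(self, rng):
        mats = [rng.normal(size=(20, 4)) for _ in range(2)]
        prov = make_provider(mats, mode="unstacked")
        first = [Yi.copy() for _, Yi in prov.iter_subjects()]
        second = [Yi.copy() for _, Yi in prov.iter_subjects()]
        for a, b in zip(first, second):
            assert np.array_equal(a, b)

    def test_inconsistent_rows_rejected_with_subject_name(self, rng):
        mats = [rng.normal(size=(10, 3)), rng.normal(size=(11, 3))]
        with pytest.raises(ValueError, match="subject001"):
            make_provider(mats)

    def test_unreadable_source_names_subject(self, tmp_path):
        with pytest.raises(ValueError, match="subject000"):
            make_provider([str(tmp_path / "missing.h5")])

    def test_group_products_match_dense(self, rng):
        mats = [rng.normal(size=(30, 4)) for _ in range(3)]
        prov = make_provider(mats)
        Y = prov.stacked_matrix()
        X = rng.normal(size=(30, 5))
        F = rng.normal(size=(12, 5))
        assert np.allclose(prov.apply_cov(X), Y @ (Y.T @ X), atol=1e-10)
        assert np.allclose(prov.adjoint(X), Y.T @ X, atol=1e-12)
        assert np.allclose(prov.project(F), Y @ F, atol=1e-12)


class TestFileSources:
    def test_hdf5_and_mat_round_trip(self, tmp_path, rng):
        import h5py
        from scipy.io import savemat

        Y = rng.normal(size=(25, 6))
        h5 = tmp_path / "s.h5"
        with h5py.File(h5, "w") as f:
            f.create_dataset("Y", data=Y)
        mat = tmp_path / "s.mat"
        savemat(mat, {"Y": Y})
        assert np.allclose(load_matrix(h5), Y)
        assert np.allclose(load_matrix(mat), Y)
        prov = make_provider([str(h5), str(mat)], mode="unstacked")
        for _, Yi in prov.iter_subjects():
            assert np.allclose(Yi, Y)


class TestNifti:
    def test_nifti_masking_round_trip(self, tmp_path, rng):
        import nibabel as nib

        vol = rng.gamma(2.0, size=(4, 5, 3, 6))
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        path = tmp_path / "sub.nii.gz"
        nib.save(img, path)
        loaded = np.asarray(nib.load(path).dataobj)
        mask = subject_mask(loaded)
        dm = apply_mask(loaded, mask)
        assert dm.values.shape == (mask.n_voxels, 6)
        assert np.allclose(dm.values[0], vol[tuple(mask.coordinates()[0])])
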