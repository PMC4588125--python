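import numpy as np
import pytest

from tvconn import RoiSpec, SyntheticConfig
from tvconn.extract import (extract_first_eigenvariate, extract_mean,
                            extract_roi_series, make_sphere_mask,
                            read_motion_table, read_roi_table,
                            read_roi_timeseries, write_roi_table,
                            write_roi_timeseries)
from tvconn.synthetic import embed_in_volumes, simulate_cohort


def brute_force_sphere_count(center, radius, voxel_size):
    """Independent oracle: count lattice points of a voxel_size grid whose
    centers lie within radius of a lattice point."""
    reach = int(np.ceil(radius / voxel_size)) + 1
    count = 0
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            for k in range(-reach, reach + 1):
                d2 = (i * i + j * j + k * k) * voxel_size ** 2
                if d2 <= radius ** 2:
                    count += 1
    return count


class TestSphereMask:
    def _geometry(self, voxel_size=3.0, n=21):
        affine = np.diag([voxel_size] * 3 + [1.0])
        affine[:3, 3] = -voxel_size * (n // 2)
        return (n, n, n), affine

    def test_8mm_sphere_on_3mm_grid_is_81_voxels(self):
        shape, affine = self._geometry()
        mask = make_sphere_mask(RoiSpec("roi", 0, 0, 0, 8.0), shape, affine)
        assert mask.sum() == 81
        assert mask.sum() == brute_force_sphere_count((0, 0, 0), 8.0, 3.0)

    def test_tiny_radius_keeps_one_voxel(self):
        shape, affine = self._geometry()
        mask = make_sphere_mask(RoiSpec("roi", 0, 0, 0, 1.0), shape, affine)
        assert mask.sum() == 1

    def test_lattice_translation_invariance(self):
        shape, affine = self._geometry()
        base = make_sphere_mask(RoiSpec("roi", 0, 0, 0, 8.0), shape, affine).sum()
        for shift in [(3, 0, 0), (0, -3, 3), (6, 3, -3)]:
            moved = make_sphere_mask(RoiSpec("roi", *shift, radius=8.0),
                                     shape, affine).sum()
            assert moved == base

    def test_sphere_outside_fov_raises(self):
        shape, affine = self._geometry()
        with pytest.raises(ValueError, match="outside"):
            make_sphere_mask(RoiSpec("far", 500, 500, 500, 8.0), shape, affine)

    def test_singular_affine_rejected(self):
        shape, _ = self._geometry()
        with pytest.raises(np.linalg.LinAlgError):
            make_sphere_mask(RoiSpec("roi", 0, 0, 0, 8.0), shape, np.zeros((4, 4)))


class TestExtractMean:
    def _data(self, rng, n_vox=5, n_t=30):
        shape = (4, 4, 4)
        data = np.zeros((*shape, n_t))
        mask = np.zeros(shape, bool)
        flat = rng.choice(64, size=n_vox, replace=False)
        series = rng.standard_normal((n_vox, n_t))
        for v, f in enumerate(flat):
            idx = np.unravel_index(f, shape)
            mask[idx] = True
            data[idx] = series[v]
        return data, mask, series

    def test_identical_voxels_unchanged(self, rng):
        data, mask, series = self._data(rng, n_vox=1)
        data[mask] = series[0]
        np.testing.assert_allclose(extract_mean(data, mask), series[0])

    def test_antisymmetric_voxels_cancel(self):
        shape = (2, 1, 1)
        s = np.sin(np.arange(20.0))
        data = np.stack([s, -s]).reshape(2, 1, 1, 20)
        mask = np.ones(shape, bool)
        np.testing.assert_allclose(extract_mean(data, mask), 0.0, atol=1e-15)

    def test_matches_direct_summation(self, rng):
        data, mask, series = self._data(rng)
        oracle = np.zeros(series.shape[1])
        for row in series:
            oracle += row
        oracle /= series.shape[0]
        np.testing.assert_allclose(extract_mean(data, mask), oracle, atol=1e-13)


class TestEigenvariate:
    def test_rank_one_roi_recovers_series(self, rng):
        shape = (3, 3, 1)
        base = rng.standard_normal(40)
        weights = rng.uniform(0.5, 2.0, 9)
        data = (weights[:, None] * base[None, :]).reshape(3, 3, 1, 40)
        mask = np.ones(shape, bool)
        eig = extract_first_eigenvariate(data, mask)
        c = np.corrcoef(eig, base)[0, 1]
        assert c == pytest.approx(1.0, abs=1e-10)

    def test_sign_tie_break_for_antisymmetric_pair(self):
        s = np.sin(np.arange(30.0))
        data = np.stack([s, -s]).reshape(2, 1, 1, 30)
        mask = np.ones((2, 1, 1), bool)
        eig = extract_first_eigenvariate(data, mask)
        # mean residual is zero -> tie broken by the first voxel's residual
        assert np.corrcoef(eig, s)[0, 1] > 0

    def test_matches_full_svd_oracle(self, rng):
        shape = (10, 1, 1)
        Y = rng.standard_normal((10, 50))  # voxels x time
        data = Y.reshape(10, 1, 1, 50)
        mask = np.ones(shape, bool)
        eig = extract_first_eigenvariate(data, mask)
        R = Y.T - Y.T.mean(axis=0)  # intercept-adjusted, time x voxel
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        c = np.corrcoef(eig, U[:, 0])[0, 1]
        assert c ** 2 == pytest.approx(1.0, abs=1e-10)

    def test_scaling_is_rms_amplitude(self, rng):
        Y = rng.standard_normal((6, 40))
        data = Y.reshape(6, 1, 1, 40)
        mask = np.ones((6, 1, 1), bool)
        eig = extract_first_eigenvariate(data, mask)
        R = Y.T - Y.T.mean(axis=0)
        _, s, _ = np.linalg.svd(R, full_matrices=False)
        np.testing.assert_allclose(np.linalg.norm(eig), s[0] / np.sqrt(6), rtol=1e-10)

    def test_rank_deficient_nuisance_rejected(self, rng):
        data = rng.standard_normal((2, 2, 1, 20))
        mask = np.ones((2, 2, 1), bool)
        bad = np.ones((20, 2))  # duplicate of the intercept
        with pytest.raises(np.linalg.LinAlgError):
            extract_first_eigenvariate(data, mask, adjust=bad)

    def test_mean_and_eigenvariate_agree_on_rank_one(self, rng):
        base = rng.standard_normal(40)
        data = np.tile(base, (2, 2, 1, 1))
        mask = np.ones((2, 2, 1), bool)
        m = extract_mean(data, mask)
        e = extract_first_eigenvariate(data, mask)
        c = np.corrcoef(m - m.mean(), e)[0, 1]
        assert c == pytest.approx(1.0, abs=1e-10)


class TestVolumeRoundTrip:
    def _specs(self):
        return [RoiSpec("LMOG", 0, 0, 0, 8.0), RoiSpec("LFuG", 30, 0, 0, 8.0)]

    def _dataset(self, n_subjects=2):
        from tvconn import constant_trajectory, checkerboard_design
        design = checkerboard_design()
        trajs = [constant_trajectory(("LMOG", "LFuG"), design, 0.4)]
        config = SyntheticConfig(n_subjects=n_subjects, seed=77,
                                 roi_names=("LMOG", "LFuG"),
                                 activated_rois=("LMOG",),
                                 trajectories=trajs)
        return simulate_cohort(config)

    def test_noiseless_mean_extraction_is_exact(self):
        dataset = self._dataset(1)
        images, table = embed_in_volumes(dataset, self._specs(),
                                         voxel_noise_sd=0.0)
        img = images[0]
        assert float(img.header.get_zooms()[3]) == pytest.approx(0.645)
        for spec in self._specs():
            mask = make_sphere_mask(spec, img.shape[:3], img.affine)
            extracted = extract_mean(img, mask)
            np.testing.assert_allclose(extracted,
                                       dataset.subjects[0].column(spec.name),
                                       atol=1e-5)  # float32 storage

    def test_noisy_extraction_correlates_above_99(self):
        dataset = self._dataset(1)
        images, _ = embed_in_volumes(dataset, self._specs(), voxel_noise_sd=0.1)
        img = images[0]
        for spec in self._specs():
            mask = make_sphere_mask(spec, img.shape[:3], img.affine)
            c = np.corrcoef(extract_mean(img, mask),
                            dataset.subjects[0].column(spec.name))[0, 1]
            assert c > 0.99

    def test_single_voxel_sphere_returns_that_voxel(self):
        dataset = self._dataset(1)
        specs = [RoiSpec("LMOG", 0, 0, 0, 1.0), RoiSpec("LFuG", 30, 0, 0, 1.0)]
        # grid aligned so the sphere centers fall on voxel centers (a radius
        # below half the voxel size keeps exactly that voxel)
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-15.0, -15.0, -15.0)
        images, _ = embed_in_volumes(dataset, specs, shape=(21, 11, 11),
                                     affine=affine, voxel_noise_sd=0.0)
        img = images[0]
        mask = make_sphere_mask(specs[0], img.shape[:3], img.affine)
        assert mask.sum() == 1
        np.testing.assert_allclose(extract_mean(img, mask),
                                   dataset.subjects[0].column("LMOG"),
                                   atol=1e-5)

    def test_overlapping_spheres_rejected(self):
        dataset = self._dataset(1)
        specs = [RoiSpec("LMOG", 0, 0, 0, 8.0), RoiSpec("LFuG", 6, 0, 0, 8.0)]
        with pytest.raises(ValueError, match="overlap"):
            embed_in_volumes(dataset, specs)

    def test_extract_roi_series_pipeline_entry(self):
        dataset = self._dataset(1)
        images, _ = embed_in_volumes(dataset, self._specs(), voxel_noise_sd=0.05)
        series = extract_roi_series(images[0], self._specs(), method="mean",
                                    subject_id="sub-000")
        assert series.roi_names == ["LMOG", "LFuG"]
        assert series.tr == pytest.approx(0.645)
        assert series.n_samples == 240


class TestTextRoundTrips:
    def test_roi_table(self, tmp_path):
        specs = [RoiSpec("LMOG", -21, -91, -5, 8.0), RoiSpec("PCC", -5, -49, 40, 8.0)]
        path = tmp_path / "rois.tsv"
        write_roi_table(specs, path)
        back = read_roi_table(path)
        assert back == specs

    def test_roi_table_rejects_duplicates(self, tmp_path):
        path = tmp_path / "rois.csv"
        path.write_text("name,x,y,z,radius\nA,0,0,0,8\nA,1,1,1,8\n")
        with pytest.raises(ValueError, match="unique"):
            read_roi_table(path)

    def test_timeseries_tsv(self, tmp_path, rng):
        from tvconn import RoiTimeSeries
        series = RoiTimeSeries("sub-001", ["A", "B"], 0.645,
                               rng.standard_normal((50, 2)), t0=9.03)
        path = tmp_path / "series.tsv"
        write_roi_timeseries(series, path)
        back = read_roi_timeseries(path)
        assert back.subject_id == "sub-001"
        assert back.roi_names == ["A", "B"]
        assert back.tr == pytest.approx(0.645)
        assert back.t0 == pytest.approx(9.03)
        np.testing.assert_allclose(back.values, series.values, atol=1e-9)

    def test_motion_table(self, tmp_path, rng):
        table = rng.standard_normal((20, 6))
        path = tmp_path / "motion.txt"
        np.savetxt(path, table)
        np.testing.assert_allclose(read_motion_table(path), table)
        bad = tmp_path / "bad.txt"
        np.savetxt(bad, rng.standard_normal((20, 5)))
        with pytest.raises(ValueError, match="6 columns"):
            read_motion_table(bad)
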