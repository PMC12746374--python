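import numpy as np
import pytest

from hpurea import (
    DynamicSeries,
    FitOptions,
    PhantomSpec,
    PhysioParams,
    VIFParams,
    auc_map,
    extract_vif_timecourse,
    generate_phantom,
    simulate_dynamic_signal,
    voxelwise_fit,
)


@pytest.fixture(scope="module")
def clean_phantom():
    spec = PhantomSpec(peak_snr=None)
    series, truth = generate_phantom(spec, seed=0)
    return spec, series, truth


class TestPhantom:
    def test_noise_free_voxels_bitmatch_simulator(self, clean_phantom):
        spec, series, truth = clean_phantom
        acq = series.acquisition
        expected = simulate_dynamic_signal(spec.physio, acq, spec.vif, "I").values
        i, j, k = np.argwhere(truth["tumor_mask"])[0]
        assert np.array_equal(series.data[i, j, k, :], expected)
        bg = np.zeros(series.n_timepoints)
        assert np.array_equal(series.data[0, 0, 0, :], bg)

    def test_sensitivity_scaling(self):
        sens = np.ones((16, 16, 1))
        sens[8:14, 8:14, :] = 0.5
        a, _ = generate_phantom(PhantomSpec(peak_snr=None), seed=0)
        b, _ = generate_phantom(PhantomSpec(peak_snr=None, sensitivity=sens), seed=0)
        assert np.allclose(b.data[8:14, 8:14, 0, :], 0.5 * a.data[8:14, 8:14, 0, :])

    def test_reproducible_under_seed(self):
        a, _ = generate_phantom(PhantomSpec(peak_snr=13.0), seed=5)
        b, _ = generate_phantom(PhantomSpec(peak_snr=13.0), seed=5)
        c, _ = generate_phantom(PhantomSpec(peak_snr=13.0), seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_empirical_peak_snr(self):
        """At the realism setting of peak SNR 13, the realized tumor peak
        over noise SD matches the request within Monte-Carlo error."""
        spec = PhantomSpec(peak_snr=13.0)
        series, truth = generate_phantom(spec, seed=1)
        peaks = series.data[truth["tumor_mask"]].max(axis=1)
        snr = peaks.mean() / truth["noise_sigma"]
        assert snr == pytest.approx(13.0, rel=0.15)

    def test_vif_voxel_inside_tumor_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(vif_voxel=(9, 9, 0)), seed=0)


class TestVIFExtraction:
    def test_recovers_generating_bolus(self, clean_phantom):
        spec, series, truth = clean_phantom
        curve = extract_vif_timecourse(series, spec.vif_voxel)
        assert np.allclose(curve.values, truth["vif_curve"])

    def test_zero_voxel_warns(self, clean_phantom):
        _, series, _ = clean_phantom
        with pytest.warns(RuntimeWarning, match="not bolus-like"):
            extract_vif_timecourse(series, (0, 0, 0))

    def test_out_of_bounds_rejected(self, clean_phantom):
        _, series, _ = clean_phantom
        with pytest.raises(IndexError):
            extract_vif_timecourse(series, (99, 0, 0))

    def test_single_timepoint_series_rejected(self):
        with pytest.raises(ValueError):
            DynamicSeries(np.zeros((4, 4, 1, 1)), tr=1.0, flip_deg=20.0)


class TestAUCMap:
    def test_single_timepoint_window(self, clean_phantom):
        _, series, _ = clean_phantom
        m = auc_map(series, [3.0, 4.0])
        assert np.array_equal(m, series.data[..., 3])

    def test_constant_series(self):
        series = DynamicSeries(np.full((3, 3, 1, 10), 2.5), tr=1.0, flip_deg=20.0)
        assert np.allclose(auc_map(series, [0.0, 10.0]), 2.5)

    def test_vif_brighter_than_tumor_early(self, clean_phantom):
        spec, series, truth = clean_phantom
        m = auc_map(series, [0.0, 15.0])
        assert m[spec.vif_voxel] > m[truth["tumor_mask"]].mean()

    def test_additivity(self, clean_phantom):
        _, series, _ = clean_phantom
        a = auc_map(series, [0.0, 10.0])
        b = auc_map(series, [10.0, 30.0])
        c = auc_map(series, [0.0, 30.0])
        assert np.allclose((10 * a + 20 * b) / 30, c)

    def test_empty_window_rejected(self, clean_phantom):
        _, series, _ = clean_phantom
        with pytest.raises(ValueError):
            auc_map(series, [200.0, 300.0])


class TestVoxelwiseFit:
    def test_mask_safety_and_maps(self, clean_phantom):
        spec, series, truth = clean_phantom
        vif_curve = extract_vif_timecourse(series, spec.vif_voxel)
        mask = np.zeros(series.spatial_shape, dtype=bool)
        mask[8:10, 8, 0] = True
        maps = voxelwise_fit(series, mask, vif_curve, "I")
        assert np.isnan(maps["kve"][~mask]).all()
        assert np.isfinite(maps["kve"][mask]).all()
        assert set(maps.maps) >= {"kve", "vb", "vee", "vif_scale", "kve_ve", "residual_norm", "converged"}

    def test_all_false_mask_rejected(self, clean_phantom):
        spec, series, _ = clean_phantom
        vif_curve = extract_vif_timecourse(series, spec.vif_voxel)
        with pytest.raises(ValueError):
            voxelwise_fit(series, np.zeros(series.spatial_shape, bool), vif_curve, "I")

    def test_dataframe_export(self, clean_phantom):
        spec, series, truth = clean_phantom
        vif_curve = extract_vif_timecourse(series, spec.vif_voxel)
        mask = np.zeros(series.spatial_shape, dtype=bool)
        mask[8, 8, 0] = True
        maps = voxelwise_fit(series, mask, vif_curve, "I")
        df = maps.to_dataframe()
        assert len(df) == 1
        assert {"x", "y", "z", "kve", "kve_ve"} <= set(df.columns)


class TestNiftiRoundtrip:
    def test_series_roundtrip(self, tmp_path, clean_phantom):
        _, series, _ = clean_phantom
        path = tmp_path / "series.nii.gz"
        series.to_nifti(path)
        back = DynamicSeries.from_nifti(path, flip_deg=series.flip_deg)
        assert back.tr == pytest.approx(series.tr)
        assert np.allclose(back.data, series.data)

    def test_parameter_maps_to_nifti(self, tmp_path, clean_phantom):
        import nibabel as nib

        spec, series, _ = clean_phantom
        vif_curve = extract_vif_timecourse(series, spec.vif_voxel)
        mask = np.zeros(series.spatial_shape, dtype=bool)
        mask[8, 8, 0] = True
        maps = voxelwise_fit(series, mask, vif_curve, "I")
        maps.to_nifti(tmp_path)
        img = nib.load(tmp_path / "kve.nii.gz")
        arr = np.asarray(img.get_fdata())
        assert arr.shape == series.spatial_shape
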