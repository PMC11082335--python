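"""Phantom generation, ground truth, determinism, and cohort structure."""

import dataclasses
import warnings

import numpy as np
import pytest

from csfpulse.metric import SliceSignals, compute_csfpulse_series
from csfpulse.roi import BoundingBox, segment_csf_roi, voxel_volume
from csfpulse.synthetic import (
    CohortSpec,
    PhantomSpec,
    SpecError,
    VelocityWaveform,
    VentricleGeometry,
    _solve_amplitude,
    default_cohort_spec,
    generate_cohort,
    generate_phantom,
    simulate_pair_signals,
)


def small_phantom(**overrides):
    defaults = dict(
        shape_xy=(32, 32),
        ventricle=VentricleGeometry(
            center_xy=(16, 16), radius_vox=2.0, slice_span=(8, 11)
        ),
        waveform=VelocityWaveform(kind="constant", v0_mm_s=3.7),
        noise_sd=0.0,
        seed=1,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def run_estimator_on(img, truth, bbox=BoundingBox(12, 12, 20, 20)):
    """The analysis path: segment both target slices, extract ROI means,
    apply the estimator with the phantom's own calibration."""
    data = np.asarray(img.dataobj, dtype=np.float64)
    lo = truth["target_lower_slice"]
    vv = truth["voxel_volume_mm3"]
    rois = {
        i: segment_csf_roi(
            data[:, :, i - 1, 5:].mean(axis=-1), bbox, voxel_volume_mm3=vv
        )
        for i in (lo, lo + 1)
    }
    sig = {i: data[:, :, i - 1, :][rois[i].mask].mean(axis=0) for i in (lo, lo + 1)}
    return compute_csfpulse_series(
        SliceSignals(sig[lo], sig[lo + 1]),
        truth["alpha"],
        rois[lo + 1].roi_volume_mm3,
    )


class TestPhantom:
    def test_static_phantom_is_constant_at_steady_state(self):
        spec = small_phantom(waveform=VelocityWaveform(kind="constant", v0_mm_s=0.0))
        img, truth = generate_phantom(spec)
        data = np.asarray(img.dataobj)
        vent = data[16, 16, 7:11, :]  # in-tube voxel across target slices
        assert np.ptp(vent) == 0.0
        assert vent[0, 0] == pytest.approx(0.371938, abs=1e-5)

    def test_ground_truth_is_exact_function_of_waveform(self, protocol):
        spec = small_phantom()
        _, truth = generate_phantom(spec)
        f = np.asarray(truth["fraction"])
        # constant 3.7 mm/s, interTR 322 ms, 4 mm slices: f = 0.29785
        assert np.allclose(f, 3.7 * 0.322 / 4.0)
        assert np.allclose(
            truth["pulsed_volume_mm3"], f * truth["roi_volume_mm3"]
        )

    def test_noise_free_recovery_is_exact(self):
        img, truth = generate_phantom(small_phantom())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant series: no z-score
            series = run_estimator_on(img, truth)
        expected = np.maximum(np.asarray(truth["pulsed_volume_mm3"])[5:], 0).mean()
        assert len(series) == 155
        assert abs(series.mean_pulse - expected) < 1e-6

    def test_descending_flow_drives_positive_ratio_down(self):
        asc = small_phantom(
            waveform=VelocityWaveform(kind="sinusoid", amplitude_mm_s=4.0),
            noise_sd=0.01, seed=5,
        )
        desc = dataclasses.replace(
            asc,
            waveform=VelocityWaveform(
                kind="sinusoid", v0_mm_s=-6.0, amplitude_mm_s=4.0
            ),
        )
        ratios = {}
        for name, spec in (("asc", asc), ("desc", desc)):
            img, truth = generate_phantom(spec)
            ratios[name] = run_estimator_on(img, truth).positive_ratio
        assert ratios["desc"] < ratios["asc"]

    def test_velocities_beyond_capture_range_register_nothing(self):
        # 30 mm/s > v_max = 24.8 mm/s: zero exchanged fraction, static tube
        spec = small_phantom(waveform=VelocityWaveform(kind="constant", v0_mm_s=30.0))
        img, truth = generate_phantom(spec)
        assert np.all(np.asarray(truth["fraction"]) == 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = run_estimator_on(img, truth)
        assert series.positive_ratio == 0.0

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        import nibabel as nib

        spec = small_phantom(noise_sd=0.05)
        for run in ("a", "b"):
            img, _ = generate_phantom(spec)
            nib.save(img, str(tmp_path / f"{run}.nii"))
        assert (tmp_path / "a.nii").read_bytes() == (tmp_path / "b.nii").read_bytes()

    def test_target_pair_outside_tube_rejected(self):
        with pytest.raises(SpecError, match="outside ventricle span"):
            small_phantom(target_lower_slice=12)

    def test_signal_level_shortcut_matches_image_path_noise_free(self):
        spec = small_phantom()
        signals, truth = simulate_pair_signals(spec)
        series = compute_csfpulse_series(
            signals, truth["alpha"], truth["roi_volume_mm3"]
        )
        img, img_truth = generate_phantom(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            image_series = run_estimator_on(img, img_truth)
        assert series.mean_pulse == pytest.approx(image_series.mean_pulse, rel=1e-9)


class TestVentricleGeometry:
    def test_exact_voxel_count_mode(self):
        for k in (2, 7, 13):
            g = VentricleGeometry(center_xy=(16, 16), n_voxels=k)
            assert g.cross_section((32, 32)).sum() == k

    def test_waveform_must_be_finite(self):
        w = VelocityWaveform(kind="sinusoid", amplitude_mm_s=np.inf)
        with pytest.raises(ValueError, match="finite"):
            w.evaluate([0.0, 1.0])


class TestCohort:
    def test_study_group_structure(self):
        manifest = generate_cohort(default_cohort_spec(seed=2), image_mode="none")
        sizes = manifest.groupby("group").size().to_dict()
        assert sizes == {"HC": 17, "PDD-L": 16, "PDD-H": 19}
        assert manifest.subject_id.is_unique
        genders = manifest.groupby(["group", "gender"]).size()
        assert genders["HC", "M"] == 10 and genders["HC", "F"] == 7
        assert genders["PDD-L", "M"] == 11 and genders["PDD-H", "M"] == 13

    def test_missing_instruments_follow_study_availability(self):
        manifest = generate_cohort(default_cohort_spec(seed=2), image_mode="none")
        assert manifest.loc[manifest.group == "HC", "mmse"].isna().all()
        assert manifest.loc[manifest.group != "HC", "mmse"].notna().all()
        updrs_n = manifest.groupby("group")["updrs"].count().to_dict()
        assert updrs_n == {"HC": 0, "PDD-L": 11, "PDD-H": 15}

    def test_determinism_under_fixed_seed(self):
        a = generate_cohort(default_cohort_spec(seed=9), image_mode="signal")
        b = generate_cohort(default_cohort_spec(seed=9), image_mode="signal")
        assert a.equals(b)

    def test_group_pulsation_targets_recovered_within_sampling_error(self):
        spec = default_cohort_spec(seed=4)
        manifest = generate_cohort(spec, image_mode="signal")
        for g in spec.groups:
            got = manifest.loc[manifest.group == g.name, "mean_pulse"].mean()
            # group mean of the estimate vs the published target, within
            # twice the published standard error of that mean
            assert abs(got - g.pulse_mean) < 2.5 * g.pulse_se * np.sqrt(2.0), (
                g.name, got, g.pulse_mean
            )

    def test_estimates_track_per_subject_targets(self):
        manifest = generate_cohort(default_cohort_spec(seed=4), image_mode="signal")
        err = manifest.mean_pulse - manifest.truth_mean_pulse
        assert np.abs(err).median() < 1.0  # a.u., targets span ~3-30

    def test_infeasible_target_raises_spec_error(self, protocol, tissue):
        from csfpulse.acquisition import interslice_interval
        from csfpulse.bloch import calibrate_alpha

        pair = interslice_interval(protocol, 8)
        alpha = calibrate_alpha(protocol, tissue, pair).alpha
        spec = default_cohort_spec()
        with pytest.raises(SpecError, match="exceeds the capture"):
            _solve_amplitude(
                1e6, 0.3, spec, roi_volume=181.5, k=6, alpha=alpha, pair=pair
            )

    def test_nifti_mode_writes_loadable_images(self, tmp_path):
        import nibabel as nib

        spec = default_cohort_spec(seed=6)
        tiny = tuple(
            dataclasses.replace(g, n=2, n_male=1, n_female=1, n_updrs=None)
            for g in spec.groups
        )
        spec = dataclasses.replace(spec, groups=tiny, shape_xy=(24, 24))
        manifest = generate_cohort(spec, out_dir=tmp_path, image_mode="nifti")
        assert (tmp_path / "manifest.tsv").exists()
        img = nib.load(manifest.image_path.iloc[0])
        assert img.shape == (24, 24, 31, 160)
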