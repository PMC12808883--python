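import numpy as np
import pytest

from glucocest.phantom import (
    CALIBRATED_FRACTIONS,
    CohortSpec,
    add_rician_noise,
    b0_field,
    generate_cardiac_phantom,
    generate_roi_cohort,
    generate_tube_phantom,
)
from glucocest.pipeline import mtr_asym, normalize, process_spectrum, roi_spectrum
from glucocest.stats import group_compare

SMALL = dict(n_healthy=1, n_mi=1, image_size=(48, 48), annulus_radii=(7.0, 12.0))


class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        out = add_rician_noise(img, 0.0, 1)
        assert np.array_equal(out, img)

    def test_rayleigh_mean_at_zero_signal(self):
        """Magnitude of pure noise has mean sigma*sqrt(pi/2)."""
        rng = np.random.default_rng(0)
        out = add_rician_noise(np.zeros(200_000), 0.05, rng)
        assert out.mean() == pytest.approx(0.05 * np.sqrt(np.pi / 2), rel=0.01)

    def test_reproducible_per_seed(self):
        img = np.ones((8, 8))
        a = add_rician_noise(img, 0.1, 42)
        b = add_rician_noise(img, 0.1, 42)
        assert np.array_equal(a, b)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -0.1, 0)


class TestB0Field:
    def test_amplitude_and_smoothness(self):
        rng = np.random.default_rng(3)
        f = b0_field((48, 48), 0.3, rng)
        assert np.abs(f).max() == pytest.approx(0.3, rel=1e-9)
        # smooth: neighbouring pixels differ much less than the amplitude
        assert np.abs(np.diff(f, axis=0)).max() < 0.1

    def test_zero_amplitude(self):
        rng = np.random.default_rng(3)
        assert np.all(b0_field((8, 8), 0.0, rng) == 0)


class TestCardiacPhantom:
    def test_deterministic_per_seed(self):
        a = generate_cardiac_phantom(CohortSpec(**SMALL, seed=9))
        b = generate_cardiac_phantom(CohortSpec(**SMALL, seed=9))
        assert np.array_equal(a[0].raw_pre.stack, b[0].raw_pre.stack)
        assert np.array_equal(a[1].vfa_stack, b[1].vfa_stack)
        assert np.array_equal(a[1].b0_field_ppm, b[1].b0_field_ppm)

    def test_regions_disjoint_and_labelled(self):
        animals = generate_cardiac_phantom(CohortSpec(**SMALL, seed=1))
        healthy, mi = animals
        assert set(healthy.rois) == {"healthy"}
        assert set(mi.rois) == {"mi", "rm"}
        assert not np.any(mi.rois["mi"] & mi.rois["rm"])

    def test_geometry_must_fit(self):
        with pytest.raises(ValueError):
            CohortSpec(image_size=(16, 16), annulus_radii=(7.0, 12.0))

    def test_noiseless_uniform_phantom_matches_calibration(self):
        """With all degradations off, the ROI-level chain reproduces the
        band-mean contrasts the region fractions were calibrated to."""
        spec = CohortSpec(
            **SMALL,
            noise_sigma=0.0,
            ripple_amplitude=0.0,
            b0_amplitude_ppm=0.0,
            animal_scale_sigma=0.0,
            state_jitter_sigma=0.0,
            seed=2,
        )
        animals = generate_cardiac_phantom(spec)
        healthy = animals[0]
        pre = mtr_asym(roi_spectrum(healthy.raw_pre, healthy.rois["healthy"]))
        post = mtr_asym(roi_spectrum(healthy.raw_post, healthy.rois["healthy"]))
        assert pre.contrast_mean == pytest.approx(0.035, abs=1e-3)
        assert post.contrast_mean == pytest.approx(0.009, abs=1e-3)

    def test_ground_truth_signs_recorded(self):
        animals = generate_cardiac_phantom(CohortSpec(**SMALL, seed=1))
        mi = animals[1]
        assert mi.truth["expected_delta_sign"] == {"mi": +1, "rm": 0}
        assert animals[0].truth["expected_delta_sign"] == {"healthy": -1}


class TestRoiCohort:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort_contrasts():
        cohort = generate_roi_cohort(CohortSpec(seed=1))
        rows = {}
        for rec in cohort:
            for region, states in rec["regions"].items():
                for state, raw in states.items():
                    z, _ = normalize(raw)
                    spec = process_spectrum(
                        np.array(raw.offsets_hz), z, raw.ref_freq_mhz
                    )
                    rows.setdefault((region, state), []).append(
                        mtr_asym(spec).contrast_mean
                    )
        return {k: np.array(v) for k, v in rows.items()}

    def test_group_delta_signs_match_ground_truth(self, cohort_contrasts):
        """Per-animal Δ contrast signs: healthy negative, MI positive, for
        at least 13 of the 14 sign-bearing animals."""
        dh = cohort_contrasts[("healthy", "post")] - cohort_contrasts[("healthy", "pre")]
        dm = cohort_contrasts[("mi", "post")] - cohort_contrasts[("mi", "pre")]
        n_correct = int(np.sum(dh < 0) + np.sum(dm > 0))
        assert n_correct >= 13

    def test_remote_delta_smallest_in_magnitude(self, cohort_contrasts):
        dh = cohort_contrasts[("healthy", "post")] - cohort_contrasts[("healthy", "pre")]
        dm = cohort_contrasts[("mi", "post")] - cohort_contrasts[("mi", "pre")]
        dr = cohort_contrasts[("rm", "post")] - cohort_contrasts[("rm", "pre")]
        assert abs(dr.mean()) < abs(dh.mean())
        assert abs(dr.mean()) < abs(dm.mean())

    def test_paired_and_unpaired_tests_reject(self, cohort_contrasts):
        _, p_h, _ = group_compare(
            cohort_contrasts[("healthy", "post")],
            cohort_contrasts[("healthy", "pre")],
            paired=True,
        )
        dm = cohort_contrasts[("mi", "post")] - cohort_contrasts[("mi", "pre")]
        dh = cohort_contrasts[("healthy", "post")] - cohort_contrasts[("healthy", "pre")]
        _, p_u, _ = group_compare(dm, dh, paired=False)
        assert p_h < 0.05
        assert p_u < 0.05


class TestTubePhantom:
    def test_water_only_tube_has_no_contrast(self):
        raw, masks = generate_tube_phantom([0.0])
        spec = roi_spectrum(raw, masks[0.0])
        assert abs(mtr_asym(spec).contrast) < 2e-3

    def test_contrast_monotone_in_concentration(self):
        raw, masks = generate_tube_phantom([10.0, 25.0, 50.0, 75.0])
        cs = [mtr_asym(roi_spectrum(raw, m)).contrast for m in masks.values()]
        assert np.all(np.diff(cs) > 0)

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ValueError):
            generate_tube_phantom([])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_tube_phantom([-5.0])

    def test_deterministic_with_noise(self):
        a, _ = generate_tube_phantom([10.0], noise_sigma=0.02, seed=4)
        b, _ = generate_tube_phantom([10.0], noise_sigma=0.02, seed=4)
        assert np.array_equal(a.stack, b.stack)


class TestFullChainRecovery:
    def test_b0_field_recovered_within_tolerance(self):
        """Per-pixel B0 shift estimates track the generated field with
        RMSE below 0.05 ppm at default noise."""
        animals = generate_cardiac_phantom(CohortSpec(**SMALL, seed=5))
        errs = []
        for a in animals:
            z, mask = normalize(a.raw_pre)
            for idx in zip(*np.nonzero(mask)):
                sp = process_spectrum(
                    np.array(a.raw_pre.offsets_hz), z[(slice(None), *idx)], 400.2
                )
                if sp.valid:
                    errs.append(sp.b0_shift_ppm - a.b0_field_ppm[idx])
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 0.05

    def test_t1_t2_recovered_within_5pct(self):
        from glucocest.phantom import ECHO_TIMES_MS, FLIP_ANGLES_DEG, VFA_TR_MS
        from glucocest.relaxometry import VfaSeries, fit_t1_vfa, roi_t2_mean

        animals = generate_cardiac_phantom(CohortSpec(**SMALL, seed=6))
        for a in animals:
            for region, mask in a.rois.items():
                sig = np.array([a.vfa_stack[j][mask].mean() for j in range(5)])
                t1 = fit_t1_vfa(VfaSeries(sig, FLIP_ANGLES_DEG, VFA_TR_MS))
                assert t1.valid
                assert t1.time_ms == pytest.approx(a.truth["t1_ms"][region], rel=0.05)
                t2 = roi_t2_mean(a.me_stack, ECHO_TIMES_MS, mask)
                assert t2 == pytest.approx(a.truth["t2_ms"][region], rel=0.05)
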