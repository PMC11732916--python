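import numpy as np
import pytest

import dynpet as dp
from dynpet.errors import ParameterError, PhantomSpecError


class TestTissueLibrary:
    def test_population_mean_entries(self, library):
        liver = library["liver"]
        assert (liver.vB, liver.K1, liver.k2, liver.k3) == (0.002, 0.571, 0.674, 0.005)
        tumor = library["tumor"]
        assert (tumor.vB, tumor.K1, tumor.k2, tumor.k3) == (0.057, 0.267, 0.863, 0.234)
        assert set(library) == {
            "liver", "kidney", "spleen", "lung", "muscle", "bone", "tumor"
        }

    def test_derived_influx(self, library):
        assert library["liver"].ki == pytest.approx(0.0042, abs=5e-5)
        assert library["tumor"].ki == pytest.approx(0.0570, abs=5e-4)
        for p in library.values():
            assert p.k4 == 0.0

    def test_ground_truth_validation(self):
        with pytest.raises(ParameterError):
            dp.KineticParams(vB=1.5, K1=0.1, k2=0.1, k3=0.1).validate_ground_truth()
        with pytest.raises(ParameterError):
            dp.KineticParams(vB=0.1, K1=-0.1, k2=0.1, k3=0.1).validate_ground_truth()


class TestInputModel:
    def test_starts_at_zero_and_stays_nonnegative(self, feng):
        t = np.linspace(0, 60, 14401)
        c = feng(t)
        assert feng(0.0) == 0.0
        assert c.min() >= 0.0

    def test_single_early_peak_then_monotone_decay(self, feng):
        t = np.linspace(0, 60, 14401)
        c = feng(t)
        peak = c.argmax()
        assert 0.5 <= t[peak] <= 1.0  # 30-60 s post-injection
        assert np.all(np.diff(c[peak:]) <= 0)

    def test_late_tail_fraction(self, feng):
        t = np.linspace(0, 60, 14401)
        c = feng(t)
        assert 0.10 <= c[-1] / c.max() <= 0.25

    def test_delay_shifts_onset(self):
        delayed = dp.FengInput(delay=0.5)
        assert delayed(0.4) == 0.0
        assert delayed(0.6) > 0.0


class TestSimulateTac:
    def test_tumor_uptake_keeps_rising_late(self, library, schedule, feng):
        tac = dp.simulate_tac(library["tumor"], feng, schedule)
        i600 = int(np.searchsorted(schedule.ends, 600.0))
        assert tac.values[-1] > tac.values[i600]

    def test_liver_peaks_early_then_declines(self, library, schedule, feng):
        tac = dp.simulate_tac(library["liver"], feng, schedule)
        assert tac.values.argmax() < 20
        assert tac.values[-1] < tac.values.max()

    def test_midpoint_sampling_option(self, library, schedule, feng):
        avg = dp.simulate_tac(library["bone"], feng, schedule)
        mid = dp.simulate_tac(library["bone"], feng, schedule, frame_average=False)
        assert not np.array_equal(avg.values, mid.values)
        np.testing.assert_allclose(avg.values[-8:], mid.values[-8:], rtol=0.01)


class TestPhantom:
    def test_noiseless_region_voxels_carry_region_tac(
        self, small_noiseless_phantom, library, feng
    ):
        (image, vois, truth), spec = small_noiseless_phantom
        tac = dp.simulate_tac(library["liver"], spec.input_model, image.schedule)
        region = image.voxels[vois.mask("liver")]
        np.testing.assert_array_equal(region, np.tile(tac.values, (len(region), 1)))

    def test_blood_region_carries_frame_averaged_input(
        self, small_noiseless_phantom, feng
    ):
        (image, vois, _), spec = small_noiseless_phantom
        cp = spec.input_model.frame_averages(image.schedule)
        region = image.voxels[vois.mask("aorta")]
        np.testing.assert_array_equal(region, np.tile(cp, (len(region), 1)))

    def test_truth_table_lists_influx(self, small_noiseless_phantom, library):
        (_, _, truth), _ = small_noiseless_phantom
        row = truth.set_index("name").loc["tumor_1"]
        assert row["Ki"] == pytest.approx(library["tumor"].ki, rel=1e-12)
        assert row["tissue_type"] == "tumor"

    def test_fixed_seed_is_bit_reproducible(self):
        spec = dp.default_phantom_spec(noise_scale=0.3, seed=11,
                                       grid_shape=(12, 12, 24))
        a, _, _ = dp.build_phantom(spec)
        b, _, _ = dp.build_phantom(spec)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_overlapping_regions_rejected(self, library):
        regions = [
            dp.Region("a", 1, "ellipsoid", (6, 6, 6), (3, 3, 3), library["liver"]),
            dp.Region("b", 2, "ellipsoid", (7, 6, 6), (3, 3, 3), library["bone"]),
        ]
        spec = dp.PhantomSpec(grid_shape=(12, 12, 12), regions=regions,
                              noise_scale=0.0)
        with pytest.raises(PhantomSpecError):
            dp.build_phantom(spec)

    def test_spec_round_trip_through_dict(self):
        spec = dp.default_phantom_spec(noise_scale=0.1, seed=3,
                                       grid_shape=(12, 12, 24))
        back = dp.PhantomSpec.from_dict(spec.to_dict())
        a, _, ta = dp.build_phantom(spec)
        b, _, tb = dp.build_phantom(back)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert ta.equals(tb)

    def test_noisy_region_mean_tracks_truth(self, small_noisy_phantom, library,
                                            feng):
        """Monte-Carlo: the voxel mean per frame stays within 3 standard
        errors of the noiseless curve."""
        (image, vois, _), spec = small_noisy_phantom
        tac = dp.simulate_tac(library["liver"], spec.input_model, image.schedule)
        mask = vois.mask("liver")
        n = int(mask.sum())
        sd = np.sqrt(spec.noise_scale * np.maximum(tac.values, spec.noise_floor)
                     / image.schedule.durations_min)
        sem = sd / np.sqrt(n)
        z = np.abs(image.voxels[mask].mean(axis=0) - tac.values) / sem
        assert np.sum(z > 3.0) <= 1


class TestNoiseModel:
    def _constant_image(self, value, n_vox_side=22):
        sched = dp.FrameSchedule([0.0, 60.0], [60.0, 300.0])
        vox = np.full((n_vox_side, n_vox_side, n_vox_side, 2), value)
        return dp.DynamicImage(vox, sched), sched

    def test_zero_scale_is_identity(self):
        image, _ = self._constant_image(2.0)
        out = dp.add_noise(image, scale=0.0, seed=1)
        np.testing.assert_array_equal(out.voxels, image.voxels)

    def test_seed_reproducibility(self):
        image, _ = self._constant_image(2.0)
        a = dp.add_noise(image, scale=0.3, seed=42)
        b = dp.add_noise(image, scale=0.3, seed=42)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c = dp.add_noise(image, scale=0.3, seed=43)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_empirical_variance_matches_model(self):
        """Variance on ~10^4 voxels: scale * value / duration_min, per frame."""
        value, scale = 2.0, 0.3
        image, sched = self._constant_image(value)
        noisy = dp.add_noise(image, scale=scale, seed=0)
        resid = noisy.voxels - value
        for f, dur in enumerate(sched.durations_min):
            expected = scale * value / dur
            measured = resid[..., f].var()
            assert measured == pytest.approx(expected, rel=0.10)

    def test_negative_scale_rejected(self):
        image, _ = self._constant_image(1.0)
        with pytest.raises(ParameterError):
            dp.add_noise(image, scale=-0.1)


class TestJitter:
    def test_multi_tissue_library_composition(self):
        lib = dp.multi_tissue_library(50, seed=3)
        assert len(lib) == 50
        types = [t for _, t, _ in lib]
        assert types.count("tumor") == 20
        for _, _, p in lib:
            assert p.K1 > 0 and p.k2 > 0 and p.k3 > 0
            assert 0 <= p.vB <= 1

    def test_jitter_centred_on_population_mean(self):
        rng = np.random.default_rng(0)
        draws = [dp.jittered_tissue_params("tumor", rng) for _ in range(4000)]
        k1 = np.array([d.K1 for d in draws])
        # log-normal jitter is mean-preserving by construction
        assert k1.mean() == pytest.approx(0.267, rel=0.05)

    def test_seed_controls_draws(self):
        a = dp.multi_tissue_library(10, seed=5)
        b = dp.multi_tissue_library(10, seed=5)
        assert all(pa.K1 == pb.K1 for (_, _, pa), (_, _, pb) in zip(a, b))
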