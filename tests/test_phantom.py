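import numpy as np
import pytest
from scipy import stats

from radrep.grid import GridImage
from radrep.phantom import (
    CohortSpec,
    GroupSpec,
    PhantomSpec,
    default_frame_schedule,
    make_phantom,
    radius_for_volume_ml,
    reconstruct_image,
    simulate_cohort,
    simulate_counts,
    split_events,
    volume_ml_for_radius,
)


class TestMakePhantom:
    def test_piecewise_constant_ratio_exact(self, noiseless_spec):
        img = make_phantom(noiseless_spec, seed=0)
        tumor = img.meta["tumor_mask_true"]
        assert img.values[tumor].mean() == pytest.approx(2.0)
        assert img.values[~tumor].mean() == pytest.approx(1.0)
        # exactly two values present: no texture, no blur
        assert set(np.unique(img.values)) == {1.0, 2.0}

    def test_tumor_mean_before_blur(self, noiseless_spec):
        img = make_phantom(noiseless_spec, seed=0)
        tumor = img.meta["tumor_mask_true"]
        assert img.values[tumor].mean() == pytest.approx(
            noiseless_spec.tbr_contrast * noiseless_spec.background_uptake
        )

    def test_sphere_volume_closed_form(self):
        # 15 mm radius -> 4/3*pi*15^3 mm^3 = 14.14 mL
        assert volume_ml_for_radius(15.0) == pytest.approx(14.137, abs=1e-3)
        assert radius_for_volume_ml(volume_ml_for_radius(15.0)) == pytest.approx(15.0)

    def test_tumor_outside_grid_raises(self, noiseless_spec):
        import dataclasses

        bad = dataclasses.replace(noiseless_spec, tumor_center=(2.0, 47.0, 47.0))
        with pytest.raises(ValueError, match="does not fit"):
            make_phantom(bad, seed=0)

    def test_texture_amplitude_validated(self, noiseless_spec):
        import dataclasses

        bad = dataclasses.replace(noiseless_spec, texture_amplitude=1.5)
        with pytest.raises(ValueError):
            make_phantom(bad, seed=0)

    def test_determinism(self, textured_spec):
        a = make_phantom(textured_spec, seed=3)
        b = make_phantom(textured_spec, seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestSimulateCounts:
    def test_zero_map_gives_zero_counts(self):
        img = GridImage(np.zeros((6, 6, 6)))
        counts = simulate_counts(img, exposure=100.0, seed=0)
        assert counts.values.sum() == 0

    def test_large_exposure_convergence(self):
        img = GridImage(np.full((8, 8, 8), 2.5))
        counts = simulate_counts(img, exposure=1e6, seed=1)
        rel = np.abs(counts.values / 1e6 - 2.5) / 2.5
        assert rel.max() < 0.01

    def test_poisson_variance_matches_mean(self):
        img = GridImage(np.full((4, 4, 4), 5.0))
        draws = np.array(
            [simulate_counts(img, exposure=4.0, seed=s).values for s in range(2000)],
            dtype=float,
        )
        # per-voxel mean and variance of Poisson(20)
        assert draws.mean() == pytest.approx(20.0, rel=0.02)
        assert draws.var(axis=0).mean() == pytest.approx(20.0, rel=0.05)

    def test_nonfinite_rejected(self):
        img = GridImage(np.full((4, 4, 4), np.nan))
        with pytest.raises(ValueError):
            simulate_counts(img, exposure=1.0, seed=0)


class TestSplitEvents:
    def test_zero_count_voxel(self):
        img = GridImage(np.zeros((4, 4, 4), dtype=np.int64), unit="counts")
        a, b = split_events(img, seed=0)
        assert a.values.sum() == 0 and b.values.sum() == 0

    def test_sum_conservation_exact(self, rng):
        counts = GridImage(rng.poisson(50.0, size=(10, 10, 10)), unit="counts")
        a, b = split_events(counts, seed=5)
        np.testing.assert_array_equal(a.values + b.values, counts.values)

    def test_alternate_mode_conserves(self, rng):
        counts = GridImage(rng.poisson(9.0, size=(6, 6, 6)), unit="counts")
        a, b = split_events(counts, seed=0, mode="alternate")
        np.testing.assert_array_equal(a.values + b.values, counts.values)
        assert np.all(np.abs(a.values - b.values) <= 1)

    def test_halves_uncorrelated(self):
        # across many independent realizations the half deviations decorrelate
        n = 10_000
        rng = np.random.default_rng(0)
        counts = GridImage(rng.poisson(100.0, size=(n, 1, 1)), unit="counts")
        a, b = split_events(counts, seed=1)
        r = np.corrcoef(a.values.ravel(), b.values.ravel())[0, 1]
        assert abs(r) < 0.05

    def test_half_is_poisson_half_mean(self):
        # chi-square GOF of half-counts against Poisson(mean/2) at the 1% level
        mean = 40.0
        n = 20_000
        rng = np.random.default_rng(2)
        counts = GridImage(rng.poisson(mean, size=(n, 1, 1)), unit="counts")
        a, _ = split_events(counts, seed=3)
        observed = a.values.ravel()
        kmax = int(observed.max())
        obs_counts = np.bincount(observed, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), mean / 2.0) * n
        # pool sparse tails so expected counts stay >= 5
        keep = expected >= 5
        obs_pooled = np.concatenate([obs_counts[keep], [obs_counts[~keep].sum()]])
        exp_pooled = np.concatenate([expected[keep], [expected[~keep].sum()]])
        exp_pooled *= obs_pooled.sum() / exp_pooled.sum()
        chi2, p = stats.chisquare(obs_pooled, exp_pooled)
        assert p > 0.01


class TestReconstruct:
    def test_uniform_counts_normalize_to_one(self):
        img = GridImage(np.full((5, 5, 5), 40, dtype=np.int64), unit="counts")
        rec = reconstruct_image(img, exposure=40.0)
        np.testing.assert_allclose(rec.values, 1.0)

    def test_zero_smoothing_is_identity(self, rng):
        img = GridImage(rng.poisson(10.0, size=(6, 6, 6)), unit="counts")
        rec = reconstruct_image(img, exposure=2.0, post_smoothing_fwhm=0.0)
        np.testing.assert_allclose(rec.values, np.asarray(img.values) / 2.0)

    def test_halves_unbiased_for_map(self, noiseless_spec):
        activity = make_phantom(noiseless_spec, seed=0)
        acc_a = np.zeros(noiseless_spec.shape)
        acc_b = np.zeros(noiseless_spec.shape)
        n_rep = 60
        for s in range(n_rep):
            counts = simulate_counts(activity, noiseless_spec.exposure, seed=s)
            a, b = split_events(counts, seed=1000 + s)
            acc_a += reconstruct_image(a, noiseless_spec.exposure / 2).values
            acc_b += reconstruct_image(b, noiseless_spec.exposure / 2).values
        for acc in (acc_a, acc_b):
            np.testing.assert_allclose(acc / n_rep, activity.values, rtol=0.05, atol=0.02)


class TestCohort:
    def test_cohort_size_matches_groups(self):
        spec = CohortSpec(
            groups=[
                GroupSpec("wildtype", 3, volume_mean_ml=14.0, volume_sd_ml=2.0),
                GroupSpec("mutant", 2, volume_mean_ml=10.0, volume_sd_ml=2.0),
            ],
            shape=(48, 48, 48),
            exposure=100.0,
            seed=11,
        )
        subjects = simulate_cohort(spec)
        assert len(subjects) == 5
        assert sum(s.genotype == "wildtype" for s in subjects) == 3

    def test_determinism_bitwise(self):
        spec = CohortSpec(
            groups=[GroupSpec("a", 2), GroupSpec("b", 2)],
            shape=(48, 48, 48),
            exposure=50.0,
            seed=4,
        )
        c1 = simulate_cohort(spec)
        c2 = simulate_cohort(spec)
        for s1, s2 in zip(c1, c2):
            np.testing.assert_array_equal(s1.test.values, s2.test.values)
            np.testing.assert_array_equal(s1.retest.values, s2.retest.values)
            assert s1.true_volume_ml == s2.true_volume_ml

    def test_counter_based_seeds_stable_under_growth(self):
        base = dict(shape=(48, 48, 48), exposure=50.0, seed=9)
        small = simulate_cohort(CohortSpec(groups=[GroupSpec("a", 2), GroupSpec("b", 2)], **base))
        # adding a subject to the *last* group must not reshuffle earlier subjects
        big = simulate_cohort(CohortSpec(groups=[GroupSpec("a", 2), GroupSpec("b", 3)], **base))
        for s1, s2 in zip(small, big):
            np.testing.assert_array_equal(s1.test.values, s2.test.values)

    def test_group_volume_means_differ_in_direction(self):
        spec = CohortSpec(
            groups=[
                GroupSpec("big", 8, volume_mean_ml=22.0, volume_sd_ml=3.0),
                GroupSpec("small", 8, volume_mean_ml=8.0, volume_sd_ml=3.0),
            ],
            shape=(48, 48, 48),
            exposure=20.0,
            seed=21,
        )
        subjects = simulate_cohort(spec)
        big = [s.true_volume_ml for s in subjects if s.genotype == "big"]
        small = [s.true_volume_ml for s in subjects if s.genotype == "small"]
        t, p = stats.ttest_ind(big, small)
        assert t > 0 and p < 0.01

    def test_small_group_rejected(self):
        spec = CohortSpec(groups=[GroupSpec("solo", 1)])
        with pytest.raises(ValueError, match="at least two subjects"):
            simulate_cohort(spec)

    def test_pair_shares_grid(self):
        spec = CohortSpec(groups=[GroupSpec("a", 2), GroupSpec("b", 2)], shape=(48, 48, 48), exposure=20.0)
        for s in simulate_cohort(spec):
            assert s.test.same_grid(s.retest)


class TestFrameSchedule:
    def test_default_schedule(self):
        sched = default_frame_schedule()
        assert sched.n_frames == 16
        assert sched.durations_min == tuple([1.0] * 5 + [3.0] * 5 + [5.0] * 6)
        assert sched.total_minutes == 50.0

    def test_static_window_frames(self):
        sched = default_frame_schedule()
        i, j = sched.window(20.0, 40.0)
        assert sum(sched.durations_min[i:j]) == 20.0

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            default_frame_schedule().window(40.0, 60.0)
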