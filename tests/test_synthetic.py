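import numpy as np
import pytest

from ogttfda.shapes import classify_shape
from ogttfda.synthetic import (ARCHETYPES, BIPHASIC, FLAT, MONOPHASIC,
                               MONOTONIC, GeneratorParams, Latents,
                               _draw_shape_params, assign_followup,
                               event_probability, generate_cohort,
                               generate_profile, intercept_for_prevalence,
                               latent_height)

ARCH_TO_SHAPE = {MONOPHASIC: "monophasic", BIPHASIC: "biphasic",
                 MONOTONIC: "monotonically_increasing",
                 FLAT: "inconclusive"}


def make_latents(archetype, rng, amplitude=None, fasting=83.0, gain=2.0):
    sp = _draw_shape_params(archetype, rng)
    params = GeneratorParams()
    if amplitude is None:
        amplitude = 0.0 if archetype == FLAT else \
            params.amplitude_mean[archetype]
    return Latents(archetype=archetype, fasting=fasting, amplitude=amplitude,
                   shape_params=sp, gain=gain, insulin_basal=6.0,
                   insulin_scale=1.0, insulin_delay=10.0)


class TestProfiles:
    def test_flat_zero_noise_is_constant(self):
        p = GeneratorParams(noise_sd_glucose=0, noise_sd_insulin=0)
        lat = make_latents(FLAT, np.random.default_rng(0))
        prof = generate_profile(lat, p, np.random.default_rng(0))
        assert np.allclose(prof.glucose, prof.glucose[0])

    def test_monotonic_zero_noise_strictly_increasing(self):
        p = GeneratorParams(noise_sd_glucose=0, noise_sd_insulin=0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            lat = make_latents(MONOTONIC, rng)
            prof = generate_profile(lat, p, rng)
            assert np.all(np.diff(prof.glucose) > 0)

    def test_doubling_gain_doubles_preflush_insulin(self):
        """With an identical noise stream, the pre-floor insulin values are
        exactly proportional to the participant gain."""
        p = GeneratorParams()
        rng = np.random.default_rng(2)
        lat1 = make_latents(MONOPHASIC, rng, gain=2.0)
        lat2 = Latents(**{**{k: v for k, v in lat1.__dict__.items()
                             if not k.startswith("_")}, "gain": 4.0})
        prof1 = generate_profile(lat1, p, np.random.default_rng(77))
        prof2 = generate_profile(lat2, p, np.random.default_rng(77))
        assert np.allclose(prof1.glucose, prof2.glucose)
        ok = prof1.insulin > 1.0  # below the floor the ratio is clipped
        assert np.allclose(prof2.insulin[ok], 2.0 * prof1.insulin[ok])

    def test_zero_noise_archetypes_classify_as_themselves(self):
        p = GeneratorParams(noise_sd_glucose=0, noise_sd_insulin=0)
        rng = np.random.default_rng(3)
        for arch in ARCHETYPES:
            for _ in range(50):
                amp = None if arch == FLAT else \
                    float(rng.uniform(GeneratorParams().amplitude_floor[arch],
                                      180.0))
                lat = make_latents(arch, rng, amplitude=amp)
                prof = generate_profile(lat, p, rng)
                assert classify_shape(prof.glucose).label == \
                    ARCH_TO_SHAPE[arch]

    def test_generated_profiles_satisfy_invariants(self, small_cohort):
        for rec in small_cohort.records:
            rec.baseline_profile.validate()
            if rec.followup_profile is not None:
                rec.followup_profile.validate()


class TestCohort:
    def test_archetype_frequencies_match_mixture(self):
        coh = generate_cohort(n=1000, seed=1)
        freqs = coh.truth["archetype"].value_counts(normalize=True)
        assert abs(freqs.get(MONOPHASIC, 0) - 0.547) < 0.03
        assert abs(freqs.get(BIPHASIC, 0) - 0.420) < 0.03
        assert abs(freqs.get(MONOTONIC, 0) - 0.025) < 0.03

    def test_marginal_frequencies_converge(self):
        """Law of large numbers: mixture and demographic margins land
        within +/-2 binomial standard deviations at n=4000."""
        n = 4000
        coh = generate_cohort(n=n, seed=9)
        t = coh.truth
        for arch, w in GeneratorParams().mixture.items():
            sd = np.sqrt(w * (1 - w) / n)
            got = (t["archetype"] == arch).mean()
            assert abs(got - w) <= max(2 * sd, 2 / n)
        frac_female = np.mean([r.sex == "female" for r in coh.records])
        assert abs(frac_female - 0.539) <= 2 * np.sqrt(0.539 * 0.461 / n)
        fu = t["has_followup"].mean()
        assert abs(fu - 0.288) <= 2 * np.sqrt(0.288 * 0.712 / n)

    def test_determinism_and_substream_stability(self):
        a = generate_cohort(n=5, seed=123)
        b = generate_cohort(n=5, seed=123)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.baseline_profile.glucose,
                                  rb.baseline_profile.glucose)
            assert np.array_equal(ra.baseline_profile.insulin,
                                  rb.baseline_profile.insulin)
            assert ra.hba1c == rb.hba1c
        # enlarging the cohort must not perturb existing participants
        c = generate_cohort(n=10, seed=123)
        for ra, rc in zip(a.records, c.records[:5]):
            assert np.array_equal(ra.baseline_profile.glucose,
                                  rc.baseline_profile.glucose)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n=0, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(n=10, seed=1,
                            mixture={MONOPHASIC: 0.9, BIPHASIC: 0.3,
                                     MONOTONIC: 0.0, FLAT: 0.0})

    def test_demographics_in_range(self, small_cohort):
        for r in small_cohort.records:
            assert 8 <= r.age <= 18
            assert r.bmi_percentile >= 85
            r.validate()

    def test_bmi_positively_linked_to_curve_height(self):
        coh = generate_cohort(n=1500, seed=6)
        bmi = np.array([r.bmi_percentile for r in coh.records])
        h = coh.truth["latent_height"].to_numpy()
        keep = coh.truth["archetype"] != FLAT
        assert np.corrcoef(bmi[keep], h[keep])[0, 1] > 0.1


class TestOutcome:
    def test_prevalence_with_zero_coefficients(self):
        """With slopes zero and intercept logit(0.073), prevalence is 7.3%
        up to binomial error."""
        coh = generate_cohort(
            n=10000, seed=4, followup_fraction=1.0,
            outcome_coef_height=0.0, outcome_coef_exc120=0.0,
            outcome_intercept=intercept_for_prevalence(0.073))
        prev = coh.truth["event"].astype(float).mean()
        assert abs(prev - 0.073) < 0.01

    def test_default_calibration_prevalence(self):
        coh = generate_cohort(n=8000, seed=5, followup_fraction=1.0)
        prev = coh.truth["event"].astype(float).mean()
        assert abs(prev - 0.073) < 0.015

    def test_large_negative_intercept_gives_zero_events(self):
        coh = generate_cohort(n=2000, seed=6, followup_fraction=1.0,
                              outcome_intercept=-40.0)
        assert coh.truth["event"].astype(float).sum() == 0

    def test_event_label_consistent_with_thresholds(self):
        coh = generate_cohort(n=3000, seed=7, followup_fraction=1.0)
        for rec, event in zip(coh.records, coh.truth["event"]):
            fpg = rec.followup_profile.fpg
            pg2h = rec.followup_profile.pg2h
            assert event == (fpg > 100 or pg2h > 140)

    def test_followup_interval_at_least_six_months(self):
        coh = generate_cohort(n=500, seed=8)
        for r in coh.records:
            if r.has_followup:
                assert r.followup_interval >= 6

    def test_event_group_has_higher_glucose_fpc1(self):
        """Monte-Carlo: a strong positive coefficient on curve height makes
        the event group's mean glucose FPC1 score higher."""
        from ogttfda.config import PipelineConfig
        from ogttfda.fpca import fit_fpca, score_cohort, standardize_scores
        from ogttfda.pipeline import smooth_cohort

        coh = generate_cohort(n=2000, seed=9, followup_fraction=1.0,
                              outcome_coef_height=2.0,
                              outcome_coef_exc120=0.0)
        _, _, _, curves = smooth_cohort(coh.records, PipelineConfig())
        model = fit_fpca(curves["glucose"])
        z = standardize_scores(score_cohort(model, curves["glucose"]))
        event = coh.truth["event"].astype(bool).to_numpy()
        assert z[event, 0].mean() > z[~event, 0].mean() + 0.3

    def test_event_probability_monotone_in_height(self):
        params = GeneratorParams()
        rng = np.random.default_rng(11)
        lo = make_latents(MONOPHASIC, rng, amplitude=30.0)
        hi = make_latents(MONOPHASIC, rng, amplitude=120.0)
        assert event_probability(hi, params) > event_probability(lo, params)

    def test_fasting_glucose_carries_no_outcome_signal(self):
        coh = generate_cohort(n=6000, seed=10, followup_fraction=1.0)
        fpg = np.array([r.followup_profile.fpg for r in coh.records])
        event = coh.truth["event"].astype(bool).to_numpy()
        from ogttfda.prediction import roc_auc
        assert abs(roc_auc(fpg, event)["auc"] - 0.5) < 0.04
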