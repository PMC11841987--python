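"""Synthetic-cohort generator tests: waveform, schedule, CTQ, ratings, cohort."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from fearcond.scoring import ScoringConfig, score_recording
from fearcond.stats import cohens_d
from fearcond.synthetic import (
    SIMILARITY,
    STIMULI,
    SimulationConfig,
    draw_ctq_profiles,
    generate_cohort,
    generate_ctq_profile,
    generate_ratings,
    generate_trial_schedule,
    scr_waveform,
)
from fearcond.adversity import SUBSCALES, classify_dichotomous


class TestWaveform:
    def test_zero_amplitude_is_identically_zero(self):
        t = np.linspace(0, 20, 5000)
        assert not scr_waveform(t, 0.0).any()

    def test_peak_equals_amplitude(self):
        t = np.linspace(0, 30, 300_001)
        w = scr_waveform(t, 0.5)
        assert w.max() == pytest.approx(0.5, abs=1e-6)

    def test_peak_latency_within_scoring_window(self):
        t = np.linspace(0, 30, 300_001)
        w = scr_waveform(t, 1.0)
        assert 2.0 <= t[np.argmax(w)] <= 6.0

    def test_zero_before_latency_and_single_peak(self):
        t = np.linspace(0, 20, 20_001)
        w = scr_waveform(t, 1.0, latency=1.5)
        assert not w[t <= 1.5].any()
        peak = np.argmax(w)
        assert (np.diff(w[:peak]) >= 0).all()
        assert (np.diff(w[peak:]) <= 0).all()

    @pytest.mark.parametrize("kwargs", [{"rise": 0.0}, {"decay": -1.0},
                                        {"rise": 3.0, "decay": 2.0}])
    def test_invalid_time_constants_raise(self, kwargs):
        with pytest.raises(ValueError):
            scr_waveform(np.arange(5.0), 1.0, **kwargs)


class TestSchedule:
    def test_trial_counts_two_per_stimulus(self, rng):
        cfg = replace(SimulationConfig(), n_habituation_per_cs=2,
                      n_acquisition_per_cs=2, n_generalization_per_stimulus=2)
        s = generate_trial_schedule(cfg, rng)
        counts = s.groupby("phase").size()
        assert counts["habituation"] == 4
        assert counts["acquisition"] == 4
        assert counts["generalization"] == 12

    def test_onsets_strictly_increasing_and_spaced(self, rng):
        s = generate_trial_schedule(SimulationConfig(), rng)
        d = np.diff(s["onset"])
        assert (d > 0).all() and (d >= 6.0).all()

    def test_phase_order_and_stimulus_membership(self, rng):
        s = generate_trial_schedule(SimulationConfig(), rng)
        phases = s["phase"].drop_duplicates().tolist()
        assert phases == ["habituation", "acquisition", "generalization"]
        assert set(s.loc[s["phase"] == "habituation", "trial_type"]) == {"CS+", "CS-"}
        assert set(s.loc[s["phase"] == "generalization", "trial_type"]) == set(STIMULI)
        gs_rows = s[s["trial_type"].str.startswith("GS")]
        assert (gs_rows["phase"] == "generalization").all()

    def test_us_only_on_csplus_outside_habituation(self, rng):
        s = generate_trial_schedule(SimulationConfig(), rng)
        us = s[s["us"]]
        assert (us["trial_type"] == "CS+").all()
        assert not (us["phase"] == "habituation").any()
        acq = s[(s["phase"] == "acquisition") & (s["trial_type"] == "CS+")]
        assert us[us["phase"] == "acquisition"].shape[0] == round(0.5 * len(acq))

    def test_deterministic_under_fixed_seed(self):
        a = generate_trial_schedule(SimulationConfig(), np.random.default_rng(5))
        b = generate_trial_schedule(SimulationConfig(), np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            replace(SimulationConfig(), n_acquisition_per_cs=1)


class TestSignal:
    def test_zero_noise_roundtrip_recovers_amplitudes_within_1pc(self):
        cfg = replace(SimulationConfig(), n=2, noise_sd_us=0.0,
                      mains_amplitude_us=0.0, nonresponse_prob=0.0,
                      trial_log_sd=0.0, sampling_rate=100.0)
        cohort = generate_cohort(cfg, seed=5, ratings=False)
        sc = ScoringConfig(notch_hz=None)
        for i in range(2):
            tab = score_recording(cohort.render_recording(i), cohort.schedule,
                                  sc, preprocess=False)
            lat = cohort.latent_amplitudes[i]
            m = lat >= sc.min_response_us
            rel = np.abs(tab["raw"].to_numpy()[m] - lat[m]) / lat[m]
            assert rel.max() < 0.01

    def test_attenuation_one_removes_group_difference_in_expectation(self):
        cfg = replace(SimulationConfig(), n=4000, prevalence=0.5,
                      csplus_attenuation=1.0, reactivity_attenuation=1.0)
        c = generate_cohort(cfg, seed=6, ratings=False)
        m = c.latent_amplitudes.mean(axis=1)
        e = c.participants["exposed_true"].to_numpy()
        assert abs(cohens_d(m[e], m[~e])) < 0.08

    def test_forced_nonresponse_zeroes_every_trial(self):
        cfg = replace(SimulationConfig(), n=3, nonresponse_prob=1.0)
        c = generate_cohort(cfg, seed=7, ratings=False)
        assert not c.latent_amplitudes.any()

    def test_low_sampling_rate_with_mains_rejected(self):
        with pytest.raises(ValueError, match="200"):
            replace(SimulationConfig(), sampling_rate=100.0)


class TestCtq:
    def test_scores_within_instrument_range(self, default_config, ctq_multiplier, rng):
        prof = draw_ctq_profiles(default_config, 2000, rng, ctq_multiplier)
        assert prof.min().min() >= 5 and prof.max().max() <= 25

    def test_low_latent_hits_floor(self, rng):
        prof = generate_ctq_profile(np.full(200, -8.0), rng)
        assert (prof.to_numpy() == 5).mean() > 0.95

    def test_higher_latent_gives_stochastically_higher_scores(self, default_config, ctq_multiplier, rng):
        lo = generate_ctq_profile(np.full(2000, -1.0), rng, default_config, ctq_multiplier)
        hi = generate_ctq_profile(np.full(2000, 1.5), rng, default_config, ctq_multiplier)
        assert (hi.mean() > lo.mean()).all()

    def test_calibrated_prevalence_recovered(self, default_config, ctq_multiplier, rng):
        """Monte-Carlo check of the generator's own calibration routine."""
        prof = draw_ctq_profiles(default_config, 10_000, rng, ctq_multiplier)
        frac = classify_dichotomous(prof).mean()
        assert frac == pytest.approx(default_config.prevalence, abs=0.02)


class TestRatings:
    def test_contingency_scale_and_absence_at_habituation(self, rng):
        r = generate_ratings(SimulationConfig(), 50, rng)
        cont = r[r["rating_type"] == "contingency"]
        assert cont["value"].isin(range(0, 101, 10)).all()
        assert not (cont["timepoint"] == "post_habituation").any()
        likert = r[r["rating_type"] != "contingency"]["value"]
        assert likert.between(1, 9).all()

    def test_zero_noise_forces_cs_ordering_everywhere(self, rng):
        cfg = replace(SimulationConfig(), rating_noise_sd=0.0,
                      contingency_noise_sd=0.0)
        r = generate_ratings(cfg, 20, rng)
        piv = r[r["phase"] != "habituation"].pivot_table(
            index=["participant", "timepoint", "rating_type"],
            columns="stimulus", values="value", observed=True)
        arous = piv.xs("arousal", level="rating_type")
        assert (arous["CS+"] >= arous["CS-"]).all()
        cont = piv.xs("contingency", level="rating_type")
        assert (cont["CS+"] >= cont["CS-"]).all()


class TestCohort:
    def test_deterministic_under_fixed_seed(self, default_config, ctq_multiplier):
        cfg = replace(default_config, n=40)
        a = generate_cohort(cfg, seed=3, ctq_multiplier=ctq_multiplier)
        b = generate_cohort(cfg, seed=3, ctq_multiplier=ctq_multiplier)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        np.testing.assert_array_equal(a.latent_amplitudes, b.latent_amplitudes)
        pd.testing.assert_frame_equal(a.ratings, b.ratings)

    def test_prevalence_binomial_and_ids_unique(self, default_config, ctq_multiplier):
        cfg = replace(default_config, n=100)
        c = generate_cohort(cfg, seed=1, ctq_multiplier=ctq_multiplier)
        k = c.participants["exposed_true"].sum()
        assert 3 <= k <= 30  # ~Binomial(100, 0.14)
        assert c.participants["participant"].is_unique

    def test_assigned_status_matches_ctq_classification(self, small_cohort):
        prof = small_cohort.participants[list(SUBSCALES)]
        flags = classify_dichotomous(prof)
        assert (flags.to_numpy() == small_cohort.participants["exposed_true"].to_numpy()).all()

    def test_stai_group_shift_recovered_at_large_n(self, default_config, ctq_multiplier):
        cfg = replace(default_config, n=10_000)
        c = generate_cohort(cfg, seed=2, ratings=False, ctq_multiplier=ctq_multiplier)
        e = c.participants["exposed_true"]
        d = cohens_d(c.participants.loc[e, "stai_t"], c.participants.loc[~e, "stai_t"])
        assert d == pytest.approx(0.58, abs=0.05)

    def test_zero_prevalence_gives_empty_group_error_downstream(self, ctq_multiplier):
        from fearcond.pipeline import run_questionnaire_analysis

        cfg = replace(SimulationConfig(), n=30, prevalence=0.0)
        c = generate_cohort(cfg, seed=4, ratings=False, ctq_multiplier=ctq_multiplier)
        parts = c.participants.set_index("participant")
        with pytest.raises(ValueError, match="empty group"):
            run_questionnaire_analysis(parts, parts["exposed_true"])
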