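"""Simulation experiments validating the statistical battery.

These routines are the package's own calibration and power checks: type-I
error of the two-sample tests under a common-normal null, the fraction of
significant main-analysis tests when the generator injects no group effect,
and recovery of the injected CS+ attenuation effect across many cohorts.
"""

from __future__ import annotations

import numpy as np

from . import stats as st
from .adversity import classify_dichotomous
from .outcomes import build_outcome_set
from .pipeline import run_main_analysis, score_cohort
from .synthetic import (
    SimulationConfig,
    calibrate_ctq_multiplier,
    generate_cohort,
    injected_effect_d,
)

__all__ = [
    "null_rejection_rates",
    "pipeline_null_fraction",
    "recover_discrimination_effect",
]


def null_rejection_rates(n_reps: int = 10_000, n_per_group: int = 30,
                         seed: int = 0, trim: float = 0.2) -> dict[str, float]:
    """Empirical two-tailed rejection rates at alpha=.05 for Welch's t and
    Yuen's trimmed t when both groups are drawn from the same normal."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    rej = {"welch": 0, "yuen": 0, "student": 0}
    for _ in range(n_reps):
        a, b = rng.normal(size=(2, n_per_group))
        if st.welch_t(a, b).p < st.ALPHA:
            rej["welch"] += 1
        if st.student_t_ind(a, b).p < st.ALPHA:
            rej["student"] += 1
        if st.yuen_t(a, b, trim=trim).p < st.ALPHA:
            rej["yuen"] += 1
    return {k: v / n_reps for k, v in rej.items()}


def pipeline_null_fraction(n_seeds: int = 500,
                           config: SimulationConfig | None = None,
                           seed: int = 0) -> dict[str, float]:
    """Fraction of significant main-analysis tests over simulated cohorts
    with every injected group effect removed (exposure-null calibration)."""
    cfg = (config or SimulationConfig()).null()
    mult = calibrate_ctq_multiplier(cfg)
    n_sig = n_tot = 0
    base = np.random.SeedSequence([int(seed), 23]).generate_state(n_seeds) % (2**31)
    for s in base:
        cohort = generate_cohort(cfg, seed=int(s), ctq_multiplier=mult)
        amp = score_cohort(cohort)
        outcomes = build_outcome_set(amp, cohort.ratings)
        exposed = classify_dichotomous(
            cohort.participants.set_index("participant"))
        main, _ = run_main_analysis(outcomes, exposed)
        n_sig += int((main["p"] < st.ALPHA).sum())
        n_tot += len(main)
    return {"fraction_significant": n_sig / n_tot, "n_tests": n_tot,
            "n_seeds": n_seeds}


def recover_discrimination_effect(n_cohorts: int = 200,
                                  config: SimulationConfig | None = None,
                                  seed: int = 0,
                                  reference_n: int = 200_000) -> dict[str, float]:
    """Recover the injected exposed-vs-unexposed effect over many cohorts.

    Returns the mean and SD of the per-cohort Cohen's d for transformed
    acquisition CS discrimination, the fraction of cohorts recovering the
    injected (negative) sign, and the generator's own large-sample reference
    value of the injected d with its Monte-Carlo SE.
    """
    cfg = config or SimulationConfig()
    mult = calibrate_ctq_multiplier(cfg)
    base = np.random.SeedSequence([int(seed), 31]).generate_state(n_cohorts) % (2**31)
    ds = []
    for s in base:
        cohort = generate_cohort(cfg, seed=int(s), ratings=False,
                                 ctq_multiplier=mult)
        amp = score_cohort(cohort)
        outcomes = build_outcome_set(amp, None)
        scr = outcomes.set_index("participant")
        exposed = classify_dichotomous(
            cohort.participants.set_index("participant")).reindex(scr.index)
        vals = scr["cs_disc_acq"]
        ds.append(st.cohens_d(vals[exposed], vals[~exposed]))
    ds = np.asarray(ds)
    ref = injected_effect_d(cfg, n=reference_n,
                            seed=int(np.random.SeedSequence([int(seed), 37])
                                     .generate_state(1)[0] % (2**31)))
    return {
        "mean_d": float(ds.mean()),
        "sd_d": float(ds.std(ddof=1)),
        "se_mean_d": float(ds.std(ddof=1) / np.sqrt(len(ds))),
        "sign_recovery_rate": float((ds < 0).mean()),
        "injected_d": ref["cs_disc_acq"],
        "injected_d_se": ref["cs_disc_acq_se"],
        "n_cohorts": n_cohorts,
    }
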