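"""Derive the three conditioning outcomes per participant and measure.

CS discrimination (CS+ minus CS- responding), the linear deviation score
(gradient's departure from linearity) and general reactivity, for SCRs and
each rating type.
"""

from dataclasses import replace

from fearcond import SimulationConfig, build_outcome_set, generate_cohort
from fearcond.pipeline import score_cohort

cfg = replace(SimulationConfig(), n=100)
cohort = generate_cohort(cfg, seed=3)
amplitudes = score_cohort(cohort)  # amplitude mode: latent amps -> criterion
outcomes = build_outcome_set(amplitudes, cohort.ratings)

print(outcomes.head(8).to_string(index=False))
means = outcomes.groupby("measure")[["cs_disc_acq", "cs_disc_gen", "lds",
                                     "reactivity"]].mean()
print("\ncohort means per measure:")
print(means.round(3).to_string())
print("\npositive SCR cs_disc_acq = stronger responding to the danger cue; "
      "positive lds = gradient bends above the linear interpolation.")
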