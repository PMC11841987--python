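"""Simulate a small fear-conditioning cohort and inspect its structure.

Generates 50 participants (~14% exposed to childhood adversity), each with
a habituation/acquisition/generalization trial schedule, latent per-trial
SCR amplitudes, CTQ subscale scores, ratings and questionnaire totals.
"""

from dataclasses import replace

from fearcond import SimulationConfig, generate_cohort

cfg = replace(SimulationConfig(), n=50)
cohort = generate_cohort(cfg, seed=1)

print("trial schedule (first rows):")
print(cohort.schedule.head(6).to_string(index=False))
print(f"\n{len(cohort.schedule)} trials per participant; "
      f"{cohort.participants['exposed_true'].sum()} of {cfg.n} exposed")
print("\nparticipant table (first rows):")
print(cohort.participants.head(3).to_string(index=False))
# exposed participants carry elevated CTQ scores by construction: their
# profiles are sampled conditional on crossing at least one moderate cut-off
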