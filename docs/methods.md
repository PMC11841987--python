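# Methods notes

## Scope and design

The package implements a complete fear-conditioning analysis chain for
studies of childhood-adversity exposure: synthetic cohort generation,
skin-conductance preprocessing and trough-to-peak (TTP) scoring, derived
conditioning outcomes, Childhood Trauma Questionnaire (CTQ) exposure
operationalizations, and the statistical battery comparing exposed and
unexposed participants. Because raw participant data of such studies are
not redistributable, the synthetic-data generator is a first-class,
tested component: it defines the statistical structure every downstream
stage is validated against.

## SCR scoring

* **Filtering.** Zero-phase (forward-backward) Butterworth low-pass at
  1 Hz plus an IIR notch at 50 Hz. The literature names only the cut-off
  frequencies, so the filter family and order are configuration
  parameters; the default is a 4th-order low-pass and a Q=30 notch.
  Zero-phase filtering of a clean event-locked waveform slightly biases
  the TTP amplitude (ringing ahead of the response onset and passband
  attenuation; ≤ ~3% for the default waveform — quantified in the test
  suite). This is irrelevant for group comparisons (it applies to all
  trials alike) but matters for exact round-trip checks, which therefore
  score unfiltered signals (with all noise sources disabled there is
  nothing to remove).
* **TTP.** The amplitude is the largest peak-minus-trough difference with
  the trough in the 900–4000 ms and the peak in the 2000–6000 ms
  post-onset window, peak strictly after trough; ties resolve to the
  earliest peak. The implementation uses a running-minimum formulation and
  is tested for exact equality against an exhaustive pair search.
  Amplitudes below the 0.02 µS criterion are set to exactly 0 and kept as
  non-response rows.
* **Transform.** `log10(1 + amp)` then division by the participant's
  maximum log amplitude across *all* scored trials of all phases (a single
  participant-level scale, consistent with defining general reactivity
  across phases). The log dialect handles exact zeros; the base is
  configurable. All-zero participants map to all-zero transformed values.
  Range correction is idempotent and bounds values in [0, 1].
* **Split-half reliability.** Odd/even (default) or first/second-half
  split of per-participant trials, Pearson correlation of the half means
  across participants, Spearman–Brown corrected (r_sb = 2r/(1+r)).

## Outcomes

CS discrimination excludes the first acquisition trial *of each CS*
(no learning can have occurred on a first presentation under delay
conditioning); a configuration switch restricts the exclusion to the
single chronologically first trial instead. The LDS uses all
generalization-phase trials with no exclusion. General reactivity uses raw
µS amplitudes for SCR and native scales for ratings (valence inverted
first so that higher = more aversive across measures). Rating outcomes
average over the phase's rating timepoints (mid- and post-phase); there
are no per-trial ratings.

## Exposure operationalizations

Moderate CTQ cut-offs (EA 13, PA 10, SA 8, EN 15, PN 10) are bundled;
low/severe cut-offs come from the CTQ manual and are deliberately *not*
bundled — they are mandatory inputs for the severity-group model, which
assigns each participant the maximum band reached on any subscale
(paralleling the "any subscale" dichotomization; a band-of-the-sum rule
would be a different model). Abuse = EA+PA+SA, neglect = EN+PN.

## Statistical battery

* Welch's t is used when a median-centred Levene pretest rejects variance
  homogeneity, Student's t otherwise; exploratory regressions switch to
  HC3 robust standard errors on a Breusch–Pagan rejection. The pretests
  themselves are conventional choices and configurable.
* Cohen's d uses the pooled SD; its CI uses the normal approximation
  `d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`.
* Yuen's trimmed-means t (default trim 0.2) uses Winsorized variances with
  the classical small-sample degrees of freedom. The explanatory effect
  size ξ is `√(Var(fitted trimmed means) / σ̂²_tot)`, where σ̂²_tot is the
  pooled Winsorized variance rescaled by the Winsorized variance of a
  standard normal at the same trim (≈0.4121 at 20%), clipped to [0, 1];
  benchmarks 0.10/0.30/0.50 for small/medium/large.
* The 2×2 split-plot ANOVA is computed from the classical sums-of-squares
  decomposition (verified complete on every input and cross-checked
  against an independent implementation in the test suite).
* Theory comparison converts exploratory effects to |d| (t-type:
  |t|√(1/n₁+1/n₂); F(1,df): 2√(F/df); r: 2|r|/√(1−r²)) and checks them
  against the closed main-analysis CI; F tests with numerator df > 1
  (the severity-group ANOVA) are flagged as not convertible rather than
  silently transformed. Exploratory blocks are deliberately not corrected
  for multiplicity; post-hoc families use Holm.

## Synthetic cohorts

* **Trial schedule.** Habituation (CS+/CS− only), acquisition,
  generalization (CS+, CS−, GS1–GS4 with GS1 most similar to the CS+).
  Defaults: 4 habituation and 8 acquisition trials per CS, 50%
  reinforcement of CS+ trials, 4 generalization trials per stimulus, 12 s
  onset spacing. These are package defaults (the source paradigms vary),
  all configurable. The US flag is kept for schedule realism; no US
  artifact is rendered into the signal.
* **Amplitude model.** Per-trial latent amplitudes are log-normal around a
  phase×stimulus median (habituation 0.30 µS; acquisition CS+ 0.50 / CS−
  0.25; generalization linear in similarity from 0.45 to 0.23), with a
  participant-level log-scale (SD 0.4), trial-level log noise (SD 0.5) and
  10% non-responses. Log-normality makes amplitudes non-negative and
  right-skewed like empirical SCRs, and makes the log transform
  meaningful.
* **Exposure effects.** Exposed participants' CS+ amplitudes in
  acquisition/generalization are multiplied by 0.9312 and all amplitudes
  by 0.956. These factors were calibrated once by large-scale Monte Carlo
  so the induced effects are d ≈ −0.18 on transformed acquisition CS
  discrimination and d ≈ −0.16 on raw general reactivity — the magnitudes
  reported for community samples of this kind. `injected_effect_d`
  recomputes the implied effects for any configuration and serves as the
  generator's own reference in recovery tests. Ratings carry no injected
  group effect (consistent with the empirical pattern that group effects
  appear in SCRs but not ratings).
* **CTQ.** Subscale scores (integers 5–25) arise by inverse-CDF mapping of
  correlated Gaussian latents through geometric-tail marginals whose
  exceedance probability at the moderate cut-off is set exactly; a common
  multiplier on the per-subscale exceedance rates is calibrated
  (Gauss–Hermite quadrature + root finding) so the fraction of profiles
  with ≥ 1 subscale at cut-off equals the configured prevalence (default
  14%). Cohort generation assigns true exposure status Bernoulli
  (prevalence) and rejection-samples profiles consistent with the assigned
  status, so the CTQ classification exactly recovers the generating flag.
  The abuse/neglect domain latents correlate 0.94 by default, emulating
  the strong co-occurrence (and resulting VIFs near 8–9) seen empirically;
  the correlation of the *discretized composite scores* is attenuated
  relative to this latent value.
* **Questionnaires.** STAI-T / ADS-K / age are drawn per group with the
  published group means and SDs (shifts d ≈ 0.58 / 0.35 / 0.29); age uses
  a shifted log-normal (≥ 18) matching the group moments; totals are
  rounded and clipped to instrument ranges (a ≤ 2% distortion of the
  injected d, covered by the recovery tolerance).
* **Signal rendering.** signal = 2 µS baseline + optional drift + Σ
  event-locked biexponential responses (unit-peak normalized; latency
  1.5 s, rise 0.75 s, decay 2.5 s → peak ≈ 2.8 s post onset, inside the
  scoring window) + Gaussian noise (SD 0.01 µS) + 50 Hz mains (0.005 µS);
  1000 Hz default, ≥ 200 Hz required when mains is on.

## Two simulation modes and problem sizes

`amplitude` mode feeds latent per-trial amplitudes directly to the
minimum-response criterion; `signal` mode renders continuous recordings
and scores them through the full filter + TTP path. The modes agree by
construction (the round-trip tests verify recovery within 1% with noise
disabled, exactly at the criterion's resolution). Statistical calibration
experiments (type-I error, pipeline null across hundreds of cohorts of
n = 1402, effect recovery across 200 cohorts) run in amplitude mode —
rendering hundreds of thousands of 1000-Hz recordings would add nothing to
the quantities being checked; the scoring path is validated separately.
Chosen sizes: 10,000 replicates for the two-sample null, 500 cohort seeds
for the pipeline null, 200 cohorts for effect recovery, 1000 random cases
for the TTP oracle.

## What the synthetic data do not emulate

Tonic drifts and spontaneous (non-event-locked) fluctuations, US-evoked
responses, habituation/sensitization trends within phases, missing data
and artifacts, site effects, and item-level CTQ structure (subscale scores
are generated directly). Passing tests therefore show that the *pipeline*
is correct and calibrated under the stated model, not that the model
captures every feature of empirical electrodermal data.

## Known limitations

* The severity-group banding rule (max band across subscales) is one of
  several defensible readings; the alternative sum-band rule is not
  implemented.
* Robust mixed ANOVA for trimmed means is limited to the 2×2 case via
  Yuen-type contrasts; no general split-plot robust ANOVA.
* The normal-approximation CI for d is slightly liberal at small n; a
  noncentral-t CI is not implemented.
* `signal` mode is O(n · duration · sampling rate) and intended for
  moderate cohorts; large-scale experiments should use amplitude mode.
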