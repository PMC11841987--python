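"""Synthetic fear-conditioning cohorts with the structure the analyses assume.

A simulated participant carries: a trial schedule (habituation, acquisition,
generalization; stimuli CS+, CS-, GS1-GS4 ordered by similarity to the CS+),
latent per-trial SCR amplitudes from a log-normal model, optionally a
rendered continuous skin-conductance trace built from a biexponential
response waveform, CTQ subscale scores tied to a latent severity, ratings
(valence, arousal, US contingency), and STAI-T / ADS-K / age / sex values.

Exposure to childhood adversity is injected in two ways: exposed
participants' CS+ amplitudes during acquisition and generalization are
attenuated multiplicatively (blunted threat responding) and all their
amplitudes are attenuated by a general-reactivity factor. Default factors
are calibrated so that the exposed-vs-unexposed effect on the transformed
acquisition CS discrimination is Cohen's d ~= 0.18 and on raw general
reactivity d ~= 0.16, the magnitudes the analysis battery is built to
detect. Ratings carry no injected group effect.

Two simulation modes keep the statistics testable at scale: ``amplitude``
mode hands the latent per-trial amplitudes directly to the scoring
criterion (no waveform rendering), while ``signal`` mode renders continuous
recordings for the full filtering + trough-to-peak path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .adversity import MODERATE_CUTOFFS, SUBSCALES
from .scoring import ScoringConfig, SkinConductanceRecording, apply_minimum_criterion

__all__ = [
    "SimulationConfig",
    "CohortDataset",
    "scr_waveform",
    "generate_trial_schedule",
    "generate_scr_timeseries",
    "generate_ctq_profile",
    "generate_ratings",
    "generate_cohort",
    "ctq_exceedance_probs",
    "calibrate_ctq_multiplier",
    "STIMULI",
    "SIMILARITY",
]

STIMULI = ("CS+", "GS1", "GS2", "GS3", "GS4", "CS-")
#: perceptual similarity to the CS+ (GS1 most similar, GS4 least)
SIMILARITY: dict[str, float] = {
    "CS+": 1.0, "GS1": 0.8, "GS2": 0.6, "GS3": 0.4, "GS4": 0.2, "CS-": 0.0,
}
PHASES = ("habituation", "acquisition", "generalization")
RATING_TIMEPOINTS = (
    ("post_habituation", "habituation"),
    ("mid_acquisition", "acquisition"),
    ("post_acquisition", "acquisition"),
    ("mid_generalization", "generalization"),
    ("post_generalization", "generalization"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (defaults are the study conditions)."""

    n: int = 1402
    prevalence: float = 0.14
    sampling_rate: float = 1000.0

    # paradigm layout (trial counts are configurable defaults, not study facts)
    n_habituation_per_cs: int = 4
    n_acquisition_per_cs: int = 8
    reinforcement_rate: float = 0.5
    n_generalization_per_stimulus: int = 4
    iti_s: float = 12.0
    lead_in_s: float = 10.0
    stimulus_duration_s: float = 6.0

    # SCR amplitude model (median amplitudes in uS, unexposed)
    amp_habituation: float = 0.30
    amp_cs_plus_acq: float = 0.50
    amp_cs_minus_acq: float = 0.25
    amp_cs_plus_gen: float = 0.45
    amp_cs_minus_gen: float = 0.23
    gradient_slope: float = 1.0
    participant_log_sd: float = 0.4
    trial_log_sd: float = 0.5
    nonresponse_prob: float = 0.10
    # attenuation factors for exposed participants; defaults calibrated by
    # Monte-Carlo so the induced effects are d ~= 0.18 (CS discrimination,
    # transformed scale) and d ~= 0.16 (raw general reactivity)
    csplus_attenuation: float = 0.9312
    reactivity_attenuation: float = 0.956

    # continuous-signal rendering
    baseline_us: float = 2.0
    drift_us_per_s: float = 0.0
    noise_sd_us: float = 0.01
    mains_amplitude_us: float = 0.005
    mains_hz: float = 50.0
    waveform_latency_s: float = 1.5
    waveform_rise_s: float = 0.75
    waveform_decay_s: float = 2.5

    # ratings model (latent means before discretization)
    rating_noise_sd: float = 1.0
    contingency_noise_sd: float = 12.0
    arousal_base: float = 4.0
    arousal_gain: float = 3.0
    valence_base: float = 6.0
    valence_gain: float = 3.0
    contingency_base: float = 20.0
    contingency_gain: float = 60.0

    # CTQ latent-severity model
    ctq_latent_loading: float = 0.75
    abuse_neglect_corr: float = 0.94
    ctq_base_exceedance: Mapping[str, float] = field(
        default_factory=lambda: {"ea": 0.09, "pa": 0.05, "sa": 0.055, "en": 0.095, "pn": 0.07}
    )

    # questionnaire group parameters: (unexposed mean, unexposed sd,
    # exposed mean, exposed sd)
    stai_t: tuple[float, float, float, float] = (34.04, 7.83, 38.73, 9.52)
    ads_k: tuple[float, float, float, float] = (6.69, 5.70, 8.71, 6.31)
    age: tuple[float, float, float, float] = (25.14, 5.50, 26.80, 6.99)
    female_prob: float = 0.61

    def __post_init__(self):
        if not 0 <= self.prevalence < 1:
            raise ValueError("prevalence must lie in [0, 1)")
        for name in ("csplus_attenuation", "reactivity_attenuation"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if min(self.n_habituation_per_cs, self.n_acquisition_per_cs,
               self.n_generalization_per_stimulus) < 2:
            raise ValueError("need at least 2 trials per stimulus per phase")
        if self.iti_s < 6.0:
            raise ValueError("inter-trial spacing must cover the 6 s scoring window")
        if self.mains_amplitude_us > 0 and self.sampling_rate < 200:
            raise ValueError("sampling rate >= 200 Hz required to represent mains noise")

    def null(self) -> "SimulationConfig":
        """Copy with all injected group effects removed (for calibration runs)."""
        q = {
            "csplus_attenuation": 1.0,
            "reactivity_attenuation": 1.0,
            "stai_t": (self.stai_t[0], self.stai_t[1], self.stai_t[0], self.stai_t[1]),
            "ads_k": (self.ads_k[0], self.ads_k[1], self.ads_k[0], self.ads_k[1]),
            "age": (self.age[0], self.age[1], self.age[0], self.age[1]),
        }
        return replace(self, **q)


# --------------------------------------------------------------------------
# SCR waveform and continuous signal
# --------------------------------------------------------------------------

def scr_waveform(t, amplitude: float, latency: float = 1.5,
                 rise: float = 0.75, decay: float = 2.5) -> np.ndarray:
    """Biexponential SCR shape, unit-peak normalized then scaled by amplitude.

    ``t`` is time since stimulus onset in seconds. Zero at and before
    ``latency``; single-peaked with the peak at
    latency + ln(decay/rise) * rise*decay / (decay - rise).
    """
    if rise <= 0 or decay <= 0:
        raise ValueError("time constants must be positive")
    if decay <= rise:
        raise ValueError("decay constant must exceed rise constant")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(t, dtype=float)
    u = t - latency
    shape = np.where(u > 0, np.exp(-np.maximum(u, 0) / decay) - np.exp(-np.maximum(u, 0) / rise), 0.0)
    u_peak = math.log(decay / rise) * rise * decay / (decay - rise)
    peak = math.exp(-u_peak / decay) - math.exp(-u_peak / rise)
    return amplitude * shape / peak


def generate_trial_schedule(config: SimulationConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Ordered event table: onset, duration, trial_type, phase, trial_index, us.

    Phases run habituation -> acquisition -> generalization; trial_index is
    the 1-based occurrence of the stimulus within its phase; the US co-occurs
    with a random ``reinforcement_rate`` subset of CS+ trials in acquisition
    and generalization.
    """
    rows: list[tuple[str, str, bool]] = []

    def block(stims: list[str], phase: str, reinforce: bool):
        order = rng.permutation(len(stims))
        seq = [stims[i] for i in order]
        csp = [i for i, s in enumerate(seq) if s == "CS+"]
        n_us = int(round(config.reinforcement_rate * len(csp))) if reinforce else 0
        us_at = set(rng.choice(csp, size=n_us, replace=False)) if n_us else set()
        for i, s in enumerate(seq):
            rows.append((phase, s, i in us_at))

    block(["CS+", "CS-"] * config.n_habituation_per_cs, "habituation", reinforce=False)
    block(["CS+", "CS-"] * config.n_acquisition_per_cs, "acquisition", reinforce=True)
    block(list(STIMULI) * config.n_generalization_per_stimulus, "generalization",
          reinforce=True)

    df = pd.DataFrame(rows, columns=["phase", "trial_type", "us"])
    df["onset"] = config.lead_in_s + np.arange(len(df)) * config.iti_s
    df["duration"] = config.stimulus_duration_s
    df["trial_index"] = df.groupby(["phase", "trial_type"]).cumcount() + 1
    return df[["onset", "duration", "trial_type", "phase", "trial_index", "us"]]


def _mean_amplitude(config: SimulationConfig, phase: np.ndarray,
                    stimulus: np.ndarray, exposed: bool) -> np.ndarray:
    """Median trial amplitude per (phase, stimulus) with exposure attenuation."""
    sim = np.array([SIMILARITY[s] for s in stimulus])
    amp = np.empty(len(phase), dtype=float)
    hab = phase == "habituation"
    acq = phase == "acquisition"
    gen = phase == "generalization"
    amp[hab] = config.amp_habituation
    amp[acq] = np.where(stimulus[acq] == "CS+", config.amp_cs_plus_acq,
                        config.amp_cs_minus_acq)
    span = config.amp_cs_plus_gen - config.amp_cs_minus_gen
    amp[gen] = config.amp_cs_minus_gen + config.gradient_slope * span * sim[gen]
    if exposed:
        is_csp = (stimulus == "CS+") & ~hab
        amp = np.where(is_csp, amp * config.csplus_attenuation, amp)
        amp = amp * config.reactivity_attenuation
    return amp


def _latent_amplitudes(config: SimulationConfig, schedule: pd.DataFrame,
                       exposed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n_participants, n_trials) latent amplitude matrix in uS."""
    phase = schedule["phase"].to_numpy()
    stim = schedule["trial_type"].to_numpy()
    mu = np.stack([
        _mean_amplitude(config, phase, stim, exposed=False),
        _mean_amplitude(config, phase, stim, exposed=True),
    ])
    n, t = len(exposed), len(schedule)
    g = rng.normal(0.0, config.participant_log_sd, size=(n, 1))
    eps = rng.normal(0.0, config.trial_log_sd, size=(n, t))
    amps = mu[exposed.astype(int)] * np.exp(g + eps)
    if config.nonresponse_prob > 0:
        amps[rng.random((n, t)) < config.nonresponse_prob] = 0.0
    return amps


def generate_scr_timeseries(amplitudes: np.ndarray, schedule: pd.DataFrame,
                            config: SimulationConfig, rng: np.random.Generator,
                            participant: str = "sub-001") -> SkinConductanceRecording:
    """Render a continuous conductance trace from per-trial latent amplitudes.

    signal = tonic baseline + linear drift + sum of event-locked biexponential
    responses + Gaussian noise + mains sinusoid.
    """
    if config.mains_amplitude_us > 0 and config.sampling_rate < 200:
        raise ValueError("sampling rate >= 200 Hz required to represent mains noise")
    fs = config.sampling_rate
    tail_s = config.waveform_latency_s + 8.0
    n_samp = int(round((schedule["onset"].max() + tail_s) * fs))
    t = np.arange(n_samp) / fs
    x = np.full(n_samp, config.baseline_us) + config.drift_us_per_s * t
    win = int(round((tail_s + 4.0) * fs))
    tw = np.arange(win) / fs
    for onset, amp in zip(schedule["onset"].to_numpy(), np.asarray(amplitudes, float)):
        if amp <= 0:
            continue
        i0 = int(round(onset * fs))
        seg = scr_waveform(tw, amp, config.waveform_latency_s,
                           config.waveform_rise_s, config.waveform_decay_s)
        i1 = min(i0 + win, n_samp)
        x[i0:i1] += seg[: i1 - i0]
    if config.noise_sd_us > 0:
        x += rng.normal(0.0, config.noise_sd_us, size=n_samp)
    if config.mains_amplitude_us > 0:
        x += config.mains_amplitude_us * np.sin(2 * np.pi * config.mains_hz * t)
    return SkinConductanceRecording(participant=participant, sampling_rate=fs, samples=x)


# --------------------------------------------------------------------------
# CTQ generation
# --------------------------------------------------------------------------

def _marginal_pmf(cutoff: int, exceedance: float) -> np.ndarray:
    """Geometric-decay pmf on scores 5..25 whose tail at ``cutoff`` equals
    ``exceedance`` exactly."""
    j_star = cutoff - 5
    js = np.arange(21)

    def tail(logr: float) -> float:
        w = np.exp(js * logr)
        return float(w[j_star:].sum() / w.sum()) - exceedance

    lo, hi = -8.0, 8.0
    logr = optimize.brentq(tail, lo, hi, xtol=1e-12)
    w = np.exp(js * logr)
    return w / w.sum()


def ctq_exceedance_probs(config: SimulationConfig, multiplier: float) -> dict[str, float]:
    return {s: min(0.9, multiplier * config.ctq_base_exceedance[s]) for s in SUBSCALES}


def _ctq_tables(config: SimulationConfig, multiplier: float):
    """Per-subscale (pmf cdf, latent threshold) for the given multiplier."""
    probs = ctq_exceedance_probs(config, multiplier)
    cdfs, zstars = {}, {}
    for s in SUBSCALES:
        pmf = _marginal_pmf(MODERATE_CUTOFFS[s], probs[s])
        cdf = np.cumsum(pmf)
        cdfs[s] = cdf
        zstars[s] = sps.norm.ppf(cdf[MODERATE_CUTOFFS[s] - 5 - 1])
    return cdfs, zstars


def _prob_unexposed(config: SimulationConfig, multiplier: float, nodes: int = 48) -> float:
    """P(no subscale reaches its cut-off) under the latent model (Gauss-Hermite)."""
    _, zstars = _ctq_tables(config, multiplier)
    lam = config.ctq_latent_loading
    rho = config.abuse_neglect_corr
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    wn = w / w.sum()
    # bivariate domain latents via Cholesky of [[1, rho], [rho, 1]]
    la = x[:, None] * np.ones(nodes)[None, :]
    ln = rho * x[:, None] + math.sqrt(1 - rho**2) * x[None, :]
    denom = math.sqrt(1 - lam**2)
    p_none = np.ones((nodes, nodes))
    for s in SUBSCALES:
        dom = la if s in ("ea", "pa", "sa") else ln
        p_none *= sps.norm.cdf((zstars[s] - lam * dom) / denom)
    return float(np.einsum("i,j,ij->", wn, wn, p_none))


def calibrate_ctq_multiplier(config: SimulationConfig) -> float:
    """Common multiplier on the base exceedance rates so that the fraction of
    profiles with >= 1 subscale at the moderate cut-off equals the configured
    prevalence."""
    target = config.prevalence

    def f(m):
        return (1 - _prob_unexposed(config, m)) - target

    return optimize.brentq(f, 1e-4, 9.0, xtol=1e-10)


def _draw_ctq(config: SimulationConfig, multiplier: float, n: int,
              rng: np.random.Generator,
              latents: np.ndarray | None = None) -> pd.DataFrame:
    cdfs, _ = _ctq_tables(config, multiplier)
    lam = config.ctq_latent_loading
    rho = config.abuse_neglect_corr
    if latents is None:
        la = rng.normal(size=n)
        ln = rho * la + math.sqrt(1 - rho**2) * rng.normal(size=n)
    else:
        la = ln = np.asarray(latents, float)
    out = {}
    for s in SUBSCALES:
        dom = la if s in ("ea", "pa", "sa") else ln
        z = lam * dom + math.sqrt(1 - lam**2) * rng.normal(size=n)
        u = sps.norm.cdf(z)
        out[s] = 5 + np.searchsorted(cdfs[s], u, side="right").clip(0, 20)
    return pd.DataFrame(out)


def injected_effect_d(config: SimulationConfig, n: int = 200_000,
                      seed: int = 987_654) -> dict[str, float]:
    """Monte-Carlo calibration of the group effects the config injects.

    Simulates one large balanced cohort (half exposed) at the amplitude
    level and returns the implied Cohen's d (exposed minus unexposed) for
    transformed acquisition CS discrimination and raw general reactivity,
    plus the Monte-Carlo standard error of each estimate. This is the
    generator's own reference value for parameter-recovery checks.
    """
    cfg = replace(config, n=n, prevalence=0.5)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424_242]))
    sched = generate_trial_schedule(cfg, np.random.default_rng(123))
    exposed = np.arange(n) < n // 2
    amps = _latent_amplitudes(cfg, sched, exposed, rng)
    raw = apply_minimum_criterion(amps.ravel()).reshape(amps.shape)
    logged = np.log10(1 + raw)
    mx = logged.max(axis=1, keepdims=True)
    tr = np.where(mx > 0, logged / np.where(mx > 0, mx, 1.0), 0.0)
    phase = sched["phase"].to_numpy()
    stim = sched["trial_type"].to_numpy()
    ti = sched["trial_index"].to_numpy()
    acq = phase == "acquisition"
    disc = (tr[:, acq & (stim == "CS+") & (ti > 1)].mean(axis=1)
            - tr[:, acq & (stim == "CS-") & (ti > 1)].mean(axis=1))
    react = raw.mean(axis=1)

    out = {}
    for name, x in (("cs_disc_acq", disc), ("reactivity", react)):
        a, b = x[exposed], x[~exposed]
        sp = math.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                       / (len(a) + len(b) - 2))
        d = (a.mean() - b.mean()) / sp
        out[name] = float(d)
        out[f"{name}_se"] = math.sqrt(4 / n + d**2 / (2 * n))
    return out


def draw_ctq_profiles(config: SimulationConfig, n: int, rng: np.random.Generator,
                      multiplier: float | None = None) -> pd.DataFrame:
    """Unconditional CTQ profiles under the cohort's bivariate latent model."""
    if multiplier is None:
        multiplier = calibrate_ctq_multiplier(config)
    return _draw_ctq(config, multiplier, n, rng)


def generate_ctq_profile(latent_severity: float | np.ndarray,
                         rng: np.random.Generator,
                         config: SimulationConfig | None = None,
                         multiplier: float | None = None) -> pd.DataFrame:
    """CTQ subscale scores for given latent severities (higher => more severe).

    Both abuse and neglect domains share the supplied latent. Scores are
    integers in [5, 25]; the mapping is monotone in the latent.
    """
    config = config or SimulationConfig()
    if multiplier is None:
        multiplier = calibrate_ctq_multiplier(config)
    latents = np.atleast_1d(np.asarray(latent_severity, float))
    return _draw_ctq(config, multiplier, len(latents), rng, latents=latents)


def _draw_ctq_conditional(config: SimulationConfig, multiplier: float,
                          exposed: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """CTQ profiles whose dichotomous classification matches the assigned
    exposure flags (rejection sampling on the latent model)."""
    cutvec = np.array([MODERATE_CUTOFFS[s] for s in SUBSCALES])
    n = len(exposed)
    need_exp = int(exposed.sum())
    need_un = n - need_exp
    pools: dict[bool, list[pd.DataFrame]] = {True: [], False: []}
    have = {True: 0, False: 0}
    p_exp = max(config.prevalence, 1e-3)
    while have[True] < need_exp or have[False] < need_un:
        m = max(256, int(1.5 * max(
            (need_exp - have[True]) / p_exp, (need_un - have[False]) / (1 - p_exp)
        )))
        batch = _draw_ctq(config, multiplier, m, rng)
        flags = (batch.to_numpy() >= cutvec).any(axis=1)
        for val in (True, False):
            sel = batch[flags == val]
            if have[val] < (need_exp if val else need_un):
                pools[val].append(sel)
                have[val] += len(sel)
    arr = np.empty((n, len(SUBSCALES)), dtype=int)
    if need_exp:
        exp_pool = pd.concat(pools[True], ignore_index=True).iloc[:need_exp]
        arr[exposed] = exp_pool.to_numpy()
    if need_un:
        un_pool = pd.concat(pools[False], ignore_index=True).iloc[:need_un]
        arr[~exposed] = un_pool.to_numpy()
    return pd.DataFrame(arr, columns=list(SUBSCALES))


# --------------------------------------------------------------------------
# ratings
# --------------------------------------------------------------------------

def generate_ratings(config: SimulationConfig, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Tidy rating table for ``n`` participants.

    Rows: participant, timepoint, phase, stimulus, rating_type, value.
    Arousal/valence are 9-point Likert; contingency 0..100 in steps of 10 and
    absent at the post-habituation timepoint (no US occurred yet). Valence is
    stored pre-inversion (higher = more pleasant). No group effect is
    injected.
    """
    rows = []
    for tp, phase in RATING_TIMEPOINTS:
        stims = list(STIMULI) if phase == "generalization" else ["CS+", "CS-"]
        learned = phase != "habituation"
        for s in stims:
            simv = SIMILARITY[s] if learned else 0.0
            rows.append((tp, phase, s, "arousal",
                         config.arousal_base + config.arousal_gain * simv, 1.0, 9.0, 1.0))
            rows.append((tp, phase, s, "valence",
                         config.valence_base - config.valence_gain * simv, 1.0, 9.0, 1.0))
            if learned:
                rows.append((tp, phase, s, "contingency",
                             config.contingency_base + config.contingency_gain * simv,
                             0.0, 100.0, 10.0))
    meta = pd.DataFrame(
        rows, columns=["timepoint", "phase", "stimulus", "rating_type",
                       "mean", "lo", "hi", "step"],
    )
    k = len(meta)
    noise_sd = np.where(meta["rating_type"] == "contingency",
                        config.contingency_noise_sd, config.rating_noise_sd)
    vals = meta["mean"].to_numpy()[None, :] + rng.normal(size=(n, k)) * noise_sd[None, :]
    step = meta["step"].to_numpy()[None, :]
    vals = np.clip(np.round(vals / step) * step, meta["lo"].to_numpy(), meta["hi"].to_numpy())
    long = meta.drop(columns=["mean", "lo", "hi", "step"])
    long = long.loc[np.tile(long.index, n)].reset_index(drop=True)
    long["participant"] = np.repeat(np.arange(n), k)
    long["value"] = vals.ravel()
    long["inverted"] = False
    return long[["participant", "timepoint", "phase", "stimulus", "rating_type",
                 "value", "inverted"]]


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """One simulated cohort: participants, schedule, trial amplitudes, ratings."""

    config: SimulationConfig
    seed: int
    participants: pd.DataFrame
    schedule: pd.DataFrame
    latent_amplitudes: np.ndarray  # (n, n_trials), uS
    ratings: pd.DataFrame | None

    def amplitude_table(self, scoring: ScoringConfig | None = None) -> pd.DataFrame:
        """Long per-trial table with the minimum response criterion applied
        to the latent amplitudes (amplitude simulation mode)."""
        scoring = scoring or ScoringConfig()
        n, t = self.latent_amplitudes.shape
        raw = apply_minimum_criterion(self.latent_amplitudes.ravel(), scoring)
        df = pd.DataFrame(
            {
                "participant": np.repeat(self.participants["participant"].to_numpy(), t),
                "phase": np.tile(self.schedule["phase"].to_numpy(), n),
                "stimulus": np.tile(self.schedule["trial_type"].to_numpy(), n),
                "trial_index": np.tile(self.schedule["trial_index"].to_numpy(), n),
                "raw": raw,
            }
        )
        df["response"] = df["raw"] > 0
        return df

    def render_recording(self, i: int, rng: np.random.Generator | None = None) -> SkinConductanceRecording:
        """Continuous recording for participant row ``i`` (signal mode)."""
        rng = rng or np.random.default_rng(
            np.random.SeedSequence([self.seed, 7_654_321, int(i)])
        )
        return generate_scr_timeseries(
            self.latent_amplitudes[i], self.schedule, self.config, rng,
            participant=str(self.participants["participant"].iloc[i]),
        )


def generate_cohort(config: SimulationConfig, seed: int = 0,
                    ratings: bool = True,
                    ctq_multiplier: float | None = None) -> CohortDataset:
    """Simulate a full cohort; deterministic in (config, seed)."""
    ss = np.random.SeedSequence([int(seed), 20_260_930])
    r_status, r_sched, r_amp, r_ctq, r_quest, r_rate = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]
    exposed = r_status.random(config.n) < config.prevalence
    schedule = generate_trial_schedule(config, r_sched)
    amps = _latent_amplitudes(config, schedule, exposed, r_amp)

    if ctq_multiplier is None:
        ctq_multiplier = calibrate_ctq_multiplier(config)
    ctq = _draw_ctq_conditional(config, ctq_multiplier, exposed, r_ctq)

    def quest(params):
        m0, s0, m1, s1 = params
        mean = np.where(exposed, m1, m0)
        sd = np.where(exposed, s1, s0)
        return mean + sd * r_quest.normal(size=config.n)

    stai = np.clip(np.round(quest(config.stai_t)), 20, 80)
    ads = np.clip(np.round(quest(config.ads_k)), 0, 45)
    # age: shifted lognormal (>= 18) matching the group means/SDs exactly
    ages = np.empty(config.n)
    for flag, (m, s) in ((False, config.age[:2]), (True, config.age[2:])):
        mask = exposed == flag
        mu_ln = m - 18.0
        sigma2 = math.log(1 + (s / mu_ln) ** 2)
        mu = math.log(mu_ln) - sigma2 / 2
        ages[mask] = 18.0 + np.exp(mu + math.sqrt(sigma2) * r_quest.normal(size=mask.sum()))
    female = r_quest.random(config.n) < config.female_prob

    participants = pd.DataFrame(
        {
            "participant": [f"sub-{i + 1:04d}" for i in range(config.n)],
            "exposed_true": exposed,
            "stai_t": stai,
            "ads_k": ads,
            "age": ages,
            "female": female,
            **{s: ctq[s].to_numpy() for s in SUBSCALES},
        }
    )
    rating_table = None
    if ratings:
        rating_table = generate_ratings(config, config.n, r_rate)
        rating_table["participant"] = participants["participant"].to_numpy()[
            rating_table["participant"].to_numpy()
        ]
    return CohortDataset(
        config=config,
        seed=int(seed),
        participants=participants,
        schedule=schedule,
        latent_amplitudes=amps,
        ratings=rating_table,
    )
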