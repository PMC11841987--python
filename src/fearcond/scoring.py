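"""Event-related scoring of continuous skin-conductance recordings.

The raw electrodermal signal is low-pass filtered (1 Hz high cut-off) and
notch filtered (50 Hz mains), then each trial is scored with the
trough-to-peak (TTP) approach: the response amplitude is the largest
positive difference between a peak inside the peak window (2000-6000 ms
after stimulus onset) and a preceding trough inside the onset window
(900-4000 ms). Amplitudes below the 0.02 uS minimum response criterion are
scored as exactly zero (non-responses are retained, not excluded).

Scored amplitudes are transformed by log10(1 + x) followed by range
correction: division by the participant's maximum log amplitude across all
scored trials, putting every responder on a [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig

__all__ = [
    "SkinConductanceRecording",
    "ScoringConfig",
    "preprocess_signal",
    "score_trial_ttp",
    "score_recording",
    "apply_minimum_criterion",
    "transform_amplitudes",
    "split_half_reliability",
]


@dataclass
class SkinConductanceRecording:
    """One participant's continuous conductance trace in microsiemens."""

    participant: str
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def time(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class ScoringConfig:
    """Windows in ms after stimulus onset; filter cut-offs in Hz."""

    onset_window_ms: tuple[float, float] = (900.0, 4000.0)
    peak_window_ms: tuple[float, float] = (2000.0, 6000.0)
    min_response_us: float = 0.02
    lowpass_hz: float = 1.0
    notch_hz: float | None = 50.0
    filter_order: int = 4
    notch_q: float = 30.0
    log_base: float = 10.0

    def __post_init__(self):
        if self.onset_window_ms[0] >= self.onset_window_ms[1]:
            raise ValueError("onset window start must precede its end")
        if self.peak_window_ms[1] <= self.onset_window_ms[0]:
            raise ValueError("peak window must extend past the onset-window start")
        if self.min_response_us < 0:
            raise ValueError("minimum response criterion must be >= 0")


def preprocess_signal(recording: SkinConductanceRecording,
                      config: ScoringConfig | None = None) -> SkinConductanceRecording:
    """Zero-phase low-pass + notch filtering; timing and length preserved."""
    config = config or ScoringConfig()
    fs = recording.sampling_rate
    x = recording.samples
    if config.notch_hz:
        if fs <= 2 * config.notch_hz:
            raise ValueError(
                f"sampling rate {fs} Hz too low for a {config.notch_hz} Hz notch"
            )
        b, a = spsig.iirnotch(config.notch_hz, config.notch_q, fs=fs)
        x = spsig.filtfilt(b, a, x)
    sos = spsig.butter(config.filter_order, config.lowpass_hz, btype="low",
                       fs=fs, output="sos")
    x = spsig.sosfiltfilt(sos, x)
    return replace(recording, samples=x)


def score_trial_ttp(samples: np.ndarray, sampling_rate: float, onset_s: float,
                    config: ScoringConfig | None = None,
                    label: str = "trial") -> float:
    """Trough-to-peak amplitude of one trial, floored at 0.

    Maximizes ``x[peak] - x[trough]`` over trough indices in the onset window
    and peak indices in the peak window with peak strictly after trough;
    among equal differences the earliest peak wins. Results below the
    minimum response criterion are returned as exactly 0.
    """
    config = config or ScoringConfig()
    fs = sampling_rate
    o0 = int(np.ceil(onset_s * fs + config.onset_window_ms[0] * fs / 1000))
    o1 = int(np.floor(onset_s * fs + config.onset_window_ms[1] * fs / 1000))
    p0 = int(np.ceil(onset_s * fs + config.peak_window_ms[0] * fs / 1000))
    p1 = int(np.floor(onset_s * fs + config.peak_window_ms[1] * fs / 1000))
    if p1 >= len(samples) or o0 < 0:
        raise ValueError(
            f"{label}: scoring window [{o0}, {p1}] exceeds the recording "
            f"({len(samples)} samples)"
        )
    # running minimum of the onset window up to (strictly before) each peak index
    onset_seg = samples[o0:o1 + 1]
    prefix_min = np.minimum.accumulate(onset_seg)
    peaks = np.arange(max(p0, o0 + 1), p1 + 1)
    if len(peaks) == 0:
        return 0.0
    # trough candidates for peak index k: onset-window samples with index < k
    avail = np.minimum(peaks - 1, o1) - o0  # last usable onset-window offset
    valid = avail >= 0
    if not np.any(valid):
        return 0.0
    diffs = samples[peaks[valid]] - prefix_min[avail[valid]]
    amp = float(np.max(diffs))
    if amp < config.min_response_us:
        return 0.0
    return amp


def score_recording(recording: SkinConductanceRecording, schedule: pd.DataFrame,
                    config: ScoringConfig | None = None,
                    preprocess: bool = True) -> pd.DataFrame:
    """Score every scheduled trial; returns one row per trial.

    ``schedule`` needs columns onset (s), trial_type, phase, trial_index.
    Non-responses are kept as zero-amplitude rows.
    """
    config = config or ScoringConfig()
    rec = preprocess_signal(recording, config) if preprocess else recording
    end_needed = schedule["onset"].max() + config.peak_window_ms[1] / 1000
    if rec.duration < end_needed:
        bad = schedule.loc[
            schedule["onset"] + config.peak_window_ms[1] / 1000 > rec.duration
        ]
        raise ValueError(
            "recording too short for trials: "
            + ", ".join(f"{r.phase}/{r.trial_type}#{r.trial_index}" for r in bad.itertuples())
        )
    rows = []
    for r in schedule.sort_values("onset").itertuples():
        amp = score_trial_ttp(
            rec.samples, rec.sampling_rate, r.onset - rec.start_time, config,
            label=f"{r.phase}/{r.trial_type}#{r.trial_index}",
        )
        rows.append(
            {
                "participant": recording.participant,
                "phase": r.phase,
                "stimulus": r.trial_type,
                "trial_index": r.trial_index,
                "raw": amp,
                "response": amp > 0,
            }
        )
    return pd.DataFrame(rows)


def apply_minimum_criterion(raw: np.ndarray, config: ScoringConfig | None = None) -> np.ndarray:
    """Zero out amplitudes below the minimum response criterion."""
    config = config or ScoringConfig()
    raw = np.asarray(raw, float)
    if np.any(raw < 0):
        raise ValueError("raw amplitudes must be non-negative")
    out = raw.copy()
    out[out < config.min_response_us] = 0.0
    return out


def transform_amplitudes(table: pd.DataFrame,
                         config: ScoringConfig | None = None) -> pd.DataFrame:
    """Add the log-transformed, range-corrected amplitude column.

    transformed = log(1 + raw) / max_participant log(1 + raw); all-zero
    participants get 0 throughout. Values lie in [0, 1] and each responder's
    maximum is exactly 1.
    """
    config = config or ScoringConfig()
    if (table["raw"] < 0).any():
        raise ValueError("raw amplitudes must be non-negative")
    out = table.copy()
    logged = np.log1p(out["raw"].to_numpy()) / np.log(config.log_base)
    out["transformed"] = logged
    maxima = out.groupby("participant")["transformed"].transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["transformed"] = np.where(maxima > 0, out["transformed"] / maxima, 0.0)
    return out


def split_half_reliability(table: pd.DataFrame, phase: str, stimulus: str,
                           value_col: str = "transformed",
                           scheme: str = "odd_even") -> float:
    """Spearman-Brown corrected split-half reliability of per-trial amplitudes.

    Splits each participant's trials of the given phase/stimulus into two
    halves (``odd_even`` by trial parity or ``first_second`` by position),
    correlates the per-participant half means across participants, and
    applies the Spearman-Brown correction r_sb = 2r / (1 + r).
    """
    sel = table[(table["phase"] == phase) & (table["stimulus"] == stimulus)]
    sel = sel.sort_values("trial_index")
    counts = sel.groupby("participant").size()
    if (counts < 2).any() or len(counts) < 3:
        raise ValueError("need >= 2 trials per participant and >= 3 participants")

    def halves(g: pd.DataFrame) -> pd.Series:
        v = g[value_col].to_numpy()
        if scheme == "odd_even":
            a, b = v[::2], v[1::2]
        elif scheme == "first_second":
            mid = len(v) // 2
            a, b = v[:mid], v[mid:]
        else:
            raise ValueError(f"unknown split scheme {scheme!r}")
        return pd.Series({"h1": a.mean(), "h2": b.mean()})

    hm = sel.groupby("participant").apply(halves, include_groups=False)
    r = float(np.corrcoef(hm["h1"], hm["h2"])[0, 1])
    return 2 * r / (1 + r)
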