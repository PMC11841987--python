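"""Plain-text serialization of cohorts and scored tables.

Events follow the BIDS events.tsv dialect (tab-separated, onsets in seconds
from recording start); continuous signals are two-column CSV
(time_s, conductance_uS) with a YAML sidecar carrying the sampling rate and
participant id; questionnaires, ratings and scored amplitudes are tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scoring import SkinConductanceRecording

EVENT_COLUMNS = ["onset", "duration", "trial_type", "phase", "trial_index", "us"]


def write_events(schedule: pd.DataFrame, path: str | Path) -> None:
    schedule[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table lacks columns {missing}")
    df["us"] = df["us"].astype(bool)
    return df


def write_signal(recording: SkinConductanceRecording, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"time_s": recording.time(), "conductance_uS": recording.samples}
    ).to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "participant": recording.participant,
        "sampling_rate_hz": float(recording.sampling_rate),
        "start_time_s": float(recording.start_time),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_signal(path: str | Path) -> SkinConductanceRecording:
    path = Path(path)
    df = pd.read_csv(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return SkinConductanceRecording(
        participant=str(meta["participant"]),
        sampling_rate=float(meta["sampling_rate_hz"]),
        samples=df["conductance_uS"].to_numpy(),
        start_time=float(meta.get("start_time_s", 0.0)),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_flat_config(obj, path: str | Path) -> None:
    """Dataclass-ish config as a flat key: value text file."""
    fields = {k: v for k, v in vars(obj).items() if np.isscalar(v) or v is None}
    Path(path).write_text(
        "\n".join(f"{k}: {v}" for k, v in sorted(fields.items())) + "\n"
    )
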