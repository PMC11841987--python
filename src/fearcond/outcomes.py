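"""Derived outcomes per participant and measure.

Three outcomes summarize conditioned responding for SCRs and each rating
type (arousal, valence, contingency):

* CS discrimination — mean CS+ minus mean CS- response. For the
  acquisition phase the first acquisition trial of each CS is excluded
  (no learning can have occurred on a first presentation under delay
  conditioning); the generalization-phase value uses all generalization
  trials.
* Linear deviation score (LDS) — the mean of the CS+ and CS- means minus
  the mean of the four GS means during generalization; indexes how far the
  generalization gradient departs from linearity.
* General reactivity — the unweighted mean over every trial of all stimuli
  and phases; for SCRs this uses RAW amplitudes (uS), for ratings the
  native scale with valence inverted first.

SCR CS discrimination and the LDS are computed on the log-transformed,
range-corrected amplitudes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

GS_LABELS = ("GS1", "GS2", "GS3", "GS4")
MEASURES = ("scr", "arousal", "valence", "contingency")

__all__ = [
    "invert_valence",
    "cs_discrimination",
    "linear_deviation_score",
    "general_reactivity",
    "scr_outcomes",
    "rating_outcomes",
    "build_outcome_set",
    "MEASURES",
]


def invert_valence(ratings: pd.DataFrame) -> pd.DataFrame:
    """Reflect valence ratings (v -> 10 - v) so higher means more aversive.

    Only valence rows change; the ``inverted`` flag is toggled, making the
    operation an involution. Values outside [1, 9] raise.
    """
    out = ratings.copy()
    mask = out["rating_type"] == "valence"
    vals = out.loc[mask, "value"]
    if ((vals < 1) | (vals > 9)).any():
        raise ValueError("valence ratings must lie in [1, 9]")
    out.loc[mask, "value"] = 10 - vals
    if "inverted" in out.columns:
        out.loc[mask, "inverted"] = ~out.loc[mask, "inverted"].astype(bool)
    else:
        out["inverted"] = False
        out.loc[mask, "inverted"] = True
    return out


def _stim_means(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return df.groupby(["participant", "stimulus"], observed=True)[value_col].mean().unstack()


def cs_discrimination(trials: pd.DataFrame, phase: str, value_col: str,
                      exclude_first: str = "per_cs") -> pd.Series:
    """Per-participant mean CS+ minus mean CS- response in the given phase.

    For ``phase='acquisition'`` the first trial is excluded before
    averaging: of each CS (``exclude_first='per_cs'``, default), only the
    chronologically first acquisition trial (``'chronological'``), or no
    exclusion (``'none'``).
    """
    sel = trials[trials["phase"] == phase]
    if phase == "acquisition" and exclude_first != "none":
        if exclude_first == "per_cs":
            sel = sel[sel["trial_index"] > 1]
        elif exclude_first == "chronological":
            # table rows are in presentation order within participant
            first = sel.groupby("participant").head(1)
            sel = sel.drop(first.index)
        else:
            raise ValueError(f"unknown exclusion mode {exclude_first!r}")
    if sel.empty:
        raise ValueError(f"no usable trials in phase {phase!r}")
    means = _stim_means(sel, value_col)
    for cs in ("CS+", "CS-"):
        if cs not in means.columns:
            raise ValueError(f"no {cs} trials in phase {phase!r}")
    return (means["CS+"] - means["CS-"]).rename(f"cs_disc_{phase}")


def linear_deviation_score(trials: pd.DataFrame, value_col: str) -> pd.Series:
    """Mean of the two CS means minus the mean of the four GS means
    (generalization phase). Positive values indicate a more quadratic, less
    linear gradient."""
    sel = trials[trials["phase"] == "generalization"]
    means = _stim_means(sel, value_col)
    missing = [s for s in ("CS+", "CS-", *GS_LABELS) if s not in means.columns]
    if missing:
        raise ValueError(f"generalization phase lacks stimuli {missing}")
    cs_mean = means[["CS+", "CS-"]].mean(axis=1)
    gs_mean = means[list(GS_LABELS)].mean(axis=1)
    return (cs_mean - gs_mean).rename("lds")


def general_reactivity(trials: pd.DataFrame, value_col: str) -> pd.Series:
    """Unweighted per-participant mean over all trials, stimuli and phases."""
    if trials.empty:
        raise ValueError("no trials supplied")
    return trials.groupby("participant")[value_col].mean().rename("reactivity")


def _assemble(disc_acq, disc_gen, lds, react, measure: str) -> pd.DataFrame:
    out = pd.concat(
        {"cs_disc_acq": disc_acq, "cs_disc_gen": disc_gen, "lds": lds,
         "reactivity": react},
        axis=1,
    )
    out.insert(0, "measure", measure)
    return out


def scr_outcomes(amplitudes: pd.DataFrame, exclude_first: str = "per_cs") -> pd.DataFrame:
    """SCR outcome block: discrimination and LDS on the transformed scale,
    general reactivity on raw uS amplitudes."""
    if "transformed" not in amplitudes.columns:
        raise ValueError("amplitude table lacks the transformed column; "
                         "run transform_amplitudes first")
    return _assemble(
        cs_discrimination(amplitudes, "acquisition", "transformed", exclude_first),
        cs_discrimination(amplitudes, "generalization", "transformed"),
        linear_deviation_score(amplitudes, "transformed"),
        general_reactivity(amplitudes, "raw"),
        "scr",
    )


def rating_outcomes(ratings: pd.DataFrame) -> pd.DataFrame:
    """Outcome blocks for each rating type; valence is inverted first.

    Rating CS discrimination averages over the phase's rating timepoints;
    there is no first-trial exclusion (ratings are sparse phase summaries).
    """
    if not ratings.loc[ratings["rating_type"] == "valence", "inverted"].all():
        ratings = invert_valence(ratings)
    blocks = []
    for rtype in ("arousal", "valence", "contingency"):
        sel = ratings[ratings["rating_type"] == rtype].rename(columns={"value": "v"})
        if sel.empty:
            continue
        blocks.append(
            _assemble(
                cs_discrimination(sel, "acquisition", "v", exclude_first="none"),
                cs_discrimination(sel, "generalization", "v"),
                linear_deviation_score(sel, "v"),
                general_reactivity(sel, "v"),
                rtype,
            )
        )
    return pd.concat(blocks)


def build_outcome_set(amplitudes: pd.DataFrame | None,
                      ratings: pd.DataFrame | None,
                      exclude_first: str = "per_cs") -> pd.DataFrame:
    """Tidy outcome table: one row per participant x measure.

    Cells that cannot be computed for a measure (e.g. missing contingency
    ratings) are left as NaN; participants present in only one input table
    produce a warning and partial rows.
    """
    blocks = []
    if amplitudes is not None and not amplitudes.empty:
        blocks.append(scr_outcomes(amplitudes, exclude_first))
    if ratings is not None and not ratings.empty:
        blocks.append(rating_outcomes(ratings))
    if not blocks:
        raise ValueError("no input tables supplied")
    out = pd.concat(blocks)
    if len(blocks) == 2:
        p_amp = set(blocks[0].index)
        p_rat = set(blocks[1].index)
        if p_amp != p_rat:
            warnings.warn(
                f"{len(p_amp ^ p_rat)} participants present in only one input "
                "table; their rows are partial",
                stacklevel=2,
            )
    return out.reset_index().rename(columns={"index": "participant"})
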