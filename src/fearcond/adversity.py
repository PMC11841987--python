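"""Childhood Trauma Questionnaire scoring and exposure operationalizations.

The CTQ short form yields five subscale scores, each an integer in [5, 25]:
emotional abuse (ea), physical abuse (pa), sexual abuse (sa), emotional
neglect (en), physical neglect (pn). Four operationalizations of exposure
to childhood adversity are derived from them:

* dichotomous  — exposed if any subscale reaches the published moderate
  cut-off (ea >= 13, pa >= 10, sa >= 8, en >= 15, pn >= 10);
* cumulative risk — (a) four ordered severity groups from low / moderate /
  severe cut-off bands, (b) the count of subscales at or above the moderate
  cut-off;
* specificity — abuse (ea+pa+sa) and neglect (en+pn) composite scores used
  in separate models;
* dimensional — the same composites entered jointly, mutually adjusted.

Low and severe cut-offs are not bundled: they come from the CTQ manual and
must be supplied explicitly by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SUBSCALES = ("ea", "pa", "sa", "en", "pn")
SUBSCALE_MIN, SUBSCALE_MAX = 5, 25

#: published moderate-exposure cut-offs per subscale
MODERATE_CUTOFFS: dict[str, int] = {"ea": 13, "pa": 10, "sa": 8, "en": 15, "pn": 10}

SEVERITY_LEVELS = ("none", "low", "moderate", "severe")


@dataclass(frozen=True)
class CutoffTable:
    """Per-subscale thresholds; ``low``/``severe`` are optional manual values."""

    moderate: Mapping[str, int] = field(default_factory=lambda: dict(MODERATE_CUTOFFS))
    low: Mapping[str, int] | None = None
    severe: Mapping[str, int] | None = None

    def __post_init__(self):
        for name, table in (("moderate", self.moderate), ("low", self.low),
                            ("severe", self.severe)):
            if table is not None and set(table) != set(SUBSCALES):
                raise ValueError(f"{name} cut-offs must cover exactly {SUBSCALES}")
        if self.low is not None and self.severe is not None:
            for s in SUBSCALES:
                if not self.low[s] < self.moderate[s] < self.severe[s]:
                    raise ValueError(
                        f"cut-offs for {s!r} must satisfy low < moderate < severe"
                    )

    @property
    def has_severity_bands(self) -> bool:
        return self.low is not None and self.severe is not None


def _validate(profiles: pd.DataFrame) -> pd.DataFrame:
    missing = [s for s in SUBSCALES if s not in profiles.columns]
    if missing:
        raise ValueError(f"profile table lacks subscale columns {missing}")
    vals = profiles[list(SUBSCALES)]
    if ((vals < SUBSCALE_MIN) | (vals > SUBSCALE_MAX)).any().any():
        raise ValueError(f"subscale scores must lie in [{SUBSCALE_MIN}, {SUBSCALE_MAX}]")
    return vals


def classify_dichotomous(profiles: pd.DataFrame,
                         cutoffs: CutoffTable | None = None) -> pd.Series:
    """Exposed iff at least one subscale is at or above its moderate cut-off."""
    cutoffs = cutoffs or CutoffTable()
    vals = _validate(profiles)
    hits = np.column_stack([vals[s] >= cutoffs.moderate[s] for s in SUBSCALES])
    return pd.Series(hits.any(axis=1), index=profiles.index, name="exposed")


def count_subscales_above(profiles: pd.DataFrame,
                          cutoffs: CutoffTable | None = None) -> pd.Series:
    """Number of subscales (0-5) at or above the moderate cut-off."""
    cutoffs = cutoffs or CutoffTable()
    vals = _validate(profiles)
    hits = np.column_stack([vals[s] >= cutoffs.moderate[s] for s in SUBSCALES])
    return pd.Series(hits.sum(axis=1), index=profiles.index, name="n_subscales_above")


def severity_group(profiles: pd.DataFrame, cutoffs: CutoffTable) -> pd.Series:
    """Four-level severity: the highest band reached on any subscale.

    Requires a full three-level cut-off table; the low/severe thresholds are
    manual values the caller must supply.
    """
    if not cutoffs.has_severity_bands:
        raise ValueError(
            "severity_group needs low and severe cut-offs in addition to moderate; "
            "supply them from the CTQ manual via CutoffTable(low=..., severe=...)"
        )
    vals = _validate(profiles)
    band = np.zeros(len(profiles), dtype=int)
    for s in SUBSCALES:
        v = vals[s].to_numpy()
        b = np.zeros(len(v), dtype=int)
        b[v >= cutoffs.low[s]] = 1
        b[v >= cutoffs.moderate[s]] = 2
        b[v >= cutoffs.severe[s]] = 3
        band = np.maximum(band, b)
    cats = pd.Categorical.from_codes(band, categories=list(SEVERITY_LEVELS), ordered=True)
    return pd.Series(cats, index=profiles.index, name="severity_group")


def composite_scores(profiles: pd.DataFrame) -> pd.DataFrame:
    """Abuse (ea+pa+sa, range 15-75) and neglect (en+pn, range 10-50) composites."""
    vals = _validate(profiles)
    return pd.DataFrame(
        {
            "abuse": vals["ea"] + vals["pa"] + vals["sa"],
            "neglect": vals["en"] + vals["pn"],
        },
        index=profiles.index,
    )


def classify(profiles: pd.DataFrame, cutoffs: CutoffTable | None = None) -> pd.DataFrame:
    """All operationalizations in one table.

    Columns: ``exposed``, ``n_subscales_above``, ``abuse``, ``neglect`` and,
    when the cut-off table carries low/severe bands, ``severity_group``.
    """
    cutoffs = cutoffs or CutoffTable()
    out = composite_scores(profiles)
    out.insert(0, "exposed", classify_dichotomous(profiles, cutoffs))
    out.insert(1, "n_subscales_above", count_subscales_above(profiles, cutoffs))
    if cutoffs.has_severity_bands:
        out["severity_group"] = severity_group(profiles, cutoffs)
    return out
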