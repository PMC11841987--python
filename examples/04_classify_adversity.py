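"""Operationalize childhood-adversity exposure from CTQ subscale scores.

Dichotomous cut-off classification, count of subscales above cut-off,
abuse/neglect composites, and (given user-supplied low/severe thresholds)
four severity groups.
"""

import pandas as pd

from fearcond import CutoffTable, classify

profiles = pd.DataFrame(
    [
        {"ea": 5, "pa": 5, "sa": 5, "en": 5, "pn": 5},     # floor profile
        {"ea": 13, "pa": 5, "sa": 5, "en": 5, "pn": 5},    # EA at cut-off
        {"ea": 12, "pa": 9, "sa": 7, "en": 14, "pn": 9},   # all just below
        {"ea": 18, "pa": 11, "sa": 8, "en": 16, "pn": 12}, # multiply exposed
    ],
    index=["floor", "ea_at_cutoff", "just_below", "multiple"],
)

# low/severe bands are illustrative synthetic values; the published moderate
# cut-offs (ea 13, pa 10, sa 8, en 15, pn 10) are bundled
bands = CutoffTable(low={"ea": 9, "pa": 8, "sa": 6, "en": 10, "pn": 8},
                    severe={"ea": 16, "pa": 13, "sa": 13, "en": 18, "pn": 13})

print(classify(profiles, bands).to_string())
print("\nexposed = any subscale at/above its moderate cut-off; "
      "severity_group = highest band reached on any subscale.")
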