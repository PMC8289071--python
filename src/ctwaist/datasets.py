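"""Bundled example data.

`example_crosstab` returns the published-style cross-classification of a
757-adult health-screening cohort (326 women, 431 men) by CT-measured
and tape-measured waist-circumference cutoffs within BMI category.  The
cutoffs are the ROC-optimal CT cutoffs (91.7 cm women, 96.7 cm men) and
the KSSO tape cutoffs (85 / 90 cm).  These counts drive the worked
examples: sensitivity/specificity per method, concordance, and McNemar
tests all derive from them by plain arithmetic.
"""

from __future__ import annotations

import numpy as np

from .validation_stats import BMI_CATEGORIES, CrossTab

# counts[ct_class, manual_class, bmi_category]
# classes: 0 = below cutoff, 1 = at/above cutoff
# bmi: underweight, normal, overweight, obesity
_WOMEN = np.array(
    [
        [[21, 206, 4, 0],   # CT below,  manual below
         [0, 15, 4, 0]],    # CT below,  manual at/above
        [[0, 8, 5, 0],      # CT at/above, manual below
         [0, 12, 40, 11]],  # CT at/above, manual at/above
    ]
)
_MEN = np.array(
    [
        [[3, 189, 19, 0],
         [0, 17, 11, 0]],
        [[0, 17, 14, 0],
         [0, 23, 120, 18]],
    ]
)
_CUTOFFS = {
    "women": {"ct_cutoff_cm": 91.7, "manual_cutoff_cm": 85.0},
    "men": {"ct_cutoff_cm": 96.7, "manual_cutoff_cm": 90.0},
}


def example_crosstab(group: str) -> CrossTab:
    """Return the bundled screening-cohort cross-tabulation.

    Parameters
    ----------
    group:
        ``"women"`` (n=326) or ``"men"`` (n=431).
    """
    if group == "women":
        counts = _WOMEN
    elif group == "men":
        counts = _MEN
    else:
        raise ValueError(f"group must be 'women' or 'men', got {group!r}")
    return CrossTab(counts=counts.copy(), cutoffs=dict(_CUTOFFS[group]))


__all__ = ["example_crosstab", "BMI_CATEGORIES"]
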