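"""Factor-level ordering shared by simulators, models and contrasts.

The reference level is the first ordered level; indicator variables mark
the last.  Labels are ordered alphabetically, except that the canonical
site pair REF/ASH keeps REF as the reference, so hazard ratios and
reaction-norm slopes read as "ASH relative to REF".
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ordered_levels", "indicator_level"]


def ordered_levels(values) -> list:
    levels = sorted(pd.unique(pd.Series(values).astype(str)))
    if levels == ["ASH", "REF"]:
        return ["REF", "ASH"]
    return levels


def indicator_level(values):
    """The non-reference (indicator) level of a two-or-more-level factor."""
    return ordered_levels(values)[-1]
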