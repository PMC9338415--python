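"""Scoring of the affect instruments used around the protocol.

Two instruments are administered in-app: the international short form of the
Positive and Negative Affect Schedule (I-PANAS-SF; 10 Likert items, 5 per
subscale, scored 1-5, subscale score = item mean) and visual analogue scales
(VAS; a mark on a fixed line, scored as the relative distance from the left
end on a 0-100 scale).  The element-rating summary ranks protocol elements by
their mean perceived-stress VAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Published I-PANAS-SF item sets (subscale membership is fixed; the on-screen
#: wording/order in the deployed app is not documented, so this ordering is a
#: synthetic placeholder with the correct item->subscale map).
PANAS_NA_ITEMS = ("afraid", "nervous", "upset", "hostile", "ashamed")
PANAS_PA_ITEMS = ("alert", "inspired", "determined", "attentive", "active")
PANAS_ITEMS = PANAS_NA_ITEMS + PANAS_PA_ITEMS

VAS_SCALES = ("stressed", "frustrated", "overstrained", "ashamed")
PANAS_TIMEPOINTS = ("baseline", "post")
VAS_TIMEPOINTS = ("baseline", "intermediate", "post")


@dataclass(frozen=True)
class PanasScores:
    """Subscale mean scores, each in [1, 5]."""

    na: float
    pa: float


def score_panas(items) -> PanasScores:
    """Score a 10-item I-PANAS-SF response.

    ``items`` is either a sequence of 10 integers ordered NA items first then
    PA items, or a mapping from item name to score.  Any missing or
    out-of-range item invalidates the response (completers-only analysis; no
    imputation).
    """
    if isinstance(items, dict):
        try:
            values = [items[name] for name in PANAS_ITEMS]
        except KeyError as e:
            raise ValueError(f"missing PANAS item: {e.args[0]!r}") from None
    else:
        values = list(items)
    if len(values) != 10:
        raise ValueError(f"PANAS response must have exactly 10 items, got {len(values)}")
    arr = np.asarray(values, dtype=float)
    if np.any(np.isnan(arr)) or np.any((arr < 1) | (arr > 5)) \
            or not np.allclose(arr, np.round(arr)):
        raise ValueError("PANAS items must be integers in 1..5")
    return PanasScores(na=float(arr[:5].mean()), pa=float(arr[5:].mean()))


def vas_score(mark_position: float, line_length: float) -> float:
    """Relative distance of the mark from the left end of the line, 0-100."""
    if line_length <= 0:
        raise ValueError("line length must be positive")
    if not 0 <= mark_position <= line_length:
        raise ValueError("mark must lie on the line")
    return 100.0 * mark_position / line_length


def rank_elements(ratings: pd.DataFrame) -> pd.DataFrame:
    """Descriptive ranking of protocol elements by perceived stress.

    ``ratings`` is a long table with columns ``element`` and ``value``
    (0-100), optionally ``condition``.  Returns per-element mean and SD
    sorted descending by mean; ties are broken alphabetically by element
    label so the ordering is deterministic.  Population (ddof=0) SD of a
    single rating is 0.
    """
    if ratings.empty:
        return pd.DataFrame(columns=["element", "mean", "sd"])
    group_cols = ["condition", "element"] if "condition" in ratings.columns else ["element"]
    out = (ratings.groupby(group_cols)["value"]
           .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
           .reset_index())
    sort_cols = (["condition"] if "condition" in out.columns else []) + ["mean", "element"]
    out = out.sort_values(sort_cols, ascending=[True] * (len(sort_cols) - 2) + [False, True],
                          kind="mergesort").reset_index(drop=True)
    return out
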