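"""Scoring and screening classification for CESD-10, GAD-7 and SSRS.

The three instruments are scored by plain item sums:

* CESD-10 — ten depression items rated 0-3; totals 0-30; a total of 10 or
  more screens positive for depressive symptoms.
* GAD-7 — seven anxiety items rated 0-3; totals 0-21 banded into
  normal (0-4), mild (5-9), moderate (10-14) and severe (15-21); any band
  above normal screens positive.
* SSRS — ten social-support items with a composite structure: items 1-4 and
  8-10 are 1-4 Likert responses, item 5 has five 1-4 sub-parts, and items
  6-7 record sources of support.  Totals are banded low (<=22),
  medium (23-44) and high (>=45).

Two SSRS variants are provided for items 6-7 because the instrument is
scored differently across surveys: ``binary`` scores each of items 6-7 as
0 (no source) / 1 (a source exists); ``source_count`` scores each as the
number of distinct sources endorsed (0-9), the convention under which the
scale spans 12-66.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

CESD_CUTOFF = 10
GAD_BANDS = ((0, 4, "normal"), (5, 9, "mild"), (10, 14, "moderate"), (15, 21, "severe"))
SSRS_LOW_MAX = 22
SSRS_HIGH_MIN = 45


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, scale: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n,):
        raise ValidationError(f"{scale}: expected {n} items, got shape {arr.shape}")
    for i, v in enumerate(arr):
        if not (float(v).is_integer() and lo <= v <= hi):
            raise ValidationError(f"{scale}: item {i + 1} value {v!r} outside {lo}..{hi}")
    return arr.astype(int)


def score_cesd10(items: Sequence[int]) -> int:
    """Sum of the ten CESD-10 items (each 0-3), in [0, 30]."""
    return int(_check_items(items, 10, 0, 3, "CESD-10").sum())


def classify_depression(total: int, cutoff: int = CESD_CUTOFF) -> bool:
    """Screen positive iff the CESD-10 total reaches the cut-off (default 10)."""
    if not 0 <= total <= 30:
        raise ValidationError(f"CESD-10 total {total} outside 0..30")
    return total >= cutoff


def score_gad7(items: Sequence[int]) -> tuple[int, str]:
    """GAD-7 total (0-21) and severity band.

    Bands: normal 0-4, mild 5-9, moderate 10-14, severe 15-21.
    """
    total = int(_check_items(items, 7, 0, 3, "GAD-7").sum())
    return total, classify_anxiety(total)


def classify_anxiety(total: int) -> str:
    if not 0 <= total <= 21:
        raise ValidationError(f"GAD-7 total {total} outside 0..21")
    for lo, hi, band in GAD_BANDS:
        if lo <= total <= hi:
            return band
    raise AssertionError("unreachable: bands partition 0..21")


def anxiety_positive(level: str) -> bool:
    """Mild, moderate and severe merge into the screen-positive category."""
    return level != "normal"


@dataclass(frozen=True)
class SsrsResponse:
    """One respondent's SSRS answer sheet.

    ``likert`` holds items 1-4 and 8-10 (seven 1-4 responses, in item
    order); ``item5_parts`` the five 1-4 sub-parts of item 5;
    ``item6_sources`` / ``item7_sources`` the number of support sources
    endorsed on items 6 and 7 (0-9 each).
    """

    likert: Sequence[int]
    item5_parts: Sequence[int]
    item6_sources: int
    item7_sources: int


def score_ssrs(
    response: SsrsResponse,
    item67: Literal["binary", "source_count"] = "binary",
) -> tuple[int, str]:
    """SSRS total and support level (low/medium/high).

    ``item67='binary'`` scores items 6-7 as 0/1 (any source counts 1);
    ``'source_count'`` scores them as the number of sources (0-9).
    """
    likert = _check_items(response.likert, 7, 1, 4, "SSRS items 1-4/8-10")
    parts = _check_items(response.item5_parts, 5, 1, 4, "SSRS item 5")
    for name, v in (("6", response.item6_sources), ("7", response.item7_sources)):
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= 9):
            raise ValidationError(f"SSRS item {name}: source count {v!r} outside 0..9")
    if item67 == "binary":
        s67 = int(response.item6_sources > 0) + int(response.item7_sources > 0)
    elif item67 == "source_count":
        s67 = int(response.item6_sources) + int(response.item7_sources)
    else:
        raise ValidationError(f"unknown SSRS item-6/7 variant {item67!r}")
    total = int(likert.sum() + parts.sum() + s67)
    return total, classify_ssrs(total)


def classify_ssrs(total: int) -> str:
    if total <= SSRS_LOW_MAX:
        return "low"
    if total >= SSRS_HIGH_MIN:
        return "high"
    return "medium"


# column layout used by the cohort table
CESD_COLS = [f"cesd_{i}" for i in range(1, 11)]
GAD_COLS = [f"gad_{i}" for i in range(1, 8)]
SSRS_LIKERT_COLS = [f"ssrs_{i}" for i in (1, 2, 3, 4, 8, 9, 10)]
SSRS_ITEM5_COLS = [f"ssrs_5_{j}" for j in range(1, 6)]
SSRS_SOURCE_COLS = ["ssrs_6", "ssrs_7"]


def score_cohort(
    cohort: pd.DataFrame,
    item67: Literal["binary", "source_count"] = "binary",
    cesd_cutoff: int = CESD_CUTOFF,
) -> pd.DataFrame:
    """Append scale totals, bands and binary screening outcomes to a cohort.

    Adds ``cesd_total``, ``depression_positive``, ``gad_total``,
    ``anxiety_level``, ``anxiety_positive``, ``ssrs_total``, ``ssrs_level``.
    """
    out = cohort.copy()
    rows = len(out)
    cesd = out[CESD_COLS].to_numpy()
    gad = out[GAD_COLS].to_numpy()
    if ((cesd < 0) | (cesd > 3)).any():
        raise ValidationError("CESD-10 item outside 0..3 in cohort table")
    if ((gad < 0) | (gad > 3)).any():
        raise ValidationError("GAD-7 item outside 0..3 in cohort table")
    out["cesd_total"] = cesd.sum(axis=1).astype(int)
    out["depression_positive"] = (out["cesd_total"] >= cesd_cutoff).astype(int)
    out["gad_total"] = gad.sum(axis=1).astype(int)
    out["anxiety_level"] = [classify_anxiety(t) for t in out["gad_total"]]
    out["anxiety_positive"] = (out["anxiety_level"] != "normal").astype(int)

    likert = out[SSRS_LIKERT_COLS].to_numpy()
    parts = out[SSRS_ITEM5_COLS].to_numpy()
    sources = out[SSRS_SOURCE_COLS].to_numpy()
    if ((likert < 1) | (likert > 4)).any() or ((parts < 1) | (parts > 4)).any():
        raise ValidationError("SSRS Likert component outside 1..4 in cohort table")
    if ((sources < 0) | (sources > 9)).any():
        raise ValidationError("SSRS source count outside 0..9 in cohort table")
    if item67 == "binary":
        s67 = (sources > 0).sum(axis=1)
    else:
        s67 = sources.sum(axis=1)
    out["ssrs_total"] = (likert.sum(axis=1) + parts.sum(axis=1) + s67).astype(int)
    out["ssrs_level"] = [classify_ssrs(t) for t in out["ssrs_total"]]
    assert len(out) == rows
    return out
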