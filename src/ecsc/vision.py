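"""Categorical vision and lens vocabulary shared across the package.

RAAB-style field data record visual acuity (VA) on a coarse ordinal scale
whose cut points are exactly the Snellen thresholds used to define cataract
indicators.  Every VA comparison in the pipeline is one of two one-sided
tests against a named cut: "strictly worse than X" (an unoperated cataract
eye counts as needing surgery) or "X or better" (an operated eye counts as
a good outcome).  A missing VA satisfies neither direction.
"""

from __future__ import annotations

from enum import Enum


class VACategory(str, Enum):
    """Presenting / best-corrected visual acuity, best to worst."""

    GE_6_12 = "GE_6_12"                  # can see 6/12
    LT_6_12_GE_6_18 = "LT_6_12_GE_6_18"  # <6/12 but can see 6/18
    LT_6_18_GE_6_60 = "LT_6_18_GE_6_60"  # <6/18 but can see 6/60
    LT_6_60_GE_3_60 = "LT_6_60_GE_3_60"  # <6/60 but can see 3/60
    LT_3_60 = "LT_3_60"                  # <3/60
    MISSING = "NA"


#: ordinal rank, 0 = best; MISSING is the sentinel -1 and fails every comparison
MISSING_RANK = -1
VA_RANK: dict[VACategory, int] = {
    VACategory.GE_6_12: 0,
    VACategory.LT_6_12_GE_6_18: 1,
    VACategory.LT_6_18_GE_6_60: 2,
    VACategory.LT_6_60_GE_3_60: 3,
    VACategory.LT_3_60: 4,
    VACategory.MISSING: MISSING_RANK,
}
RANK_TO_VA = {r: c for c, r in VA_RANK.items()}

#: a category is "worse than cut" iff its rank >= CUT_RANK[cut];
#: "at cut or better" iff 0 <= rank < CUT_RANK[cut]
CUT_RANK = {"6/12": 1, "6/18": 2, "6/60": 3, "3/60": 4}

SURGICAL_CUTS = ("3/60", "6/60", "6/18", "6/12")
OUTCOME_CUTS = ("6/18", "6/12")


def va_rank(cat: VACategory | str) -> int:
    return VA_RANK[VACategory(cat)]


def worse_than(cat: VACategory | str, cut: str) -> bool:
    """True iff ``cat`` is strictly worse than the Snellen cut (MISSING: False)."""
    r = va_rank(cat)
    return r >= CUT_RANK[cut]


def at_or_better(cat: VACategory | str, cut: str) -> bool:
    """True iff ``cat`` is the Snellen cut or better (MISSING: False)."""
    r = va_rank(cat)
    return 0 <= r < CUT_RANK[cut]


class LensStatus(str, Enum):
    PHAKIC_CLEAR = "PHAKIC_CLEAR"
    PHAKIC_CATARACT = "PHAKIC_CATARACT"
    PSEUDOPHAKIA = "PSEUDOPHAKIA"
    APHAKIA = "APHAKIA"
    NO_VIEW = "NO_VIEW"
    MISSING = "NA"


#: an eye is "operated" iff the lens has been removed (with or without implant)
OPERATED_LENS = frozenset({LensStatus.PSEUDOPHAKIA, LensStatus.APHAKIA})


class Cause(str, Enum):
    """Principal cause of vision impairment recorded for one eye."""

    CATARACT = "CATARACT"
    OTHER = "OTHER"
    NONE = "NONE"
    MISSING = "NA"


class Sex(str, Enum):
    F = "F"
    M = "M"


SEXES = (Sex.F.value, Sex.M.value)

#: analysis age bands, left-closed; age 50 belongs to 50-59, 80+ unbounded
AGE_BANDS = ("50-59", "60-69", "70-79", "80+")


def age_band(age: int) -> str:
    """Map an age (>=50) to its analysis band."""
    if age < 50:
        raise ValueError(f"age {age} below survey eligibility (age >= 50)")
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    if age < 80:
        return "70-79"
    return "80+"


def band_index(band: str) -> int:
    return AGE_BANDS.index(band)


#: the 8 post-stratification strata (sex x age band), in canonical order
STRATA: tuple[tuple[str, str], ...] = tuple(
    (s, b) for s in SEXES for b in AGE_BANDS
)
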