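"""Person-level classification into CSC / eCSC numerators and denominator.

Cataract surgical coverage (CSC) counts people with operated cataract
(pseudophakia or aphakia in at least one eye) over people operated plus
people with operable cataract — an unoperated cataract eye whose
best-corrected VA falls strictly below the surgical threshold.  Effective
coverage (eCSC) restricts the numerator to operated people whose presenting
VA in the better operated eye reaches the good-outcome threshold.

Two readings of which unilaterally-operated people belong in the numerator
circulate in the field; both are implemented behind
:class:`IndicatorConfig.unilateral_rule`:

``ALL_OPERATED``
    every person with at least one operated eye (the default);
``FELLOW_IMPAIRED_ONLY``
    a unilaterally operated person qualifies only if the unoperated fellow
    eye has BCVA worse than the surgical threshold.  A fellow eye whose BCVA
    is unobservable (missing, or no view of the lens) cannot demonstrate
    impairment, so the person is conservatively excluded and the exclusion
    counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Participant, Survey
from .vision import (
    AGE_BANDS,
    CUT_RANK,
    LensStatus,
    OUTCOME_CUTS,
    RANK_TO_VA,
    SURGICAL_CUTS,
    VACategory,
    VA_RANK,
    age_band,
)

ALL_OPERATED = "ALL_OPERATED"
FELLOW_IMPAIRED_ONLY = "FELLOW_IMPAIRED_ONLY"


@dataclass(frozen=True)
class IndicatorConfig:
    """Threshold configuration defining one CSC/eCSC variant.

    Parameters
    ----------
    surgical_threshold
        Snellen cut; an unoperated cataract eye is operable when BCVA is
        strictly worse than this. One of 3/60, 6/60, 6/18, 6/12.
    outcome_threshold
        Snellen cut an operated person's better-eye presenting VA must reach
        ("at or better") to count as a good outcome. 6/18 or 6/12.
    unilateral_rule
        Which unilaterally operated people enter the CSC numerator (see
        module docstring).
    require_cataract_cause
        When True (default) an operable eye must also have cataract recorded
        as the principal cause of impairment, so vision loss attributable to
        other disease does not inflate the unmet-need denominator.
    """

    surgical_threshold: str = "6/18"
    outcome_threshold: str = "6/18"
    unilateral_rule: str = ALL_OPERATED
    require_cataract_cause: bool = True

    def __post_init__(self) -> None:
        if self.surgical_threshold not in SURGICAL_CUTS:
            raise ValueError(
                f"surgical_threshold must be one of {SURGICAL_CUTS}, "
                f"got {self.surgical_threshold!r}"
            )
        if self.outcome_threshold not in OUTCOME_CUTS:
            raise ValueError(
                f"outcome_threshold must be one of {OUTCOME_CUTS}, "
                f"got {self.outcome_threshold!r}"
            )
        if self.unilateral_rule not in (ALL_OPERATED, FELLOW_IMPAIRED_ONLY):
            raise ValueError(f"unknown unilateral_rule {self.unilateral_rule!r}")

    @property
    def label(self) -> str:
        """Canonical descriptor carried on every output row."""
        return (
            f"st<{self.surgical_threshold}|ot>={self.outcome_threshold}"
            f"|{self.unilateral_rule}"
        )


DEFAULT_CONFIG = IndicatorConfig()


@dataclass(frozen=True)
class PersonClass:
    operated: str  # BILATERAL | UNILATERAL | NONE
    in_denominator: bool
    in_csc_numerator: bool
    in_ecsc_numerator: bool
    postop_pva: VACategory
    undefined: bool = False       # lens status missing in both eyes
    ecsc_undefined: bool = False  # operated but no observable postop presenting VA


def eye_operated(eye) -> bool:
    """True iff the eye has had cataract surgery (pseudophakia or aphakia)."""
    return LensStatus(eye.lens) in (LensStatus.PSEUDOPHAKIA, LensStatus.APHAKIA)


def eye_operable(eye, surgical_threshold: str, require_cataract_cause: bool = True) -> bool:
    """True iff the eye has unoperated cataract needing surgery at the cut."""
    from .vision import Cause, worse_than

    if LensStatus(eye.lens) is not LensStatus.PHAKIC_CATARACT:
        return False
    if not worse_than(eye.bcva, surgical_threshold):
        return False
    if require_cataract_cause and Cause(eye.cause) is not Cause.CATARACT:
        return False
    return True


def _rank_codes(col: pd.Series) -> np.ndarray:
    """VA string codes -> ordinal rank array (missing sentinel -1)."""
    return col.map({c.value: r for c, r in VA_RANK.items()}).to_numpy(dtype=float)


def classify_frame(frame: pd.DataFrame, cfg: IndicatorConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Vectorised classification of a canonical survey frame.

    Returns a frame aligned with the input holding: ``operated``,
    ``in_denominator``, ``in_csc_numerator``, ``in_ecsc_numerator``,
    ``postop_pva`` (string code), ``undefined``, ``ecsc_undefined``.
    """
    st_rank = CUT_RANK[cfg.surgical_threshold]
    ot_rank = CUT_RANK[cfg.outcome_threshold]

    r_lens = frame["r_lens"].to_numpy(dtype=object)
    l_lens = frame["l_lens"].to_numpy(dtype=object)
    op_codes = (LensStatus.PSEUDOPHAKIA.value, LensStatus.APHAKIA.value)
    r_op = np.isin(r_lens, op_codes)
    l_op = np.isin(l_lens, op_codes)
    n_op = r_op.astype(int) + l_op.astype(int)

    undefined = (r_lens == LensStatus.MISSING.value) & (l_lens == LensStatus.MISSING.value)

    r_bcva = _rank_codes(frame["r_bcva"])
    l_bcva = _rank_codes(frame["l_bcva"])
    r_pva = _rank_codes(frame["r_pva"])
    l_pva = _rank_codes(frame["l_pva"])

    def operable(lens, bcva, cause_col):
        ok = (lens == LensStatus.PHAKIC_CATARACT.value) & (bcva >= st_rank)
        if cfg.require_cataract_cause:
            ok &= frame[cause_col].to_numpy(dtype=object) == "CATARACT"
        return ok

    r_operable = operable(r_lens, r_bcva, "r_cause")
    l_operable = operable(l_lens, l_bcva, "l_cause")

    fellow_unknown = np.zeros(len(frame), dtype=bool)
    if cfg.unilateral_rule == ALL_OPERATED:
        csc = n_op >= 1
    else:
        fellow_bcva = np.where(r_op & ~l_op, l_bcva, np.where(l_op & ~r_op, r_bcva, np.nan))
        csc = (n_op == 2) | ((n_op == 1) & (fellow_bcva >= st_rank))
        # fellow eye impairment unobservable: excluded from numerator, counted
        fellow_unknown = (n_op == 1) & (fellow_bcva < 0)

    denom = csc | ((n_op == 0) & (r_operable | l_operable))

    # better-eye presenting VA among operated eyes; missing VAs drop out
    big = 99.0
    r_p = np.where(r_op & (r_pva >= 0), r_pva, big)
    l_p = np.where(l_op & (l_pva >= 0), l_pva, big)
    postop = np.minimum(r_p, l_p)
    ecsc_undef = csc & (postop >= big)
    ecsc = csc & (postop < ot_rank)

    postop_rank = np.where(postop >= big, -1, postop).astype(int)
    out = pd.DataFrame(
        {
            "operated": np.where(n_op == 2, "BILATERAL", np.where(n_op == 1, "UNILATERAL", "NONE")),
            "in_denominator": denom & ~undefined,
            "in_csc_numerator": csc & ~undefined,
            "in_ecsc_numerator": ecsc & ~undefined,
            "postop_pva": [RANK_TO_VA[r].value for r in postop_rank],
            "undefined": undefined,
            "ecsc_undefined": ecsc_undef & ~undefined,
            "fellow_unknown": fellow_unknown & ~undefined,
        },
        index=frame.index,
    )
    return out


def classify_person(p: Participant, cfg: IndicatorConfig = DEFAULT_CONFIG) -> PersonClass:
    """Classify a single participant (thin wrapper over :func:`classify_frame`)."""
    row = classify_frame(pd.DataFrame([p.to_row()]), cfg).iloc[0]
    return PersonClass(
        operated=row["operated"],
        in_denominator=bool(row["in_denominator"]),
        in_csc_numerator=bool(row["in_csc_numerator"]),
        in_ecsc_numerator=bool(row["in_ecsc_numerator"]),
        postop_pva=VACategory(row["postop_pva"]),
        undefined=bool(row["undefined"]),
        ecsc_undefined=bool(row["ecsc_undefined"]),
    )


@dataclass
class SurveyCounts:
    """Indicator counts per (cluster, sex, age band) cell plus exclusions."""

    cells: pd.DataFrame  # columns: cluster_id, sex, age_band, examined, denom, csc_num, ecsc_num
    exclusions: dict = field(default_factory=dict)
    config_label: str = ""

    def by_stratum(self) -> pd.DataFrame:
        return (
            self.cells.groupby(["sex", "age_band"], as_index=False, observed=True)[
                ["examined", "denom", "csc_num", "ecsc_num"]
            ].sum()
        )

    def by_cluster(self) -> pd.DataFrame:
        return (
            self.cells.groupby("cluster_id", as_index=False, observed=True)[
                ["examined", "denom", "csc_num", "ecsc_num"]
            ].sum()
        )

    def totals(self) -> dict:
        s = self.cells[["examined", "denom", "csc_num", "ecsc_num"]].sum()
        return {k: int(v) for k, v in s.items()}


def survey_counts(survey: Survey, cfg: IndicatorConfig = DEFAULT_CONFIG) -> SurveyCounts:
    """Tally numerators, denominator and examined counts per cluster-stratum cell.

    People with missing lens status in both eyes are excluded from every
    count (including ``examined``); operated people with no observable
    postoperative presenting VA stay in the denominator but are excluded
    from the eCSC numerator.  Both exclusion counts are reported.
    """
    frame = survey.frame
    cls = classify_frame(frame, cfg)
    keep = ~cls["undefined"].to_numpy()

    ages = frame["age"].astype(int).to_numpy()
    bands = np.select(
        [ages < 60, ages < 70, ages < 80],
        AGE_BANDS[:3],
        default=AGE_BANDS[3],
    )
    work = pd.DataFrame(
        {
            "cluster_id": frame["cluster_id"].astype(str).to_numpy()[keep],
            "sex": frame["sex"].to_numpy(dtype=object)[keep],
            "age_band": bands[keep],
            "examined": 1,
            "denom": cls["in_denominator"].to_numpy()[keep].astype(int),
            "csc_num": cls["in_csc_numerator"].to_numpy()[keep].astype(int),
            "ecsc_num": cls["in_ecsc_numerator"].to_numpy()[keep].astype(int),
        }
    )
    cells = work.groupby(["cluster_id", "sex", "age_band"], as_index=False, observed=True).sum()
    exclusions = {
        "undefined_lens_both_eyes": int((~keep).sum()),
        "ecsc_numerator_missing_postop_va": int(cls["ecsc_undefined"].to_numpy()[keep].sum()),
        "unilateral_fellow_eye_unknown": int(cls["fellow_unknown"].to_numpy()[keep].sum()),
    }
    return SurveyCounts(cells=cells, exclusions=exclusions, config_label=cfg.label)
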