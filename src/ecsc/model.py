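"""Domain types: eye exams, participants, surveys, population tables.

A :class:`Survey` carries its participants both as a canonical
:class:`pandas.DataFrame` (``frame``, the representation all vectorised
pipeline stages operate on) and, on demand, as a list of
:class:`Participant` records for row-level work.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .vision import (
    SEXES,
    STRATA,
    Cause,
    LensStatus,
    Sex,
    VACategory,
    age_band,
)


class SchemaError(ValueError):
    """Input file does not match the documented column schema."""


class DesignError(ValueError):
    """Survey violates a design requirement (e.g. fewer than 2 clusters)."""


class UndefinedEstimateError(ArithmeticError):
    """An estimate is undefined (e.g. weighted denominator is zero)."""


#: canonical survey CSV columns
SURVEY_COLUMNS = (
    "participant_id",
    "cluster_id",
    "age",
    "sex",
    "r_lens",
    "l_lens",
    "r_pva",
    "l_pva",
    "r_bcva",
    "l_bcva",
    "r_cause",
    "l_cause",
)

POPULATION_COLUMNS = ("sex", "age_band", "count")


@dataclass(frozen=True)
class EyeExam:
    """One eye: lens status, presenting VA, best-corrected VA, cause of VI."""

    lens: LensStatus = LensStatus.MISSING
    pva: VACategory = VACategory.MISSING
    bcva: VACategory = VACategory.MISSING
    cause: Cause = Cause.MISSING

    def __post_init__(self) -> None:
        object.__setattr__(self, "lens", LensStatus(self.lens))
        object.__setattr__(self, "pva", VACategory(self.pva))
        object.__setattr__(self, "bcva", VACategory(self.bcva))
        object.__setattr__(self, "cause", Cause(self.cause))


@dataclass(frozen=True)
class Participant:
    id: str
    cluster_id: str
    age: int
    sex: Sex
    right: EyeExam
    left: EyeExam

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.age < 50:
            raise ValueError(f"participant {self.id}: age >= 50 required, got {self.age}")
        if not str(self.cluster_id):
            raise ValueError(f"participant {self.id}: cluster_id non-empty required")

    @property
    def stratum(self) -> tuple[str, str]:
        return (Sex(self.sex).value, age_band(self.age))

    def to_row(self) -> dict:
        return {
            "participant_id": self.id,
            "cluster_id": self.cluster_id,
            "age": self.age,
            "sex": Sex(self.sex).value,
            "r_lens": self.right.lens.value,
            "l_lens": self.left.lens.value,
            "r_pva": self.right.pva.value,
            "l_pva": self.left.pva.value,
            "r_bcva": self.right.bcva.value,
            "l_bcva": self.left.bcva.value,
            "r_cause": self.right.cause.value,
            "l_cause": self.left.cause.value,
        }

    @classmethod
    def from_row(cls, row: Mapping) -> "Participant":
        def eye(side: str) -> EyeExam:
            return EyeExam(
                lens=LensStatus(row[f"{side}_lens"]),
                pva=VACategory(row[f"{side}_pva"]),
                bcva=VACategory(row[f"{side}_bcva"]),
                cause=Cause(row[f"{side}_cause"]),
            )

        return cls(
            id=str(row["participant_id"]),
            cluster_id=str(row["cluster_id"]),
            age=int(row["age"]),
            sex=Sex(row["sex"]),
            right=eye("r"),
            left=eye("l"),
        )


@dataclass(frozen=True)
class SurveyMeta:
    """Survey provenance: identity, country, year, sampling-frame scope."""

    survey_id: str
    country: str
    year: int
    scope: str = "SUBNATIONAL"  # NATIONAL | SUBNATIONAL
    region_label: str = ""
    income_label: str = ""
    #: non-empty when this subnational survey belongs to a declared series
    #: designed for national coverage; series membership is metadata, never inferred
    series_label: str = ""

    def __post_init__(self) -> None:
        if self.scope not in ("NATIONAL", "SUBNATIONAL"):
            raise ValueError(f"scope must be NATIONAL or SUBNATIONAL, got {self.scope!r}")
        if not (2000 <= int(self.year) <= 2035):
            raise ValueError(f"implausible survey year {self.year}")


@dataclass
class Survey:
    """A validated participant sample plus its metadata.

    ``frame`` holds one row per participant in the canonical column schema
    (:data:`SURVEY_COLUMNS`); all enum fields are stored as their string codes.
    """

    frame: pd.DataFrame
    meta: SurveyMeta
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in SURVEY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"survey frame missing columns: {missing}")
        self.frame = self.frame.loc[:, list(SURVEY_COLUMNS)].reset_index(drop=True)
        ids = self.frame["participant_id"].astype(str)
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5].tolist()
            raise ValueError(f"duplicate participant ids: {dupes}")
        if self.frame["cluster_id"].astype(str).nunique() < 2:
            raise DesignError(
                "cluster variance estimation requires >= 2 distinct clusters"
            )

    @classmethod
    def from_participants(
        cls,
        participants: Iterable[Participant],
        meta: SurveyMeta,
    ) -> "Survey":
        rows = [p.to_row() for p in participants]
        return cls(frame=pd.DataFrame(rows, columns=list(SURVEY_COLUMNS)), meta=meta)

    @property
    def participants(self) -> list[Participant]:
        return [Participant.from_row(r) for r in self.frame.to_dict("records")]

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_clusters(self) -> int:
        return int(self.frame["cluster_id"].astype(str).nunique())


_BAND_RE = re.compile(r"^(\d+)(?:\s*[-–]\s*(\d+)|\+)$")


def _parse_band(band: str) -> tuple[int, int | None]:
    """Return (low, high) of an age-band label; high is None for open-ended."""
    m = _BAND_RE.match(str(band).strip())
    if not m:
        raise SchemaError(f"unparseable age band {band!r}")
    low = int(m.group(1))
    high = int(m.group(2)) if m.group(2) else None
    return low, high


def _to_analysis_band(band: str) -> str:
    low, high = _parse_band(band)
    if low < 50:
        raise SchemaError(f"age band {band!r} starts below 50")
    target = age_band(low)
    if high is not None:
        # the input band must not straddle an analysis-band boundary
        if age_band(high) != target:
            raise SchemaError(f"age band {band!r} straddles analysis bands")
    elif target != "80+":
        raise SchemaError(f"open-ended band {band!r} must start at 80 or above")
    return target


@dataclass(frozen=True)
class PopulationTable:
    """Census counts of the survey area for the 8 age-sex analysis strata."""

    counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        missing = [s for s in STRATA if s not in counts]
        if missing:
            raise SchemaError(f"population table missing strata: {missing}")
        for s, c in counts.items():
            if c < 0:
                raise ValueError(f"negative population count in stratum {s}")
        if sum(counts.values()) <= 0:
            raise ValueError("population table total must be positive")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping]) -> "PopulationTable":
        """Build from (sex, age_band, count) rows, aggregating 5-year bands."""
        agg: dict[tuple[str, str], int] = {s: 0 for s in STRATA}
        seen: set[tuple[str, str]] = set()
        for row in rows:
            sex = str(row["sex"]).strip()
            if sex not in SEXES:
                raise SchemaError(f"unknown sex code {sex!r} in population table")
            band = _to_analysis_band(row["age_band"])
            count = int(row["count"])
            if count < 0:
                raise ValueError(f"negative count for {sex} {row['age_band']}")
            agg[(sex, band)] += count
            seen.add((sex, band))
        absent = [s for s in STRATA if s not in seen]
        if absent:
            raise SchemaError(f"population table missing strata: {absent}")
        return cls(counts=agg)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, sex: str, band: str) -> int:
        return self.counts[(sex, band)]

    def scaled(self, factor: float) -> "PopulationTable":
        return PopulationTable(
            {s: int(round(c * factor)) for s, c in self.counts.items()}
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sex": s, "age_band": b, "count": self.counts[(s, b)]}
                for (s, b) in STRATA
            ]
        )
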