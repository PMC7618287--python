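"""Readers and writers for the canonical delimited-text formats.

All files are UTF-8, comma-delimited, with one header row.  Survey files use
the canonical column schema (:data:`ecsc.model.SURVEY_COLUMNS`); an optional
``column_map`` translates external headers to it.  Population files carry
(sex, age_band, count) rows at 5-year or coarser resolution and are
aggregated to the four analysis bands on read.  Round trips through the
writers are lossless for every enum and numeric field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .estimate import Estimate
from .model import (
    PopulationTable,
    SchemaError,
    Survey,
    SurveyMeta,
    SURVEY_COLUMNS,
)
from .vision import Cause, LensStatus, Sex, VACategory

_ENUM_COLUMNS = {
    "sex": {s.value for s in Sex},
    "r_lens": {s.value for s in LensStatus},
    "l_lens": {s.value for s in LensStatus},
    "r_pva": {v.value for v in VACategory},
    "l_pva": {v.value for v in VACategory},
    "r_bcva": {v.value for v in VACategory},
    "l_bcva": {v.value for v in VACategory},
    "r_cause": {c.value for c in Cause},
    "l_cause": {c.value for c in Cause},
}


def read_survey(
    path: str | Path,
    meta: SurveyMeta | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Survey:
    """Read and validate a survey CSV.

    Rows violating hard invariants (age < 50, empty cluster id, missing
    mandatory field) are rejected with row-numbered diagnostics collected on
    ``Survey.diagnostics``; an unknown enum code raises a ``ValueError``
    naming the row and column; soft violations (BCVA worse than presenting
    VA) are logged as diagnostics but kept.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}")
    df = df.loc[:, list(SURVEY_COLUMNS)]

    for col, allowed in _ENUM_COLUMNS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(df.index[bad][0])
            raise ValueError(
                f"{path.name} row {i + 2}: unknown code {df[col].iloc[i]!r} "
                f"in column {col!r}"
            )

    diagnostics: list[str] = []
    age_num = pd.to_numeric(df["age"], errors="coerce")
    reject = pd.Series(False, index=df.index)

    bad_age = age_num.isna() | (age_num < 50)
    for i in df.index[bad_age]:
        diagnostics.append(
            f"row {i + 2}: rejected, age >= 50 required (got {df['age'].loc[i]!r})"
        )
    reject |= bad_age

    empty_cluster = df["cluster_id"].str.strip() == ""
    for i in df.index[empty_cluster]:
        diagnostics.append(f"row {i + 2}: rejected, cluster_id non-empty required")
    reject |= empty_cluster

    # soft invariant: best-corrected VA should not be worse than presenting VA
    from .vision import VA_RANK

    rank = {c.value: r for c, r in VA_RANK.items()}
    for side in ("r", "l"):
        p = df[f"{side}_pva"].map(rank)
        b = df[f"{side}_bcva"].map(rank)
        soft = (p >= 0) & (b >= 0) & (b > p)
        for i in df.index[soft]:
            diagnostics.append(
                f"row {i + 2}: warning, {side}_bcva worse than {side}_pva (kept)"
            )

    kept = df.loc[~reject].copy()
    kept["age"] = age_num.loc[~reject].astype(int)
    if meta is None:
        meta = SurveyMeta(survey_id=path.stem, country="", year=2020)
    survey = Survey(frame=kept, meta=meta)
    survey.diagnostics.extend(diagnostics)
    return survey


def write_survey(survey: Survey, path: str | Path) -> Path:
    path = Path(path)
    survey.frame.to_csv(path, index=False)
    return path


def read_population(path: str | Path) -> PopulationTable:
    """Read a (sex, age_band, count) CSV, aggregating to the 4 analysis bands."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("sex", "age_band", "count") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}")
    return PopulationTable.from_rows(df.to_dict("records"))


def write_population(table: PopulationTable, path: str | Path) -> Path:
    path = Path(path)
    table.as_frame().to_csv(path, index=False)
    return path


def read_meta(path: str | Path) -> SurveyMeta:
    """Read survey metadata from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SurveyMeta(**data)


def write_meta(meta: SurveyMeta, path: str | Path) -> Path:
    path = Path(path)
    data = dataclasses.asdict(meta)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))
    return path


_ESTIMATE_FIELDS = [f.name for f in dataclasses.fields(Estimate)]


def write_estimates(estimates: list[Estimate], path: str | Path) -> Path:
    """Write estimates to CSV; an empty list yields a header-only file."""
    path = Path(path)
    rows = [dataclasses.asdict(e) for e in estimates]
    pd.DataFrame(rows, columns=_ESTIMATE_FIELDS).to_csv(path, index=False)
    return path


def read_estimates(path: str | Path) -> list[Estimate]:
    df = pd.read_csv(Path(path))
    out = []
    for row in df.to_dict("records"):
        kwargs = {}
        for f in dataclasses.fields(Estimate):
            v = row[f.name]
            if f.type in ("int", int):
                v = int(v)
            elif f.type in ("float", float):
                v = float(v)
            else:
                v = "" if pd.isna(v) else str(v)
            kwargs[f.name] = v
        out.append(Estimate(**kwargs))
    return out
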