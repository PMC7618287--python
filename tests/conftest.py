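"""Shared fixtures: hand-built participants and session-scoped synthetic data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ecsc import (
    EyeExam,
    Participant,
    PopulationTable,
    ScenarioConfig,
    Survey,
    SurveyMeta,
    generate_population,
    small_scenario,
)
from ecsc.model import SURVEY_COLUMNS
from ecsc.vision import SEXES, STRATA


def eye(lens="PHAKIC_CLEAR", pva="GE_6_12", bcva=None, cause="NONE") -> EyeExam:
    """Shorthand eye builder; bcva defaults to pva."""
    return EyeExam(lens=lens, pva=pva, bcva=pva if bcva is None else bcva, cause=cause)


HEALTHY = eye()
OPERABLE = eye("PHAKIC_CATARACT", "LT_6_18_GE_6_60", cause="CATARACT")
OPERATED_GOOD = eye("PSEUDOPHAKIA", "GE_6_12")
OPERATED_BAD = eye("PSEUDOPHAKIA", "LT_6_60_GE_3_60", "LT_6_18_GE_6_60", cause="OTHER")


def person(pid, cluster="c1", age=65, sex="F", right=HEALTHY, left=HEALTHY) -> Participant:
    return Participant(id=str(pid), cluster_id=cluster, age=age, sex=sex,
                       right=right, left=left)


def make_survey(participants, survey_id="s1", country="Testland", year=2020,
                **meta_kwargs) -> Survey:
    meta = SurveyMeta(survey_id=survey_id, country=country, year=year, **meta_kwargs)
    return Survey.from_participants(participants, meta)


def uniform_population(survey: Survey, factor: int = 10) -> PopulationTable:
    """Population with identical sampling fraction in every examined stratum."""
    from ecsc.vision import age_band

    counts = {s: 0 for s in STRATA}
    for _, row in survey.frame.iterrows():
        counts[(row["sex"], age_band(int(row["age"])))] += factor
    return PopulationTable(counts)


def random_participants_frame(n: int, seed: int = 0) -> pd.DataFrame:
    """Uniformly random participants over the full enum space (incl. missing)."""
    rng = np.random.default_rng(seed)
    lens_codes = ["PHAKIC_CLEAR", "PHAKIC_CATARACT", "PSEUDOPHAKIA", "APHAKIA",
                  "NO_VIEW", "NA"]
    va_codes = ["GE_6_12", "LT_6_12_GE_6_18", "LT_6_18_GE_6_60",
                "LT_6_60_GE_3_60", "LT_3_60", "NA"]
    cause_codes = ["CATARACT", "OTHER", "NONE", "NA"]
    data = {
        "participant_id": [str(i) for i in range(n)],
        "cluster_id": rng.choice([f"c{j}" for j in range(10)], n),
        "age": rng.integers(50, 95, n),
        "sex": rng.choice(list(SEXES), n),
    }
    for side in ("r", "l"):
        data[f"{side}_lens"] = rng.choice(lens_codes, n)
        data[f"{side}_pva"] = rng.choice(va_codes, n)
        data[f"{side}_bcva"] = rng.choice(va_codes, n)
        data[f"{side}_cause"] = rng.choice(cause_codes, n)
    return pd.DataFrame(data, columns=list(SURVEY_COLUMNS))


@pytest.fixture(scope="session")
def small_pop():
    """Down-scaled roster (~27k persons) shared across tests."""
    return generate_population(small_scenario(seed=11))


@pytest.fixture(scope="session")
def default_pop():
    """Full default-scale roster (~270k persons)."""
    return generate_population(ScenarioConfig(seed=5))
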