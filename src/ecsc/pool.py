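"""Country-level estimate selection and fixed-effect pooling.

Where a country contributed several surveys, a single country estimate is
produced by a predetermined decision tree driven purely by survey metadata:

1. if any nationally representative estimate exists (a single national
   survey, or a declared series of subnational surveys designed for national
   coverage, pooled first), take the most recent;
2. otherwise take the most recent subnational survey and pool with it every
   subnational survey completed within 3 years before it (boundary
   inclusive: a 2019 survey pools with 2016).

Ties on year are broken by larger sample size, then lexicographic survey id.
Subnational estimates are combined with a fixed-effect inverse-variance
weighted average; random-effects pooling lives in :mod:`ecsc.meta`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .estimate import Z95, Estimate
from .model import SurveyMeta

logger = logging.getLogger(__name__)

SINGLE_NATIONAL = "SINGLE_NATIONAL"
POOLED_NATIONAL_SERIES = "POOLED_NATIONAL_SERIES"
SINGLE_SUBNATIONAL = "SINGLE_SUBNATIONAL"
POOLED_SUBNATIONAL = "POOLED_SUBNATIONAL"


@dataclass(frozen=True)
class SurveyEstimate:
    estimate: Estimate
    meta: SurveyMeta


@dataclass(frozen=True)
class CountryEstimate:
    country: str
    estimate: Estimate
    provenance: tuple[str, ...]  # contributing survey_ids
    method: str
    year: int  # completion year of the (most recent) contributing survey

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("country estimate requires non-empty provenance")
        pooled = self.method in (POOLED_NATIONAL_SERIES, POOLED_SUBNATIONAL)
        if pooled != (len(self.provenance) > 1):
            raise ValueError(
                f"method {self.method} inconsistent with {len(self.provenance)} surveys"
            )


def pool_inverse_variance(estimates: list[SurveyEstimate | Estimate]) -> Estimate:
    """Fixed-effect inverse-variance weighted average of estimates.

    Weights are 1/se^2; the pooled SE is sqrt(1/sum(weights)).  Zero-variance
    inputs are rejected with a diagnostic; a single estimate passes through.
    """
    ests = [e.estimate if isinstance(e, SurveyEstimate) else e for e in estimates]
    kept = []
    for e in ests:
        if e.se <= 0:
            logger.warning("rejecting zero-variance estimate (value=%s) from pooling", e.value)
            continue
        kept.append(e)
    if not kept:
        raise ValueError("no estimates with positive SE to pool")
    if len(kept) == 1:
        return kept[0]
    u = np.array([1.0 / e.se**2 for e in kept])
    v = np.array([e.value for e in kept])
    value = float(np.sum(u * v) / np.sum(u))
    se = float(math.sqrt(1.0 / np.sum(u)))
    return replace(
        kept[0],
        value=value,
        se=se,
        ci_low=max(0.0, value - Z95 * se),
        ci_high=min(100.0, value + Z95 * se),
        n_examined=sum(e.n_examined for e in kept),
        n_clusters=sum(e.n_clusters for e in kept),
        weighted_num=float("nan"),
        weighted_den=float("nan"),
    )


def _recency_key(c: SurveyEstimate):
    # most recent first; ties: larger sample, then lexicographically first id
    return (-c.meta.year, -c.estimate.n_examined, c.meta.survey_id)


def select_country_surveys(candidates: list[SurveyEstimate]) -> CountryEstimate:
    """Apply the decision tree to one country's survey estimates."""
    if not candidates:
        raise ValueError("no candidate surveys")
    countries = {c.meta.country for c in candidates}
    if len(countries) != 1:
        raise ValueError(f"candidates span several countries: {sorted(countries)}")
    country = countries.pop()

    # national candidates: single national surveys, plus declared national
    # series pooled into one candidate dated by the series' most recent year
    nationals: list[tuple[int, int, str, Estimate, tuple[str, ...], str]] = []
    for c in candidates:
        if c.meta.scope == "NATIONAL":
            nationals.append(
                (c.meta.year, c.estimate.n_examined, c.meta.survey_id,
                 c.estimate, (c.meta.survey_id,), SINGLE_NATIONAL)
            )
    series_labels = sorted({c.meta.series_label for c in candidates if c.meta.series_label})
    for label in series_labels:
        members = sorted(
            [c for c in candidates if c.meta.series_label == label], key=_recency_key
        )
        pooled = pool_inverse_variance(members)
        ids = tuple(m.meta.survey_id for m in members)
        method = POOLED_NATIONAL_SERIES if len(ids) > 1 else SINGLE_NATIONAL
        nationals.append(
            (max(m.meta.year for m in members), pooled.n_examined,
             ids[0], pooled, ids, method)
        )
    if nationals:
        nationals.sort(key=lambda t: (-t[0], -t[1], t[2]))
        year, _, _, est, ids, method = nationals[0]
        return CountryEstimate(country, est, ids, method, year)

    subs = sorted(
        [c for c in candidates if c.meta.scope == "SUBNATIONAL" and not c.meta.series_label],
        key=_recency_key,
    )
    if not subs:
        raise ValueError(f"no usable surveys for {country}")
    latest = subs[0]
    window = [c for c in subs if latest.meta.year - c.meta.year <= 3]
    if len(window) == 1:
        return CountryEstimate(
            country, latest.estimate, (latest.meta.survey_id,),
            SINGLE_SUBNATIONAL, latest.meta.year,
        )
    pooled = pool_inverse_variance(window)
    return CountryEstimate(
        country,
        pooled,
        tuple(c.meta.survey_id for c in window),
        POOLED_SUBNATIONAL,
        latest.meta.year,
    )


def country_estimates(survey_estimates: list[SurveyEstimate]) -> list[CountryEstimate]:
    """Group by country and apply :func:`select_country_surveys` to each."""
    out = []
    by_country: dict[str, list[SurveyEstimate]] = {}
    for se in survey_estimates:
        by_country.setdefault(se.meta.country, []).append(se)
    for country in sorted(by_country):
        out.append(select_country_surveys(by_country[country]))
    return out


def group_summary(
    estimates: list[CountryEstimate],
    label_of,
) -> pd.DataFrame:
    """Median, IQR, range, n and year span per group label.

    Quantiles use linear interpolation between order statistics (the
    numpy/R type-7 default).  Empty labels are grouped under "" and a group
    with no members is simply absent.
    """
    groups: dict[str, list[CountryEstimate]] = {}
    for ce in estimates:
        groups.setdefault(str(label_of(ce)), []).append(ce)
    rows = []
    for label in sorted(groups):
        vals = np.array([ce.estimate.value for ce in groups[label]])
        years = [ce.year for ce in groups[label]]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "median": float(med),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "year_min": min(years),
                "year_max": max(years),
            }
        )
    return pd.DataFrame(rows)
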