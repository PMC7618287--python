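"""Sex-disparity effect measures and DerSimonian-Laird random-effects pooling.

Each survey yields a male-female risk difference (RD, percentage points) or
risk ratio (RR) in coverage, computed from sex-specific estimates that are
age-adjusted within sex.  Across surveys the effects are pooled with the
moment-based DerSimonian-Laird random-effects model:

    u_k   = 1 / se_k^2                         (fixed weights)
    e_bar = sum(u e) / sum(u)
    Q     = sum u_k (e_k - e_bar)^2
    tau^2 = max(0, (Q - (k-1)) / (sum u - sum u^2 / sum u))
    w_k   = 1 / (se_k^2 + tau^2)               (random-effects weights)

with a normal-approximation 95% CI on the pooled effect.  Risk ratios are
pooled on the log scale (delta-method SE) and exponentiated; risk
differences are pooled on the percent scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .classify import DEFAULT_CONFIG, IndicatorConfig
from .estimate import ECSC, Z95, Estimate, coverage_estimate
from .model import PopulationTable, Survey, UndefinedEstimateError

logger = logging.getLogger(__name__)

RD = "RD"
RR = "RR"


@dataclass(frozen=True)
class SexEffect:
    """One survey's male-female contrast in coverage.

    For RD, ``effect``/``se`` are on the percent scale.  For RR, ``effect``
    is the ratio itself while ``se`` is the delta-method SE of log(RR), the
    scale on which ratios are pooled.
    """

    survey_id: str
    measure: str  # RD | RR
    effect: float
    se: float
    male: Estimate
    female: Estimate

    def __post_init__(self) -> None:
        if self.measure not in (RD, RR):
            raise ValueError(f"measure must be RD or RR, got {self.measure!r}")
        if self.measure == RR and self.effect <= 0:
            raise ValueError("risk ratio must be positive")
        if self.measure == RD and not (-100.0 <= self.effect <= 100.0):
            raise ValueError("risk difference must lie in [-100, 100]")


@dataclass(frozen=True)
class PooledEffect:
    measure: str
    effect: float
    ci_low: float
    ci_high: float
    se: float      # on the pooling scale (log scale for RR)
    tau2: float    # between-study variance on the pooling scale
    k: int

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau^2 must be non-negative")
        if not (self.ci_low <= self.effect <= self.ci_high):
            raise ValueError("CI must contain the pooled effect")


def sex_contrast(
    male: Estimate, female: Estimate, measure: str = RD, survey_id: str = ""
) -> SexEffect:
    """Combine independent sex-specific estimates into an RD or RR effect.

    RD carries se = sqrt(se_M^2 + se_F^2); RR carries the delta-method SE of
    log(RR), sqrt((se_M/v_M)^2 + (se_F/v_F)^2).
    """
    if measure == RD:
        effect = male.value - female.value
        se = math.sqrt(male.se**2 + female.se**2)
    elif measure == RR:
        if female.value <= 0:
            raise UndefinedEstimateError("risk ratio undefined when female coverage is 0")
        if male.value <= 0:
            raise UndefinedEstimateError("log risk-ratio SE undefined when male coverage is 0")
        effect = male.value / female.value
        se = math.sqrt(
            (male.se / male.value) ** 2 + (female.se / female.value) ** 2
        )
    else:
        raise ValueError(f"measure must be RD or RR, got {measure!r}")
    return SexEffect(
        survey_id=survey_id, measure=measure, effect=effect, se=se,
        male=male, female=female,
    )


def sex_effect(
    survey: Survey,
    population: PopulationTable,
    cfg: IndicatorConfig = DEFAULT_CONFIG,
    indicator: str = ECSC,
    measure: str = RD,
) -> SexEffect:
    """Male-female RD or RR for one survey, age-adjusted within each sex."""
    male = coverage_estimate(survey, population, cfg, indicator=indicator, sex="M")
    female = coverage_estimate(survey, population, cfg, indicator=indicator, sex="F")
    return sex_contrast(male, female, measure, survey_id=survey.meta.survey_id)


def _dl_pool(e: np.ndarray, se: np.ndarray) -> tuple[float, float, float]:
    """DerSimonian-Laird pooled effect, SE and tau^2 on the given scale."""
    k = e.size
    u = 1.0 / se**2
    su = u.sum()
    e_bar = float(np.sum(u * e) / su)
    q = float(np.sum(u * (e - e_bar) ** 2))
    denom = su - float(np.sum(u**2)) / su
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * e) / w.sum())
    pooled_se = float(math.sqrt(1.0 / w.sum()))
    return pooled, pooled_se, tau2


def pool_random_effects(effects: list[SexEffect]) -> PooledEffect:
    """DL random-effects pooling of per-survey RDs or RRs.

    Zero-SE effects are rejected with a diagnostic; with a single remaining
    effect the pooling degenerates to that effect (tau^2 = 0) with a warning.
    RRs are pooled on the log scale and the result exponentiated.
    """
    if not effects:
        raise ValueError("no effects to pool")
    measures = {x.measure for x in effects}
    if len(measures) != 1:
        raise ValueError(f"cannot pool mixed measures {sorted(measures)}")
    measure = measures.pop()
    kept = []
    for x in effects:
        if x.se <= 0:
            logger.warning("rejecting zero-variance effect from %s", x.survey_id)
            continue
        kept.append(x)
    if not kept:
        raise ValueError("no effects with positive SE to pool")

    log_scale = measure == RR
    e = np.array([math.log(x.effect) if log_scale else x.effect for x in kept])
    se = np.array([x.se for x in kept])

    if len(kept) == 1:
        logger.warning("single study: random-effects pooling is a passthrough")
        pooled, pooled_se, tau2 = float(e[0]), float(se[0]), 0.0
    else:
        pooled, pooled_se, tau2 = _dl_pool(e, se)

    lo, hi = pooled - Z95 * pooled_se, pooled + Z95 * pooled_se
    if log_scale:
        effect, lo, hi = math.exp(pooled), math.exp(lo), math.exp(hi)
    else:
        effect = pooled
    return PooledEffect(
        measure=measure,
        effect=effect,
        ci_low=lo,
        ci_high=hi,
        se=pooled_se,
        tau2=tau2,
        k=len(kept),
    )
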