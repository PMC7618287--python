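"""Post-stratified coverage estimation with cluster-adjusted standard errors.

Coverage is a ratio of weighted counts.  Participants are grouped into the
eight age-sex strata, each stratum's counts are multiplied by an adjustment
factor w_s = N_s / n_s (census population over number examined), and

    coverage = 100 * sum_s w_s * numerator_s / sum_s w_s * denominator_s .

The standard error accounts for the two-stage cluster design with the
classical ratio-estimator variance over cluster totals: with c clusters and
weighted per-cluster pairs (y_i, x_i) and r = sum(y)/sum(x),

    se(r) = sqrt( (c/(c-1)) * sum_i (y_i - r x_i)^2 ) / sum_i x_i ,

algebraically equal to the textbook form (1/x_bar) * sqrt(sum resid^2 /
(c (c-1))).  Weights are applied at the participant level before summing
within cluster, so the SE reflects both the weighting and the clustering.
Confidence intervals are normal-approximation value +/- 1.96 se, clipped
to [0, 100].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import DEFAULT_CONFIG, IndicatorConfig, SurveyCounts, survey_counts
from .model import DesignError, PopulationTable, Survey, UndefinedEstimateError
from .vision import AGE_BANDS, OUTCOME_CUTS, SEXES, STRATA, SURGICAL_CUTS

logger = logging.getLogger(__name__)

Z95 = 1.96

CSC = "CSC"
ECSC = "eCSC"
ALL = "ALL"


@dataclass(frozen=True)
class Estimate:
    """A coverage point estimate on the percent scale with its design-based CI."""

    indicator: str            # CSC | eCSC
    sex: str                  # ALL | F | M
    value: float              # percent, in [0, 100]
    se: float                 # percent
    ci_low: float
    ci_high: float
    n_examined: int
    n_clusters: int
    weighted_num: float
    weighted_den: float
    config_label: str = ""
    weight_direction: str = "population/examined"

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValueError(f"coverage must lie in [0, 100], got {self.value}")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError("CI must contain the point estimate")

    def rounded(self, ndigits: int = 1) -> "Estimate":
        return replace(
            self,
            value=round(self.value, ndigits),
            se=round(self.se, ndigits),
            ci_low=round(self.ci_low, ndigits),
            ci_high=round(self.ci_high, ndigits),
        )


def cluster_se(y, x) -> float:
    """Ratio-estimator SE over cluster totals, on the percent scale.

    Parameters are per-cluster numerator (`y`) and denominator (`x`) totals
    (already weighted).  Degenerate clusters contribute (0, 0) pairs and are
    retained in the cluster count c, which is a property of the design.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    c = y.size
    if c < 2:
        raise DesignError("cluster SE requires at least 2 clusters")
    sx = x.sum()
    if sx <= 0:
        raise UndefinedEstimateError("zero weighted denominator across clusters")
    r = y.sum() / sx
    resid2 = float(np.sum((y - r * x) ** 2))
    return 100.0 * math.sqrt(c / (c - 1) * resid2) / sx


def adjustment_factors(
    counts: SurveyCounts | pd.DataFrame,
    population: PopulationTable,
    sex: str = ALL,
    empty_stratum: str = "collapse",
) -> pd.DataFrame:
    """Per-stratum post-stratification factors w_s = N_s / n_s.

    ``sex`` restricts to one sex's strata (age adjustment only), as used for
    sex-disaggregated estimates.  A stratum with census population but no
    examined participants has no defined factor; by default its population is
    collapsed into the adjacent age band of the same sex (toward younger,
    else older), conserving the census total; ``empty_stratum="error"``
    raises instead.

    Returns a frame with columns sex, age_band, N, n, w.
    """
    by_stratum = counts.by_stratum() if isinstance(counts, SurveyCounts) else counts
    n_map = {
        (r["sex"], r["age_band"]): int(r["examined"])
        for _, r in by_stratum.iterrows()
    }
    sexes = SEXES if sex == ALL else (sex,)
    N = {s: float(population.counts[s]) for s in STRATA if s[0] in sexes}
    n = {s: n_map.get(s, 0) for s in N}

    for s in list(N):
        if n[s] == 0 and N[s] > 0:
            if empty_stratum == "error":
                raise DesignError(f"no participants examined in stratum {s}")
            sx, band = s
            i = AGE_BANDS.index(band)
            neighbours = [b for b in (AGE_BANDS[i - 1] if i > 0 else None,
                                      AGE_BANDS[i + 1] if i < 3 else None) if b]
            target = next(((sx, b) for b in neighbours if n.get((sx, b), 0) > 0), None)
            if target is None:
                raise DesignError(f"cannot collapse empty stratum {s}: no occupied neighbour")
            logger.warning("collapsing empty stratum %s into %s", s, target)
            N[target] += N[s]
            N[s] = 0.0

    rows = []
    for s in N:
        w = N[s] / n[s] if n[s] > 0 else float("nan")
        rows.append({"sex": s[0], "age_band": s[1], "N": N[s], "n": n[s], "w": w})
    return pd.DataFrame(rows)


def _weighted_cluster_pairs(
    counts: SurveyCounts,
    weights: pd.DataFrame,
    numerator_col: str,
    sex: str,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    cells = counts.cells
    if sex != ALL:
        cells = cells[cells["sex"] == sex]
    w_map = {
        (r["sex"], r["age_band"]): r["w"]
        for _, r in weights.iterrows()
        if r["n"] > 0
    }
    key = list(zip(cells["sex"], cells["age_band"]))
    w = np.array([w_map.get(k, 0.0) for k in key], dtype=float)
    y = cells[numerator_col].to_numpy(dtype=float) * w
    x = cells["denom"].to_numpy(dtype=float) * w

    # every design cluster contributes, including those with no denominator
    # members (or none of this sex): (0, 0) pairs
    all_clusters = counts.cells["cluster_id"].astype(str).unique()
    g = pd.DataFrame({"cluster_id": cells["cluster_id"].astype(str), "y": y, "x": x})
    agg = g.groupby("cluster_id").sum().reindex(all_clusters, fill_value=0.0)
    return agg["y"].to_numpy(), agg["x"].to_numpy(), float(y.sum()), float(x.sum())


def coverage_estimate(
    survey: Survey,
    population: PopulationTable,
    cfg: IndicatorConfig = DEFAULT_CONFIG,
    indicator: str = ECSC,
    sex: str = ALL,
    empty_stratum: str = "collapse",
    counts: SurveyCounts | None = None,
) -> Estimate:
    """Age-sex post-stratified coverage estimate with cluster-adjusted CI.

    ``sex`` in {"ALL", "F", "M"}; sex-restricted runs age-adjust within that
    sex only.  Raises :class:`UndefinedEstimateError` when the weighted
    denominator is zero.
    """
    if indicator not in (CSC, ECSC):
        raise ValueError(f"indicator must be CSC or eCSC, got {indicator!r}")
    if counts is None:
        counts = survey_counts(survey, cfg)
    weights = adjustment_factors(counts, population, sex=sex, empty_stratum=empty_stratum)
    num_col = "csc_num" if indicator == CSC else "ecsc_num"
    y, x, wnum, wden = _weighted_cluster_pairs(counts, weights, num_col, sex)
    if wden <= 0:
        raise UndefinedEstimateError(
            f"weighted denominator is zero for indicator={indicator}, sex={sex}"
        )
    value = 100.0 * wnum / wden
    se = cluster_se(y, x)
    cells = counts.cells if sex == ALL else counts.cells[counts.cells["sex"] == sex]
    return Estimate(
        indicator=indicator,
        sex=sex,
        value=value,
        se=se,
        ci_low=max(0.0, value - Z95 * se),
        ci_high=min(100.0, value + Z95 * se),
        n_examined=int(cells["examined"].sum()),
        n_clusters=int(counts.cells["cluster_id"].astype(str).nunique()),
        weighted_num=wnum,
        weighted_den=wden,
        config_label=counts.config_label,
    )


def quality_gap(csc: float, ecsc: float) -> float:
    """Relative quality gap 100*(CSC - eCSC)/CSC, on percent inputs.

    The gap is the share of accessed surgery that failed the good-outcome
    threshold; lower is better.
    """
    if csc <= 0:
        raise UndefinedEstimateError("quality gap undefined when CSC is zero")
    if ecsc > csc + 1e-12:
        raise ValueError(f"eCSC ({ecsc}) cannot exceed CSC ({csc})")
    return 100.0 * ((csc - ecsc) / csc)


def threshold_matrix(
    survey: Survey,
    population: PopulationTable,
    surgical_thresholds=SURGICAL_CUTS,
    outcome_thresholds=OUTCOME_CUTS,
    base_cfg: IndicatorConfig = DEFAULT_CONFIG,
    sex: str = ALL,
) -> pd.DataFrame:
    """eCSC estimates over a grid of surgical x outcome thresholds.

    Within a fixed outcome threshold, eCSC is non-increasing as the surgical
    threshold relaxes from <3/60 to <6/12 (the denominator grows while the
    numerator is fixed).  Returns one row per grid cell with the estimate's
    fields flattened.
    """
    rows = []
    for ot in outcome_thresholds:
        for st in surgical_thresholds:
            cfg = replace(base_cfg, surgical_threshold=st, outcome_threshold=ot)
            est = coverage_estimate(survey, population, cfg, indicator=ECSC, sex=sex)
            rows.append(
                {
                    "surgical_threshold": st,
                    "outcome_threshold": ot,
                    "value": est.value,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "config": cfg.label,
                }
            )
    return pd.DataFrame(rows)
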