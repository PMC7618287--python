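"""Synthetic populations and two-stage cluster surveys with known truth.

The generator emulates the sampling frame of a rapid population-based eye
survey: adults aged 50+ living in clusters, a per-stratum probability of
developing operable cataract rising with age, surgical access given need
that differs by sex (log-odds offset) and age, a cluster-level random
effect on access inducing intra-cluster correlation, and a configurable
probability that surgery achieves a good presenting-VA outcome.  Every
classification branch — bilateral/unilateral surgery, residual operable
fellow eyes, unoperated operable cataract, non-cataract impairment — is
reachable and directly configurable.

Ground truth is never asserted from the configuration: it is enumerated by
running the person-level classifier over the full roster (a census), so the
estimation pipeline can be checked against exact truth.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` spawn keys, so the population and each
sampled survey replicate are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import DEFAULT_CONFIG, IndicatorConfig, classify_frame
from .estimate import quality_gap
from .model import PopulationTable, Survey, SurveyMeta, SURVEY_COLUMNS
from .vision import AGE_BANDS, RANK_TO_VA, SEXES

_BAND_AGES = {"50-59": (50, 59), "60-69": (60, 69), "70-79": (70, 79), "80+": (80, 94)}

#: conditional VA-category distributions (ranks 0 best .. 4 worst)
_OPERABLE_BCVA = ([2, 3, 4], [0.45, 0.25, 0.30])
_GOOD_PVA = ([0, 1], [0.70, 0.30])
_BAD_PVA = ([2, 3, 4], [0.50, 0.30, 0.20])
_SECOND_EYE_PVA = ([0, 1, 2, 3, 4], [0.40, 0.20, 0.20, 0.10, 0.10])
_OTHER_IMPAIR_BCVA = ([2, 3, 4], [0.50, 0.30, 0.20])


def _default_stratum_population() -> dict[tuple[str, str], int]:
    per_sex = {"50-59": 60_000, "60-69": 40_000, "70-79": 25_000, "80+": 10_000}
    return {(s, b): n for s in SEXES for b, n in per_sex.items()}


def _default_p_operable() -> dict[str, float]:
    return {"50-59": 0.05, "60-69": 0.12, "70-79": 0.25, "80+": 0.40}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic setting.

    Defaults mirror a mid-coverage survey setting: ~270k adults 50+ in the
    frame, cataract prevalence rising steeply with age, surgical access
    near half of need with a male advantage of 0.19 on the log-odds scale
    (about a 3-point eCSC risk difference between sexes), 75% of operated
    people achieving a 6/18 presenting-VA outcome (true eCSC close to 40%),
    and samples of 50 clusters x 60 participants (~3000, the field's
    typical survey size).
    """

    stratum_population: Mapping[tuple[str, str], int] = field(
        default_factory=_default_stratum_population
    )
    p_operable: Mapping[str, float] = field(default_factory=_default_p_operable)
    p_unilateral_need: float = 0.30
    access_logit: float = -0.20         # base log-odds of surgery given need
    access_sex_logodds: float = 0.19    # added for men
    access_age_logodds: float = 0.15    # added per age band above 50-59
    p_operated_bilateral: float = 0.60  # both eyes done, given surgery for bilateral need
    p_good_outcome: float = 0.75        # better operated eye presents 6/18 or better
    p_aphakia: float = 0.05             # operated eye left without implant
    p_other_impair: float = 0.08        # non-cataract bilateral impairment
    n_population_clusters: int = 400
    n_clusters: int = 50                # clusters sampled per survey
    cluster_size: int = 60              # participants sampled per cluster
    rho: float = 0.05                   # intra-cluster correlation of access
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.p_unilateral_need, self.p_operated_bilateral, self.p_good_outcome,
            self.p_aphakia, self.p_other_impair, *self.p_operable.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not (0.0 <= self.rho <= 0.3):
            raise ValueError("rho must lie in [0, 0.3]")
        if self.n_clusters < 2 or self.cluster_size < 1:
            raise ValueError("need >= 2 sampled clusters and cluster_size >= 1")
        if self.n_clusters > self.n_population_clusters:
            raise ValueError("cannot sample more clusters than the frame contains")

    @property
    def total_population(self) -> int:
        return int(sum(self.stratum_population.values()))


@dataclass(frozen=True)
class TruthSummary:
    """Exact census indicator values enumerated from a roster."""

    csc: float
    ecsc: float
    quality_gap: float
    csc_by_sex: Mapping[str, float]
    ecsc_by_sex: Mapping[str, float]
    rd: float  # male - female eCSC, percentage points
    rr: float  # male / female eCSC


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class TruePopulation:
    """Full synthetic roster with cluster assignments."""

    frame: pd.DataFrame  # canonical survey columns, participant_id = roster index
    scenario: ScenarioConfig

    @cached_property
    def _cluster_members(self) -> dict[str, np.ndarray]:
        groups = self.frame.groupby("cluster_id", sort=True).indices
        return {k: np.asarray(v) for k, v in groups.items()}

    def population_table(self) -> PopulationTable:
        ages = self.frame["age"].to_numpy()
        bands = np.select([ages < 60, ages < 70, ages < 80], AGE_BANDS[:3], AGE_BANDS[3])
        df = pd.DataFrame({"sex": self.frame["sex"], "age_band": bands})
        counts = df.value_counts().to_dict()
        return PopulationTable(
            {(s, b): int(counts.get((s, b), 0)) for s in SEXES for b in AGE_BANDS}
        )

    def census_survey(self, meta: SurveyMeta | None = None) -> Survey:
        """The whole roster as one survey (a census: every w_s = 1)."""
        if meta is None:
            meta = SurveyMeta(survey_id="census", country="Simland", year=2020)
        return Survey(frame=self.frame.copy(), meta=meta)

    def truth(self, cfg: IndicatorConfig = DEFAULT_CONFIG) -> TruthSummary:
        """Brute-force truth: classify every roster member, count, divide."""
        cls = classify_frame(self.frame, cfg)
        sex = self.frame["sex"].to_numpy(dtype=object)
        den = cls["in_denominator"].to_numpy()
        csc_n = cls["in_csc_numerator"].to_numpy()
        ecsc_n = cls["in_ecsc_numerator"].to_numpy()

        def rate(num, mask=None) -> float:
            if mask is not None:
                num, d = num & mask, den & mask
            else:
                d = den
            return 100.0 * num.sum() / d.sum() if d.sum() else float("nan")

        csc, ecsc = rate(csc_n), rate(ecsc_n)
        csc_sex = {s: rate(csc_n, sex == s) for s in SEXES}
        ecsc_sex = {s: rate(ecsc_n, sex == s) for s in SEXES}
        return TruthSummary(
            csc=float(csc),
            ecsc=float(ecsc),
            quality_gap=float(quality_gap(csc, ecsc)) if csc > 0 else float("nan"),
            csc_by_sex={k: float(v) for k, v in csc_sex.items()},
            ecsc_by_sex={k: float(v) for k, v in ecsc_sex.items()},
            rd=float(ecsc_sex["M"] - ecsc_sex["F"]),
            rr=float(ecsc_sex["M"] / ecsc_sex["F"]) if ecsc_sex["F"] > 0 else float("nan"),
        )


def truth(pop: TruePopulation, cfg: IndicatorConfig = DEFAULT_CONFIG) -> TruthSummary:
    return pop.truth(cfg)


def _draw_ranks(rng: np.random.Generator, n: int, dist) -> np.ndarray:
    vals, probs = dist
    return rng.choice(vals, size=n, p=probs) if n else np.empty(0, dtype=int)


def generate_population(scenario: ScenarioConfig) -> TruePopulation:
    """Draw a full roster of persons with eye states from the scenario."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0]))
    sc = scenario

    sexes, ages, band_idx = [], [], []
    for (s, b), n in sc.stratum_population.items():
        lo, hi = _BAND_AGES[b]
        sexes.append(np.full(n, s, dtype=object))
        ages.append(rng.integers(lo, hi + 1, size=n))
        band_idx.append(np.full(n, AGE_BANDS.index(b)))
    sex = np.concatenate(sexes)
    age = np.concatenate(ages)
    band = np.concatenate(band_idx)
    n = sex.size

    cluster = rng.integers(0, sc.n_population_clusters, size=n)
    if sc.rho > 0:
        sigma = math.sqrt(sc.rho / (1.0 - sc.rho) * math.pi**2 / 3.0)
        b_k = rng.normal(0.0, sigma, size=sc.n_population_clusters)
    else:
        b_k = np.zeros(sc.n_population_clusters)

    p_need = np.array([sc.p_operable[b] for b in AGE_BANDS])[band]
    need = rng.random(n) < p_need
    uni_need = need & (rng.random(n) < sc.p_unilateral_need)

    z = (
        sc.access_logit
        + sc.access_sex_logodds * (sex == "M")
        + sc.access_age_logodds * band
        + b_k[cluster]
    )
    operated = need & (rng.random(n) < _expit(z))
    bilat_surgery = operated & ~uni_need & (rng.random(n) < sc.p_operated_bilateral)
    good = operated & (rng.random(n) < sc.p_good_outcome)
    other_imp = ~need & (rng.random(n) < sc.p_other_impair)

    # which side carries the affected/operated eye in asymmetric persons
    right_first = rng.random(n) < 0.5

    # eye state codes: 0 healthy, 1 operable cataract, 2 operated, 3 other impairment
    state = {"r": np.zeros(n, dtype=int), "l": np.zeros(n, dtype=int)}
    first = {"r": right_first, "l": ~right_first}
    for side in ("r", "l"):
        f, o = first[side], ~first[side]
        st = state[side]
        st[other_imp] = 3
        st[need & ~operated & (~uni_need | f)] = 1       # unoperated need
        st[operated & f] = 2                             # primary operated eye
        st[operated & bilat_surgery & o] = 2             # second operated eye
        st[operated & ~bilat_surgery & ~uni_need & o] = 1  # residual operable fellow

    # per-eye VA ranks and codes
    pva = {"r": np.zeros(n, dtype=int), "l": np.zeros(n, dtype=int)}
    bcva = {"r": np.zeros(n, dtype=int), "l": np.zeros(n, dtype=int)}
    lens = {
        "r": np.full(n, "PHAKIC_CLEAR", dtype=object),
        "l": np.full(n, "PHAKIC_CLEAR", dtype=object),
    }
    cause = {"r": np.full(n, "NONE", dtype=object), "l": np.full(n, "NONE", dtype=object)}

    for side in ("r", "l"):
        st, f = state[side], first[side]

        m = st == 1
        r = _draw_ranks(rng, int(m.sum()), _OPERABLE_BCVA)
        bcva[side][m] = r
        pva[side][m] = r
        lens[side][m] = "PHAKIC_CATARACT"
        cause[side][m] = "CATARACT"

        m = st == 3
        r = _draw_ranks(rng, int(m.sum()), _OTHER_IMPAIR_BCVA)
        bcva[side][m] = r
        pva[side][m] = r
        cause[side][m] = "OTHER"

        m = st == 2
        primary = m & f
        second = m & ~f
        pg, pb = primary & good, primary & ~good
        pva[side][pg] = _draw_ranks(rng, int(pg.sum()), _GOOD_PVA)
        pva[side][pb] = _draw_ranks(rng, int(pb.sum()), _BAD_PVA)
        sg, sb = second & good, second & ~good
        pva[side][sg] = _draw_ranks(rng, int(sg.sum()), _SECOND_EYE_PVA)
        pva[side][sb] = _draw_ranks(rng, int(sb.sum()), _BAD_PVA)
        bcva[side][m] = np.maximum(pva[side][m] - 1, 0)
        aph = m & (rng.random(n) < sc.p_aphakia)
        lens[side][m] = "PSEUDOPHAKIA"
        lens[side][aph] = "APHAKIA"
        cause[side][m] = np.where(pva[side][m] <= 1, "NONE", "OTHER")

    rank_code = np.array([RANK_TO_VA[i].value for i in range(5)], dtype=object)
    width = len(str(sc.n_population_clusters - 1))
    frame = pd.DataFrame(
        {
            "participant_id": np.arange(n).astype(str),
            "cluster_id": np.char.add("c", np.char.zfill(cluster.astype(str), width)),
            "age": age,
            "sex": sex,
            "r_lens": lens["r"],
            "l_lens": lens["l"],
            "r_pva": rank_code[pva["r"]],
            "l_pva": rank_code[pva["l"]],
            "r_bcva": rank_code[bcva["r"]],
            "l_bcva": rank_code[bcva["l"]],
            "r_cause": cause["r"],
            "l_cause": cause["l"],
        },
        columns=list(SURVEY_COLUMNS),
    )
    return TruePopulation(frame=frame, scenario=scenario)


def sample_survey(
    pop: TruePopulation,
    scenario: ScenarioConfig | None = None,
    replicate: int = 0,
    meta: SurveyMeta | None = None,
) -> tuple[Survey, PopulationTable]:
    """Two-stage cluster sample: c clusters, then m persons per cluster.

    Each ``replicate`` index yields an independent, reproducible survey from
    the same roster.  Returns the survey plus the roster's stratum
    population table (the census the estimates are post-stratified to).
    """
    sc = scenario or pop.scenario
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 1, replicate]))
    members = pop._cluster_members
    cluster_ids = sorted(members)
    chosen = rng.choice(len(cluster_ids), size=sc.n_clusters, replace=False)
    idx_parts = []
    for ci in sorted(chosen):
        pool_idx = members[cluster_ids[ci]]
        if pool_idx.size < sc.cluster_size:
            raise ValueError(
                f"cluster {cluster_ids[ci]} has {pool_idx.size} persons "
                f"< cluster_size {sc.cluster_size}"
            )
        idx_parts.append(rng.choice(pool_idx, size=sc.cluster_size, replace=False))
    idx = np.concatenate(idx_parts)
    frame = pop.frame.iloc[idx].reset_index(drop=True)
    if meta is None:
        meta = SurveyMeta(
            survey_id=f"sim-{sc.seed}-{replicate}", country="Simland", year=2020
        )
    return Survey(frame=frame, meta=meta), pop.population_table()


def small_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """A down-scaled scenario (~27k roster) for fast tests and examples."""
    per_sex = {"50-59": 6000, "60-69": 4000, "70-79": 2500, "80+": 1000}
    defaults = dict(
        stratum_population={(s, b): n for s in SEXES for b, n in per_sex.items()},
        n_population_clusters=120,
        n_clusters=30,
        cluster_size=40,
        seed=seed,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)
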