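"""End-to-end pipeline driver, run configuration and table rendering.

``run_pipeline`` executes read → classify → estimate → select/pool →
summarise → (optional) sex-gap meta-analysis over a set of survey inputs
and returns a :class:`ReportBundle` of publication-style tables plus a run
manifest (package version, config hash, input hashes, seed).  Nothing is
written until every stage has succeeded, so a failed run leaves no partial
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import IndicatorConfig, survey_counts
from .estimate import CSC, ECSC, Estimate, coverage_estimate, quality_gap, threshold_matrix
from .io import read_meta, read_population, read_survey
from .meta import RD, RR, pool_random_effects, sex_effect
from .model import PopulationTable, Survey, UndefinedEstimateError
from .pool import SurveyEstimate, country_estimates, group_summary


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class SurveyInput:
    survey: Survey
    population: PopulationTable


@dataclass
class RunConfig:
    """Validated run configuration (fully serialised into every manifest)."""

    inputs: list[dict] = field(default_factory=list)  # {survey, population, meta} paths
    indicator: IndicatorConfig = field(default_factory=IndicatorConfig)
    sex_gap: bool = True
    thresholds: bool = True
    journal_style: bool = False
    seed: int = 0
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        ind = IndicatorConfig(**data.pop("indicator", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(indicator=ind, **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ReportBundle:
    estimates: pd.DataFrame         # per-survey CSC/eCSC x ALL/F/M
    survey_summary: pd.DataFrame    # per-survey CSC, eCSC, quality gap
    countries: pd.DataFrame
    groups: pd.DataFrame
    thresholds: pd.DataFrame | None
    sex_gap: dict | None
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "estimates": self.estimates,
            "survey_summary": self.survey_summary,
            "countries": self.countries,
            "groups": self.groups,
        }
        if self.thresholds is not None:
            out["thresholds"] = self.thresholds
        return out


def format_estimate(value: float, ci_low: float, ci_high: float, style: str = "ascii") -> str:
    """Render "value% (95% CI low-high)" to 1 decimal.

    ``style="journal"`` uses the mid-dot decimal separator and an en dash.
    """
    s = f"{value:.1f}% (95% CI {ci_low:.1f}-{ci_high:.1f})"
    if style == "journal":
        s = s.replace(".", "·").replace("-", "–")
    elif style != "ascii":
        raise ValueError(f"unknown style {style!r}")
    return s


def _estimate_row(est: Estimate, meta) -> dict:
    row = dataclasses.asdict(est)
    row.update(
        survey_id=meta.survey_id, country=meta.country, year=meta.year,
        scope=meta.scope, region_label=meta.region_label, income_label=meta.income_label,
    )
    return row


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    loaded_inputs: list[SurveyInput] | None = None,
) -> ReportBundle:
    """Execute the full pipeline and return the report bundle.

    ``loaded_inputs`` lets callers (tests, simulations) pass in-memory
    surveys instead of file paths; file hashes are then omitted from the
    manifest.
    """
    stage = "read"
    try:
        if loaded_inputs is None:
            loaded_inputs = []
            input_hashes = {}
            for item in config.inputs:
                meta = read_meta(item["meta"]) if item.get("meta") else None
                survey = read_survey(item["survey"], meta=meta)
                pop = read_population(item["population"])
                loaded_inputs.append(SurveyInput(survey=survey, population=pop))
                for key in ("survey", "population", "meta"):
                    if item.get(key):
                        input_hashes[str(item[key])] = _sha256(item[key])
        else:
            input_hashes = {}
        if not loaded_inputs:
            raise ValueError("no survey inputs configured")

        stage = "classify/estimate"
        cfg = config.indicator
        est_rows, summary_rows, survey_estimates = [], [], []
        effects_rd, effects_rr = [], []
        for si in loaded_inputs:
            counts = survey_counts(si.survey, cfg)
            per_sex: dict[tuple[str, str], Estimate] = {}
            for indicator in (CSC, ECSC):
                for sex in ("ALL", "F", "M"):
                    try:
                        est = coverage_estimate(
                            si.survey, si.population, cfg,
                            indicator=indicator, sex=sex, counts=counts,
                        )
                    except UndefinedEstimateError:
                        continue
                    per_sex[(indicator, sex)] = est
                    est_rows.append(_estimate_row(est, si.survey.meta))
            csc = per_sex.get((CSC, "ALL"))
            ecsc = per_sex.get((ECSC, "ALL"))
            if csc is not None and ecsc is not None:
                summary_rows.append(
                    {
                        "survey_id": si.survey.meta.survey_id,
                        "country": si.survey.meta.country,
                        "year": si.survey.meta.year,
                        "csc": round(csc.value, 1),
                        "ecsc": round(ecsc.value, 1),
                        "quality_gap": round(quality_gap(csc.value, ecsc.value), 1),
                        "n_examined": csc.n_examined,
                        "n_clusters": csc.n_clusters,
                        "config": cfg.label,
                        **{f"excluded_{k}": v for k, v in counts.exclusions.items()},
                    }
                )
                survey_estimates.append(SurveyEstimate(estimate=ecsc, meta=si.survey.meta))

        stage = "select/pool"
        ces = country_estimates(survey_estimates)
        country_rows = [
            {
                "country": ce.country,
                "year": ce.year,
                "method": ce.method,
                "provenance": ";".join(ce.provenance),
                **dataclasses.asdict(ce.estimate),
            }
            for ce in ces
        ]

        stage = "summarise"
        groups = []
        for label_name, label_fn in (
            ("region", lambda ce: _meta_label(survey_estimates, ce, "region_label")),
            ("income", lambda ce: _meta_label(survey_estimates, ce, "income_label")),
        ):
            g = group_summary(ces, label_fn)
            if not g.empty:
                g.insert(0, "grouping", label_name)
                groups.append(g)
        groups_df = pd.concat(groups, ignore_index=True) if groups else pd.DataFrame()

        stage = "thresholds"
        thresholds_df = None
        if config.thresholds:
            parts = []
            for si in loaded_inputs:
                t = threshold_matrix(si.survey, si.population, base_cfg=cfg)
                t.insert(0, "survey_id", si.survey.meta.survey_id)
                parts.append(t)
            thresholds_df = pd.concat(parts, ignore_index=True)

        stage = "sex-gap"
        sex_gap = None
        if config.sex_gap:
            per_study = []
            for si in loaded_inputs:
                try:
                    effects_rd.append(sex_effect(si.survey, si.population, cfg, measure=RD))
                    effects_rr.append(sex_effect(si.survey, si.population, cfg, measure=RR))
                except UndefinedEstimateError:
                    continue
            for x in effects_rd:
                per_study.append(
                    {
                        "survey_id": x.survey_id, "measure": x.measure,
                        "effect": x.effect, "se": x.se,
                        "male": x.male.value, "female": x.female.value,
                    }
                )
            sex_gap = {"per_study": per_study}
            if len(effects_rd) >= 2:
                for name, effs in (("RD", effects_rd), ("RR", effects_rr)):
                    p = pool_random_effects(effs)
                    sex_gap[f"pooled_{name.lower()}"] = dataclasses.asdict(p)

        stage = "manifest"
        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        manifest = {
            "package": "ecsc",
            "version": __version__,
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "input_sha256": input_hashes,
            "seed": config.seed,
            "n_surveys": len(loaded_inputs),
        }
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError(f"[stage: {stage}] {exc}") from exc

    return ReportBundle(
        estimates=pd.DataFrame(est_rows),
        survey_summary=pd.DataFrame(summary_rows),
        countries=pd.DataFrame(country_rows),
        groups=groups_df,
        thresholds=thresholds_df,
        sex_gap=sex_gap,
        manifest=manifest,
    )


def _meta_label(survey_estimates, ce, attr: str) -> str:
    for se in survey_estimates:
        if se.meta.survey_id in ce.provenance:
            return getattr(se.meta, attr)
    return ""


def render_tables(bundle: ReportBundle, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
    """Write the bundle's tables (plus sex-gap JSON and manifest) to disk."""
    if fmt not in ("csv", "markdown"):
        raise ValueError(f"unknown format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in bundle.tables().items():
        df = df.copy()
        for col in df.select_dtypes("float").columns:
            df[col] = df[col].round(1)
        if fmt == "csv":
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.md"
            p.write_text(df.to_markdown(index=False) if hasattr(df, "to_markdown") else str(df))
        written.append(p)
    if bundle.sex_gap is not None:
        p = out_dir / "sex_gap.json"
        p.write_text(json.dumps(bundle.sex_gap, indent=2, default=str))
        written.append(p)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(bundle.manifest, indent=2, default=str))
    written.append(p)
    return written
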