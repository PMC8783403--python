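"""Configured end-to-end runs: simulate -> estimate -> measure -> trend -> report.

One YAML config drives the whole analysis.  Each survey either points at a
microdata CSV or embeds a population + sample-design specification to
simulate; the pipeline then writes, per survey and indicator, the
disaggregation table, the summary-measure table with bootstrap uncertainty
intervals, cross-survey trend classifications, per-dimension trend figures,
and a JSON run manifest holding every seed and setting needed to reproduce
the run.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__  # noqa: E402
from .datamodel import (DimensionSpec, IndicatorSpec, as_indicator,
                        default_dimensions, load_schema, read_microdata,
                        write_microdata)
from .estimation import disaggregate
from .exceptions import ConfigurationError, PipelineError, SchemaCompatibilityError
from .measures import bootstrap_measures
from .synthetic import (PopulationConfig, ProbabilityMap, RegionConfig,
                        SampleDesignConfig, draw_survey_sample,
                        generate_population)
from .trends import trend_table

log = logging.getLogger("equimeasure")

ALL_STAGES = ("simulate", "estimate", "measure", "trend", "report")
_FLOAT_FMT = "%.10g"  # fixed float formatting keeps reruns byte-identical


def derive_seed(seed: int, *keys: str) -> int:
    """Deterministic child seed (< 2^31) for a named pipeline stage."""
    spawn = tuple(zlib.crc32(k.encode()) for k in keys)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn)
    return int(ss.generate_state(1)[0] % (2 ** 31))


def population_config_from_dict(d: Mapping[str, Any]) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from a YAML-style mapping."""
    d = dict(d)
    regions = tuple(
        RegionConfig(r["name"], float(r["share"]), float(r["urban_share"]))
        for r in d.pop("regions"))
    sba = d.pop("sba_prob")
    nmr = d.pop("nmr_prob")
    return PopulationConfig(
        regions=regions,
        education_dist={k: tuple(v) for k, v in d.pop("education_dist").items()},
        sba_prob=ProbabilityMap(**sba) if isinstance(sba, Mapping) else sba,
        nmr_prob=ProbabilityMap(**nmr) if isinstance(nmr, Mapping) else nmr,
        **d)


@dataclass
class SurveySpec:
    """One survey in the pipeline: real microdata or a simulation recipe."""

    year: int
    microdata: str | None = None
    schema: str | None = None
    population: Mapping[str, Any] | None = None
    design: Mapping[str, Any] | None = None
    indicators: Sequence[str] | None = None  # None -> pipeline default

    def __post_init__(self):
        if (self.microdata is None) == (self.population is None):
            raise ConfigurationError(
                f"survey {self.year}: give exactly one of 'microdata' or "
                "'population'")
        if self.population is not None and self.design is None:
            raise ConfigurationError(
                f"survey {self.year}: a simulated survey needs a 'design'")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML via :func:`load_config`."""

    surveys: Sequence[SurveySpec]
    indicators: Sequence[str] = ("sba", "nmr")
    bootstrap_reps: int = 1000
    seed: int = 0
    output_dir: str = "equimeasure_out"
    sba_window_years: int | None = None
    sba_denominator: str = "all_births"
    dimensions: Mapping[int, Sequence[DimensionSpec]] | None = None

    def survey_indicators(self, survey: SurveySpec) -> list[IndicatorSpec]:
        names = survey.indicators if survey.indicators is not None else self.indicators
        return [as_indicator(n) for n in names]

    def survey_dimensions(self, survey: SurveySpec,
                          ind: IndicatorSpec) -> list[DimensionSpec]:
        if self.dimensions and survey.year in self.dimensions:
            dims = list(self.dimensions[survey.year])
            if ind.name != "nmr":
                dims = [d for d in dims if d.name != "child_sex"]
            return dims
        return default_dimensions(survey.year, ind)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    surveys = [SurveySpec(**s) for s in raw.pop("surveys")]
    return PipelineConfig(surveys=surveys, **raw)


def render_trend_figure(
    disagg_by_year: Mapping[int, pd.DataFrame],
    dimension: DimensionSpec,
    indicator: IndicatorSpec | str,
    path: str | Path,
) -> Path | None:
    """Line plot of subgroup estimates over survey years with UI bands.

    One line per subgroup; missing subgroup-year cells leave gaps.  With a
    single survey the figure is skipped with a warning.
    """
    ind = as_indicator(indicator)
    years = sorted(disagg_by_year)
    if len(years) < 2:
        warnings.warn("trend figure needs at least 2 surveys; skipped",
                      stacklevel=2)
        return None
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for level in dimension.levels:
        xs, ys, los, his = [], [], [], []
        for y in years:
            frame = disagg_by_year[y]
            row = frame[(frame["dimension"] == dimension.name)
                        & (frame["subgroup"] == level)]
            if row.empty or not np.isfinite(row["estimate"].iloc[0]):
                xs.append(y)
                ys.append(np.nan)
                los.append(np.nan)
                his.append(np.nan)
                continue
            xs.append(y)
            ys.append(float(row["estimate"].iloc[0]))
            los.append(float(row["ui_low"].iloc[0]))
            his.append(float(row["ui_high"].iloc[0]))
        line, = ax.plot(xs, ys, marker="o", label=level)
        ax.fill_between(xs, los, his, alpha=0.15, color=line.get_color())
    ax.set_xticks(years)
    unit = "%" if ind.scale == "percent" else "per 1000 live births"
    ax.set_ylabel(f"{ind.name.upper()} ({unit})")
    ax.set_xlabel("survey year")
    ax.set_title(f"{ind.name.upper()} by {dimension.name}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = ALL_STAGES
                 ) -> dict:
    """Execute the configured analysis and write its output bundle.

    Returns the run manifest (also written as ``manifest.json``).  A failing
    stage writes a manifest marked ``incomplete`` naming the stage and
    survey year, then raises :class:`PipelineError`.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    manifest: dict[str, Any] = {
        "package": "equimeasure", "version": __version__,
        "seed": config.seed, "bootstrap_reps": config.bootstrap_reps,
        "sba_window_years": config.sba_window_years,
        "sba_denominator": config.sba_denominator,
        "stages": list(stages), "status": "incomplete",
        "surveys": {}, "outputs": [], "derived_seeds": {},
    }

    def _write_manifest():
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")

    def _fail(stage: str, year, exc: Exception):
        manifest["error"] = {"stage": stage, "survey_year": year,
                             "message": str(exc)}
        _write_manifest()
        raise PipelineError(
            f"stage {stage!r} failed for survey {year}: {exc}") from exc

    def _save(frame: pd.DataFrame, name: str):
        frame.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"].append(name)

    data: dict[int, pd.DataFrame] = {}
    disagg: dict[tuple[str, int], pd.DataFrame] = {}
    measures: dict[tuple[str, int], pd.DataFrame] = {}

    # --- data stage: load or simulate every survey
    for survey in config.surveys:
        year = survey.year
        try:
            if survey.microdata is not None:
                schema = load_schema(survey.schema) if survey.schema else None
                frame, report = read_microdata(survey.microdata, schema)
                log.info("survey %s: read %d births (%d dropped)",
                         year, report.n_kept, report.n_dropped)
                manifest["surveys"][str(year)] = {
                    "source": survey.microdata, "n_births": report.n_kept,
                    "n_dropped": report.n_dropped}
            else:
                pop_seed = derive_seed(config.seed, f"population/{year}")
                smp_seed = derive_seed(config.seed, f"sample/{year}")
                manifest["derived_seeds"][f"population/{year}"] = pop_seed
                manifest["derived_seeds"][f"sample/{year}"] = smp_seed
                pop_cfg = population_config_from_dict(
                    {**survey.population, "survey_year": year})
                population = generate_population(pop_cfg, pop_seed)
                design = SampleDesignConfig(**{**survey.design, "seed": smp_seed})
                frame = draw_survey_sample(population, design)
                frame = frame.drop(columns=["true_p_sba", "true_p_death"])
                log.info("survey %s: simulated %d births in %d clusters",
                         year, len(frame), frame["cluster_id"].nunique())
                manifest["surveys"][str(year)] = {
                    "source": "simulated", "n_births": len(frame),
                    "population_seed": pop_seed, "sample_seed": smp_seed}
                if "simulate" in stages:
                    name = f"microdata_{year}.csv"
                    write_microdata(frame, out / name)
                    manifest["outputs"].append(name)
                    truth_name = f"ground_truth_{year}.csv"
                    population.ground_truth.to_csv(
                        out / truth_name, index=False, float_format=_FLOAT_FMT)
                    manifest["outputs"].append(truth_name)
            data[year] = frame
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with context
            _fail("simulate" if survey.microdata is None else "load", year, exc)

    # --- estimation and measures
    for survey in config.surveys:
        year = survey.year
        for ind in config.survey_indicators(survey):
            window = (config.sba_window_years if ind.name == "sba" else None)
            dims = config.survey_dimensions(survey, ind)
            try:
                if "estimate" in stages or "measure" in stages \
                        or "trend" in stages or "report" in stages:
                    tables = []
                    for dim in dims:
                        t = disaggregate(
                            data[year], ind, dim, window_years=window,
                            denominator=config.sba_denominator)
                        tables.append(t)
                    combined = pd.concat(tables, ignore_index=True)
                    combined["survey_year"] = year
                    disagg[(ind.name, year)] = combined
                    if "estimate" in stages:
                        _save(combined, f"disaggregation_{ind.name}_{year}.csv")
            except Exception as exc:  # noqa: BLE001
                _fail("estimate", year, exc)
            try:
                if "measure" in stages or "trend" in stages:
                    rows = []
                    for dim in dims:
                        b_seed = derive_seed(
                            config.seed, f"bootstrap/{year}/{ind.name}/{dim.name}")
                        manifest["derived_seeds"][
                            f"bootstrap/{year}/{ind.name}/{dim.name}"] = b_seed
                        for r in bootstrap_measures(
                                data[year], ind, dim, B=config.bootstrap_reps,
                                seed=b_seed, window_years=window,
                                denominator=config.sba_denominator,
                                survey_year=year, on_undefined="skip"):
                            rows.append({
                                "dimension": r.dimension, "measure": r.measure,
                                "value": r.value, "ui_low": r.ui_low,
                                "ui_high": r.ui_high,
                                "reference": r.reference_subgroup,
                                "comparator": r.comparator_subgroup,
                                "survey_year": year})
                    mtable = pd.DataFrame(rows)
                    measures[(ind.name, year)] = mtable
                    if "measure" in stages:
                        _save(mtable, f"measures_{ind.name}_{year}.csv")
            except Exception as exc:  # noqa: BLE001
                _fail("measure", year, exc)

    # --- trends
    if "trend" in stages:
        for ind_name in {k[0] for k in measures}:
            try:
                years = sorted(y for (i, y) in measures if i == ind_name)
                rows = []
                for i, ya in enumerate(years):
                    for yb in years[i + 1:]:
                        ta, tb = measures[(ind_name, ya)], measures[(ind_name, yb)]
                        for dim_name in sorted(set(ta["dimension"])
                                               & set(tb["dimension"])):
                            la = _dimension_levels(config, ya, ind_name, dim_name)
                            lb = _dimension_levels(config, yb, ind_name, dim_name)
                            try:
                                part = trend_table(
                                    {ya: ta[ta["dimension"] == dim_name],
                                     yb: tb[tb["dimension"] == dim_name]},
                                    levels_by_year={ya: la, yb: lb})
                            except SchemaCompatibilityError as exc:
                                log.warning("trend %s %s %s-%s skipped: %s",
                                            ind_name, dim_name, ya, yb, exc)
                                continue
                            rows.append(part)
                if rows:
                    table = pd.concat(rows, ignore_index=True)
                    _save(table, f"trends_{ind_name}.csv")
            except Exception as exc:  # noqa: BLE001
                _fail("trend", None, exc)

    # --- figures
    if "report" in stages:
        for ind_name in {k[0] for k in disagg}:
            ind = as_indicator(ind_name)
            years = sorted(y for (i, y) in disagg if i == ind_name)
            by_year = {y: disagg[(ind_name, y)] for y in years}
            dim_names = sorted({d for f in by_year.values()
                                for d in f["dimension"].unique()})
            for dim_name in dim_names:
                dim = _find_dimension(config, years, ind_name, dim_name)
                try:
                    p = render_trend_figure(
                        by_year, dim, ind, out / f"figure_{ind_name}_{dim_name}.png")
                    if p is not None:
                        manifest["outputs"].append(p.name)
                except Exception as exc:  # noqa: BLE001
                    _fail("report", None, exc)

    manifest["status"] = "complete"
    _write_manifest()
    manifest["outputs"].append("manifest.json")
    return manifest


def _survey_by_year(config: PipelineConfig, year: int) -> SurveySpec:
    return next(s for s in config.surveys if s.year == year)


def _dimension_levels(config, year, ind_name, dim_name):
    survey = _survey_by_year(config, year)
    for d in config.survey_dimensions(survey, as_indicator(ind_name)):
        if d.name == dim_name:
            return d.levels
    return ()


def _find_dimension(config, years, ind_name, dim_name) -> DimensionSpec:
    # for figures, prefer the widest schema (8 regions over 5)
    best = None
    for y in years:
        survey = _survey_by_year(config, y)
        for d in config.survey_dimensions(survey, as_indicator(ind_name)):
            if d.name == dim_name and (best is None
                                       or len(d.levels) > len(best.levels)):
                best = d
    if best is None:
        raise PipelineError(f"dimension {dim_name!r} not configured")
    return best
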