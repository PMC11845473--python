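"""Orchestration of the analysis stages from a single configuration.

Four stages, all configurations of the same machinery:

* **screening** — one single-factor model (factor + year dummy) per candidate
  covariate; factors whose slope's 95% CrI excludes 0 are flagged *selected*
  and feed the multivariable stage.
* **multivariable** — the year-adjusted comparison: all selected factors plus
  the year dummy, per service and service-quality level.
* **improvement** — the attributable-proportion regression on 2000–2020 mean
  covariates for every factor, no dummy.
* **descriptive** — population-weighted global coverage per ladder level.

Stages are independent: on the same inputs they can run in any order with
identical results (each fit derives its own seed from the run seed and the
model's labels, not from execution order).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bayes_logistic import McmcConfig, ModelSpec, fit, summarize
from .improvement import build_improvement_dataset
from .panel_io import (
    Dialect,
    LoadReport,
    carry_democracy_2006_to_2000,
    read_access_panel,
    read_covariates,
    with_basic_or_higher,
    write_result_table,
)
from .preprocess import FactorSpec, build_dataset, compute_vif

logger = logging.getLogger("washtrends")

DEFAULT_CANDIDATES = ("gdp_pc", "urban_pop_rate", "democracy_index", "renewable_water_pc")
DEFAULT_SELECTED = ("gdp_pc", "urban_pop_rate", "democracy_index")


def _stage_seed(base_seed: int, *labels) -> int:
    """Deterministic per-model seed independent of stage execution order."""
    tag = "|".join(str(x) for x in labels)
    return (int(base_seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass
class AnalysisRequest:
    stage: str  # screening | multivariable | improvement | descriptive
    service: str = "drinking_water"
    quality: str = "basic_or_higher"
    area: str = "total"
    year_pair: tuple[int, int] = (2000, 2020)
    factors: tuple[str, ...] | None = None
    gdp_variant: str = "gdp_pc"

    def resolved_factors(self) -> tuple[str, ...]:
        if self.factors is not None:
            base = self.factors
        elif self.stage == "screening":
            base = DEFAULT_CANDIDATES
        elif self.stage == "improvement":
            base = DEFAULT_CANDIDATES
        elif self.area in ("urban", "rural"):
            # area-specific runs add renewable water as a fourth factor
            base = DEFAULT_CANDIDATES
        else:
            base = DEFAULT_SELECTED
        if self.gdp_variant == "gdp_ppp_pc":
            base = tuple("gdp_ppp_pc" if f == "gdp_pc" else f for f in base)
        return base


@dataclass
class RunConfig:
    access_path: str | None = None
    covariates_path: str | None = None
    dialect: Dialect = field(default_factory=Dialect)
    analyses: list[AnalysisRequest] = field(default_factory=list)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    aggregation_policy: str = "cumulative"
    outdir: str = "results"
    seed: int = 0
    strict: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        dialect = Dialect(**raw.pop("dialect", {}))
        analyses = [
            AnalysisRequest(
                **{**a, "year_pair": tuple(a.get("year_pair", (2000, 2020))),
                   "factors": tuple(a["factors"]) if a.get("factors") else None}
            )
            for a in raw.pop("analyses", [])
        ]
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        return cls(dialect=dialect, analyses=analyses, mcmc=mcmc, **raw)


def load_panels(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, LoadReport]:
    """Read, harmonize and aggregate the input panels per the run config."""
    report = LoadReport()
    access, a_rep = read_access_panel(config.access_path, config.dialect)
    cov, c_rep = read_covariates(config.covariates_path, Dialect(delimiter=config.dialect.delimiter))
    report.messages = a_rep.messages + c_rep.messages
    report.n_read = a_rep.n_read + c_rep.n_read
    report.n_dropped_missing = a_rep.n_dropped_missing + c_rep.n_dropped_missing
    cov, n_carried = carry_democracy_2006_to_2000(cov, report)
    access = with_basic_or_higher(access, policy=config.aggregation_policy)
    logger.info("loaded %d records; carried %d democracy values", report.n_read, n_carried)
    return access, cov, report


def _summary_with_meta(result, model_label: str) -> pd.DataFrame:
    s = summarize(result)
    s.insert(0, "model", model_label)
    s["converged"] = result.converged
    s["n_rows"] = result.n_rows
    s["n_countries"] = max(result.n_countries_per_year.values())
    return s


def run_screening(access, cov, request: AnalysisRequest, mcmc: McmcConfig, seed: int) -> pd.DataFrame:
    """Single-factor screening fits; flags factors whose slope CrI excludes 0."""
    factors = request.resolved_factors()
    if not factors:
        raise ValueError("empty factor list for screening")
    tables = []
    for name in factors:
        dataset = build_dataset(
            access, cov, request.service, request.quality, request.area,
            request.year_pair, [FactorSpec(name)],
        )
        spec = ModelSpec(
            factor_names=(name,), include_dummy=True,
            mcmc=dataclasses.replace(
                mcmc, seed=_stage_seed(seed, "screening", request.service, request.quality,
                                       request.area, request.year_pair, name)
            ),
        )
        result = fit(dataset, spec)
        table = _summary_with_meta(result, f"screening:{name}")
        sig = table.set_index("parameter").loc[name, "significant"]
        table["selected"] = [p == name and sig for p in table["parameter"]]
        tables.append(table)
        logger.info("screening %s: slope significant=%s", name, bool(sig))
    return pd.concat(tables, ignore_index=True)


def selected_factors(screening_table: pd.DataFrame) -> list[str]:
    sel = screening_table[screening_table["selected"]]
    return list(dict.fromkeys(sel["parameter"]))


def run_multivariable(access, cov, request: AnalysisRequest, mcmc: McmcConfig, seed: int):
    """Year-adjusted multivariable fit; returns (summary table, VIF series)."""
    factors = request.resolved_factors()
    dataset = build_dataset(
        access, cov, request.service, request.quality, request.area,
        request.year_pair, [FactorSpec(f) for f in factors],
    )
    spec = ModelSpec(
        factor_names=tuple(factors), include_dummy=True,
        mcmc=dataclasses.replace(
            mcmc, seed=_stage_seed(seed, "multivariable", request.service, request.quality,
                                   request.area, request.year_pair, factors)
        ),
    )
    result = fit(dataset, spec)
    label = f"multivariable:{request.service}:{request.quality}:{request.area}"
    table = _summary_with_meta(result, label)
    vif = compute_vif(dataset.design_matrix()[:, 1:], labels=list(factors) + ["year_dummy"])
    return table, vif


def run_improvement(access, cov, request: AnalysisRequest, mcmc: McmcConfig, seed: int):
    """Attributable-proportion regression; returns (improvement table, summary, VIF)."""
    factors = request.resolved_factors()
    dataset, imp_table = build_improvement_dataset(
        access, cov, request.service, request.quality,
        [FactorSpec(f) for f in factors], request.year_pair,
    )
    excluded = imp_table[imp_table["status"] != "included"]
    if len(excluded):
        logger.info(
            "improvement %s/%s: excluded %s", request.service, request.quality,
            ", ".join(sorted(excluded["country_code"])),
        )
    spec = ModelSpec(
        factor_names=tuple(factors), include_dummy=False,
        mcmc=dataclasses.replace(
            mcmc, seed=_stage_seed(seed, "improvement", request.service, request.quality, factors)
        ),
    )
    result = fit(dataset, spec)
    table = _summary_with_meta(result, f"improvement:{request.service}:{request.quality}")
    vif = compute_vif(dataset.X, labels=list(factors))
    return imp_table, table, vif


def run_descriptive(access: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted coverage per year × service × ladder.

    ``population`` has columns country_code, year, population.  Countries
    with access data but no population are excluded from the weighted sums
    with a warning in the log.  Returns served-population counts and the
    weighted global percentage over countries with data.
    """
    nat = access[access["area"] == "total"]
    merged = nat.merge(population, on=["country_code", "year"], how="left")
    missing = merged["population"].isna()
    if missing.any():
        for code in sorted(merged.loc[missing, "country_code"].unique()):
            logger.warning("no population for %s; excluded from weighted summary", code)
        merged = merged[~missing]
    grouped = merged.groupby(["year", "service", "ladder"])
    rows = []
    for (year, service, ladder), g in grouped:
        pop = g["population"].to_numpy(dtype=float)
        served = float((g["rate"].to_numpy() * pop).sum())
        total = float(pop.sum())
        rows.append(
            {
                "year": int(year),
                "service": service,
                "ladder": ladder,
                "population_served": served,
                "population_with_data": total,
                "percent": 100.0 * served / total if total > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    tables: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_full(config: RunConfig, population: pd.DataFrame | None = None) -> RunReport:
    """Execute all requested stages, writing tables, VIFs and a manifest.

    Stage failures are logged and collected; remaining stages continue
    (unless ``config.strict``, which re-raises).  Convergence failures never
    abort — tables carry ``converged=False`` flags.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    access, cov, load_rep = load_panels(config)
    (outdir / "load_report.txt").write_text("\n".join(load_rep.messages) + "\n")

    for i, request in enumerate(config.analyses):
        label = f"{i:02d}_{request.stage}_{request.service}_{request.quality}_{request.area}"
        try:
            if request.stage == "screening":
                table = run_screening(access, cov, request, config.mcmc, config.seed)
                write_result_table(table, outdir / f"{label}.csv")
                report.tables[label] = table
            elif request.stage == "multivariable":
                table, vif = run_multivariable(access, cov, request, config.mcmc, config.seed)
                write_result_table(table, outdir / f"{label}.csv")
                vif.to_frame().to_csv(outdir / f"{label}_vif.csv")
                report.tables[label] = table
            elif request.stage == "improvement":
                imp, table, vif = run_improvement(access, cov, request, config.mcmc, config.seed)
                write_result_table(imp, outdir / f"{label}_p2.csv")
                write_result_table(table, outdir / f"{label}.csv")
                vif.to_frame().to_csv(outdir / f"{label}_vif.csv")
                report.tables[label] = table
            elif request.stage == "descriptive":
                if population is None:
                    raise ValueError("descriptive stage requires a population table")
                table = run_descriptive(access, population)
                write_result_table(table, outdir / f"{label}.csv")
                report.tables[label] = table
            else:
                raise ValueError(f"unknown stage {request.stage!r}")
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            if config.strict:
                raise
            logger.error("stage %s failed: %s", label, exc)
            report.errors.append(f"{label}: {exc}")

    report.manifest = {
        "version": __version__,
        "seed": config.seed,
        "mcmc": dataclasses.asdict(config.mcmc),
        "aggregation_policy": config.aggregation_policy,
        "analyses": [dataclasses.asdict(a) for a in config.analyses],
        "errors": report.errors,
    }
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2, default=str) + "\n")
    return report
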