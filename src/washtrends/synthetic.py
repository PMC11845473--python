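"""Synthetic country panels with the statistical structure the analysis assumes.

The generator draws, per country, a correlated vector of covariates on the
transformed scale (log10 GDP per capita, urban population rate, democracy
index, log10 renewable freshwater per capita), applies a per-year drift, and
back-transforms to the raw scale.  Access rates then follow the generative
model the regression assumes: rate = logistic(intercept + Σ C_i z_i + C_d
X_d) + Normal(0, sigma_obs), with z_i the covariates z-scored within the
generated panel.  Noise is added on the rate scale without clipping by
default, mirroring the untruncated Gaussian likelihood so recovery tests are
exact-model tests; a clipped mode exists for robustness studies.

Ladder rows are emitted consistently with the cumulative-aggregation policy:
``at_least_basic`` is the basic-or-higher rate, ``safely_managed`` a fixed
share of it, and ``basic`` the remainder, so safely_managed ≤ at_least_basic
always holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes_logistic import logistic
from .panel_io import Dialect, read_access_panel, read_covariates

FACTOR_ORDER = ("gdp_pc", "urban_pop_rate", "democracy_index", "renewable_water_pc")
#: Raw-scale bounds applied after back-transform (index and percentage caps).
_RAW_CLIP = {"urban_pop_rate": (1.0, 100.0), "democracy_index": (0.0, 10.0)}


@dataclass(frozen=True)
class CovariateModel:
    """Distribution of the covariates on the transformed scale.

    Defaults emulate a realistic cross-country panel: log10 GDP per capita
    centered near 3.7 (≈ $5,000), urban population around 55%, democracy
    index around 5.5, log10 renewable water per capita near 3.3 (≈ 2,000 m³),
    with GDP positively correlated with urbanization and democracy.
    ``drift`` is the per-20-year shift on the transformed scale.
    """

    means: tuple[float, ...] = (3.7, 55.0, 5.5, 3.3)
    sds: tuple[float, ...] = (0.55, 22.0, 2.0, 0.7)
    correlation: tuple[tuple[float, ...], ...] = (
        (1.00, 0.60, 0.50, 0.00),
        (0.60, 1.00, 0.35, 0.00),
        (0.50, 0.35, 1.00, 0.00),
        (0.00, 0.00, 0.00, 1.00),
    )
    drift: tuple[float, ...] = (0.20, 6.0, 0.2, -0.05)
    year_noise_sd: float = 0.02  # idiosyncratic within-country drift noise, in sds

    def covariance(self) -> np.ndarray:
        corr = np.asarray(self.correlation, dtype=float)
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(corr) <= 0):
            raise ValueError("correlation matrix must be positive-definite")
        sds = np.asarray(self.sds, dtype=float)
        return corr * np.outer(sds, sds)


#: Access-model truth per (service, quality): intercept, coefficients on
#: (gdp_pc, urban_pop_rate, democracy_index), year-dummy effect.  Renewable
#: water has no effect on access, matching its screening outcome.
DEFAULT_TRUE_THETA = {
    ("drinking_water", "basic_or_higher"): {
        "intercept": 2.0,
        "coefs": (1.0, 0.3, 0.1),
        "dummy": -0.5,
    },
    ("sanitation", "basic_or_higher"): {
        "intercept": 1.7,
        "coefs": (1.7, 0.3, 0.0),
        "dummy": -0.54,
    },
}
MODEL_FACTORS = ("gdp_pc", "urban_pop_rate", "democracy_index")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic panel."""

    n_countries: int = 150
    years: tuple[int, int] = (2000, 2020)
    true_theta: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_THETA.items()})
    sigma_obs: float = 0.05
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    missingness: dict = field(default_factory=dict)  # factor -> probability
    emulate_democracy_gap: bool = False
    clip_rates: bool = False
    safely_managed_share: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 10:
            raise ValueError("need at least 10 countries")
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be positive")


def _country_codes(n: int) -> list[str]:
    return [f"C{i:03d}" for i in range(n)]


def generate_covariates(config: ScenarioConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a complete covariate panel (no missingness) on the raw scale."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    cm = config.covariate_model
    n, years = config.n_countries, config.years
    base = rng.multivariate_normal(np.asarray(cm.means), cm.covariance(), size=n)
    drift = np.asarray(cm.drift)
    sds = np.asarray(cm.sds)
    span = max(years) - min(years)

    rows = []
    codes = _country_codes(n)
    for k, year in enumerate(years):
        frac = 0.0 if span == 0 else (year - min(years)) / span
        noise = rng.normal(0.0, cm.year_noise_sd, size=(n, len(FACTOR_ORDER))) * sds if k else 0.0
        vals = base + frac * drift + noise
        for j, factor in enumerate(FACTOR_ORDER):
            col = vals[:, j]
            raw = 10.0 ** col if factor in ("gdp_pc", "renewable_water_pc") else col.copy()
            if factor in _RAW_CLIP:
                raw = np.clip(raw, *_RAW_CLIP[factor])
            rows += [
                {"country_code": codes[i], "year": year, "factor": factor, "value": float(raw[i])}
                for i in range(n)
            ]
    return pd.DataFrame(rows)


def _transformed_matrix(cov: pd.DataFrame) -> pd.DataFrame:
    """Stacked (country, year) × factor matrix on the transformed scale."""
    wide = cov.pivot_table(index=["country_code", "year"], columns="factor", values="value")
    for factor in ("gdp_pc", "renewable_water_pc"):
        wide[factor] = np.log10(wide[factor])
    return wide


def generate_access(
    cov: pd.DataFrame, config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate access-ladder rows from the logistic + Gaussian-noise model.

    Requires a complete covariate panel (generate access before applying
    missingness).  Covariates are z-scored within the stacked panel, exactly
    as the analysis normalizes them.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    wide = _transformed_matrix(cov)
    if wide.isna().any().any():
        raise ValueError("covariates must be complete when generating access")
    z = (wide - wide.mean()) / wide.std(ddof=1)
    dummy = (wide.index.get_level_values("year") == max(config.years)).astype(float)

    rows = []
    share = config.safely_managed_share
    for (service, quality), theta in config.true_theta.items():
        eta = float(theta["intercept"]) + dummy * float(theta["dummy"])
        for name, c in zip(MODEL_FACTORS, theta["coefs"]):
            eta = eta + float(c) * z[name].to_numpy()
        rate = logistic(eta) + rng.normal(0.0, config.sigma_obs, size=len(eta))
        if config.clip_rates:
            rate = np.clip(rate, 0.0, 1.0)
        ladder_rates = {
            "at_least_basic": rate,
            "safely_managed": share * rate,
            "basic": (1.0 - share) * rate,
        }
        for (code, year), *vals in zip(wide.index, *ladder_rates.values()):
            for ladder, v in zip(ladder_rates, vals):
                rows.append(
                    {
                        "country_code": code,
                        "year": int(year),
                        "service": service,
                        "area": "total",
                        "ladder": ladder,
                        "rate": float(v),
                    }
                )
    return pd.DataFrame(rows)


def apply_missingness(
    cov: pd.DataFrame, config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Drop covariate records at random per the configured per-factor rates.

    With ``emulate_democracy_gap`` set, year-2000 democracy records are moved
    to 2006 so downstream code must exercise the 2006→2000 carry rule.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    out = cov.copy()
    keep = np.ones(len(out), dtype=bool)
    for factor, p in config.missingness.items():
        mask = (out["factor"] == factor).to_numpy()
        keep &= ~(mask & (rng.random(len(out)) < p))
    out = out[keep].reset_index(drop=True)
    if config.emulate_democracy_gap:
        move = (out["factor"] == "democracy_index") & (out["year"] == min(config.years))
        out.loc[move, "year"] = 2006
    return out


def generate_study(
    config: ScenarioConfig, outdir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the full study: access panel, covariate panel and truth record.

    Access is generated from the complete covariates; missingness is applied
    afterwards, so missing covariates thin the complete-case set without
    biasing the access model.  With ``outdir`` set, writes
    ``access.csv``, ``covariates.csv`` (canonical dialect) and
    ``truth.json``; files are byte-identical for identical config + seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_acc, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))
    cov_full = generate_covariates(config, rng_cov)
    access = generate_access(cov_full, config, rng_acc)
    cov = apply_missingness(cov_full, config, rng_miss)
    truth = {
        "true_theta": {f"{svc}/{qual}": theta for (svc, qual), theta in config.true_theta.items()},
        "sigma_obs": config.sigma_obs,
        "n_countries": config.n_countries,
        "years": list(config.years),
        "seed": config.seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        access.to_csv(outdir / "access.csv", index=False)
        cov.to_csv(outdir / "covariates.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return access, cov, truth


#: Improvement-model truth used by default: a mid-range P2 regime (mean 0.5)
#: in which the −0.05 exclusion rule is almost surely inactive, so recovery
#: tests measure estimation rather than truncation.
DEFAULT_IMPROVEMENT_THETA = {
    "intercept": 0.0,
    "coefs": {"gdp_pc": -0.9, "urban_pop_rate": -0.2,
              "democracy_index": 0.3, "renewable_water_pc": 0.1},
}


def generate_improvement_study(
    seed: int,
    n_countries: int = 140,
    sigma_obs: float = 0.05,
    true_theta: dict | None = None,
    c_later: float = 0.8,
    covariate_model: CovariateModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Panels whose attributable proportion follows the improvement model exactly.

    Covariates are drawn once per country from the correlated country model
    and held constant over 2000–2020 (so transform-then-average returns the
    draw itself); P2 = logistic(intercept + Σ c_i z_i) + Normal(0, sigma_obs)
    and the 2000 access rate is back-solved from a fixed 2020 rate, making
    the recomputed P2 an exact round trip.  Returns (access, covariates,
    truth dict).
    """
    theta = true_theta or DEFAULT_IMPROVEMENT_THETA
    cm = covariate_model or CovariateModel()
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(np.asarray(cm.means), cm.covariance(), size=n_countries)
    factors = list(FACTOR_ORDER)
    z = (draws - draws.mean(axis=0)) / draws.std(axis=0, ddof=1)
    eta = theta["intercept"] + z @ np.array([theta["coefs"][f] for f in factors])
    p2 = logistic(eta) + rng.normal(0.0, sigma_obs, size=n_countries)

    cov_rows, acc_rows = [], []
    for i in range(n_countries):
        code = f"C{i:03d}"
        for year in (2000, 2020):
            for j, f in enumerate(factors):
                raw = 10.0 ** draws[i, j] if f in ("gdp_pc", "renewable_water_pc") else draws[i, j]
                cov_rows.append({"country_code": code, "year": year, "factor": f, "value": float(raw)})
        for year, rate in ((2000, c_later * (1.0 - p2[i])), (2020, c_later)):
            acc_rows.append(
                {"country_code": code, "year": year, "service": "drinking_water",
                 "area": "total", "ladder": "basic_or_higher", "rate": float(rate)}
            )
    truth = {"true_theta": theta, "sigma_obs": sigma_obs, "n_countries": n_countries}
    return pd.DataFrame(acc_rows), pd.DataFrame(cov_rows), truth


def load_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_study(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Round-trip a written study through the canonical panel readers."""
    outdir = Path(outdir)
    access, _ = read_access_panel(outdir / "access.csv", Dialect(strict_bounds=False))
    cov, _ = read_covariates(outdir / "covariates.csv", Dialect())
    return access, cov, load_truth(outdir / "truth.json")
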