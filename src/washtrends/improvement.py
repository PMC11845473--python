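"""The attributable-proportion improvement statistic and its regression.

For a country with crude access rates C_2000 and C_2020 the attributable
proportion of recent improvement is

    P2 = (C_2020 − C_2000) / C_2020,

the share of 2020 coverage built since 2000 (P2 = 0.5 means half of the
2020 infrastructure is post-2000).  P2 typically lies in [0, 1]; countries
with P2 < −0.05 — an extraordinary decline beyond plausible measurement
error — are excluded before fitting, while values in [−0.05, 0) are retained
untouched since the Gaussian error model permits outcomes outside the
logistic range.  P2 is then regressed on the country's 2000–2020 mean
covariates (log-transformed first where applicable, then averaged, then
z-scored) with the same logistic-mean Gaussian-error machinery, without a
year dummy.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .preprocess import AnalysisDataset, DatasetError, FactorSpec, transform_factor, zscore

EXCLUSION_THRESHOLD = -0.05

STATUS_INCLUDED = "included"
STATUS_EXCLUDED = "excluded_below_threshold"
STATUS_UNDEFINED = "undefined_zero_denominator"


def attributable_proportion(c_prev: float, c_later: float) -> float:
    """(c_later − c_prev) / c_later; NaN when the later rate is zero."""
    if c_later == 0:
        return math.nan
    return (c_later - c_prev) / c_later


def improvement_table(
    access: pd.DataFrame,
    service: str,
    quality: str,
    year_pair: tuple[int, int] = (2000, 2020),
    threshold: float = EXCLUSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-country P2 with inclusion status, from national (area=total) rates.

    Countries need an observed rate in both years; the status column marks
    zero-denominator countries and those below the exclusion threshold.
    """
    y_prev, y_later = year_pair
    sub = access[
        (access["service"] == service)
        & (access["ladder"] == quality)
        & (access["area"] == "total")
        & (access["year"].isin([y_prev, y_later]))
    ]
    wide = sub.pivot_table(index="country_code", columns="year", values="rate", aggfunc="first")
    if y_prev not in wide.columns or y_later not in wide.columns:
        raise DatasetError(f"missing access data for years {year_pair}")
    wide = wide.dropna(subset=[y_prev, y_later])

    rows = []
    for code, r in wide.iterrows():
        c_prev, c_later = float(r[y_prev]), float(r[y_later])
        p2 = attributable_proportion(c_prev, c_later)
        if math.isnan(p2):
            status = STATUS_UNDEFINED
        elif p2 < threshold:
            status = STATUS_EXCLUDED
        else:
            status = STATUS_INCLUDED
        rows.append(
            {
                "country_code": code,
                "service": service,
                "quality": quality,
                "c_prev": c_prev,
                "c_later": c_later,
                "p2": p2,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusion(
    table: pd.DataFrame, threshold: float = EXCLUSION_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an improvement table into (included, excluded) by the strict rule.

    Exclusion is strict: p2 < threshold.  A value of exactly −0.05 is
    retained.  Zero-denominator countries are excluded too (undefined P2).
    The split is idempotent and order-independent.
    """
    p2 = table["p2"]
    undefined = p2.isna()
    below = ~undefined & (p2 < threshold)
    table = table.copy()
    table.loc[undefined, "status"] = STATUS_UNDEFINED
    table.loc[below, "status"] = STATUS_EXCLUDED
    table.loc[~undefined & ~below, "status"] = STATUS_INCLUDED
    included = table[table["status"] == STATUS_INCLUDED].reset_index(drop=True)
    excluded = table[table["status"] != STATUS_INCLUDED].reset_index(drop=True)
    if len(excluded):
        warnings.warn(
            "excluded countries: " + ", ".join(sorted(excluded["country_code"])), stacklevel=2
        )
    return included, excluded


def mean_covariates(
    cov: pd.DataFrame,
    factor_specs: list[FactorSpec],
    year_range: tuple[int, int] = (2000, 2020),
    policy: str = "transform_then_average",
) -> pd.DataFrame:
    """Per-country mean of each factor over the year range.

    Default policy transforms each annual value first (log10 for monetary and
    hydrological factors) and averages the transformed values — a
    geometric-mean-like summary appropriate for right-skewed series.  The
    ``average_then_transform`` alternative is available for sensitivity
    checks.  Countries lacking every year of a factor are dropped (NaN row,
    filtered by the caller); the result has one column per factor on the
    transformed scale.
    """
    if policy not in ("transform_then_average", "average_then_transform"):
        raise ValueError(f"unknown mean policy {policy!r}")
    lo, hi = year_range
    sub = cov[(cov["year"] >= lo) & (cov["year"] <= hi)]
    out = {}
    for spec in factor_specs:
        vals = sub[sub["factor"] == spec.factor]
        if policy == "transform_then_average":
            per_country = vals.groupby("country_code")["value"].apply(
                lambda v: float(np.mean(transform_factor(v.to_numpy(), spec.transform)))
            )
        else:
            per_country = vals.groupby("country_code")["value"].mean()
            per_country = pd.Series(
                transform_factor(per_country.to_numpy(), spec.transform),
                index=per_country.index,
            )
        out[spec.factor] = per_country
    return pd.DataFrame(out)


def build_improvement_dataset(
    access: pd.DataFrame,
    cov: pd.DataFrame,
    service: str,
    quality: str,
    factor_specs: list[FactorSpec],
    year_pair: tuple[int, int] = (2000, 2020),
    threshold: float = EXCLUSION_THRESHOLD,
    mean_policy: str = "transform_then_average",
    min_rows: int = 10,
) -> tuple[AnalysisDataset, pd.DataFrame]:
    """Assemble the improvement-regression dataset (outcome P2, no dummy).

    One row per included country; X holds the z-scored 2000–2020 mean
    covariates for every requested factor.  Returns the dataset together with
    the full improvement table (statuses included) for reporting.
    """
    table = improvement_table(access, service, quality, year_pair, threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        included, _ = apply_exclusion(table, threshold)
    means = mean_covariates(cov, factor_specs, year_pair, mean_policy)
    names = [f.factor for f in factor_specs]
    merged = included.merge(means, left_on="country_code", right_index=True).dropna(subset=names)
    merged = merged.sort_values("country_code").reset_index(drop=True)
    if len(merged) < min_rows:
        raise DatasetError(f"only {len(merged)} included countries (< {min_rows})")

    X = np.empty((len(merged), len(names)))
    norm_params = {}
    for j, name in enumerate(names):
        X[:, j], c, s = zscore(merged[name].to_numpy())
        norm_params[name] = (c, s)

    dataset = AnalysisDataset(
        service=service,
        quality=quality,
        area="total",
        year_pair=year_pair,
        countries=merged["country_code"].to_numpy(),
        years=None,
        y=merged["p2"].to_numpy(dtype=float),
        X=X,
        x_dummy=None,
        factor_names=names,
        transforms={f.factor: f.transform for f in factor_specs},
        normalization_params=norm_params,
        n_countries_per_year={year_pair[1]: len(merged)},
    )
    return dataset, table
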