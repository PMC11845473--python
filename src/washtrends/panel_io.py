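"""Reading, validation, harmonization and writing of country-panel tables.

Two long-format panels drive every analysis:

* an *access panel*: one row per (country, year, service, area, ladder)
  holding the national access rate as a proportion in [0, 1];
* a *covariate panel*: one row per (country, year, factor) holding a
  socioeconomic, political or hydrological indicator on its raw scale.

Both are plain delimited text with a header row.  The :class:`Dialect`
declares delimiter, column names and whether rates arrive as percentages;
nothing is ever sniffed.  Missing values are dropped (and counted), never
imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SERVICES = ("drinking_water", "sanitation")
AREAS = ("total", "urban", "rural")
LADDERS = (
    "safely_managed",
    "basic",
    "at_least_basic",
    "limited",
    "unimproved",
    "surface_water",
    "open_defecation",
    "basic_or_higher",
)
FACTORS = (
    "gdp_pc",
    "gdp_ppp_pc",
    "urban_pop_rate",
    "democracy_index",
    "renewable_water_pc",
)
#: Factors that must be strictly positive (they are log-transformed downstream).
POSITIVE_FACTORS = frozenset({"gdp_pc", "gdp_ppp_pc", "renewable_water_pc"})

ACCESS_KEY = ["country_code", "year", "service", "area", "ladder"]
ACCESS_COLUMNS = ACCESS_KEY + ["rate"]
COVARIATE_KEY = ["country_code", "year", "factor"]
COVARIATE_COLUMNS = COVARIATE_KEY + ["value"]


class PanelFormatError(ValueError):
    """A malformed or out-of-contract row in an input panel file."""


@dataclass(frozen=True)
class Dialect:
    """How a delimited panel file is laid out.

    Parameters
    ----------
    delimiter : field separator (comma default, tab accepted).
    rate_unit : ``"proportion"`` for rates already in [0, 1] or
        ``"percent"`` for rates in [0, 100] (divided by 100 exactly once
        at read time).
    columns : optional mapping from the file's header names to the
        canonical column names, for wide exports renamed up front.
    strict_bounds : enforce rates within [0, 1] (or [0, 100] in percent
        mode).  Set to ``False`` for panels generated under the untruncated
        Gaussian error model, where observed rates may fall slightly outside
        the unit interval.
    """

    delimiter: str = ","
    rate_unit: str = "proportion"
    columns: Mapping[str, str] | None = None
    strict_bounds: bool = True

    def __post_init__(self) -> None:
        if self.rate_unit not in ("proportion", "percent"):
            raise ValueError(f"rate_unit must be 'proportion' or 'percent', got {self.rate_unit!r}")


@dataclass
class LoadReport:
    """Structured account of what a read or harmonization step did."""

    n_read: int = 0
    n_dropped_missing: int = 0
    n_excluded_nonpositive: int = 0
    n_carried: int = 0
    n_aggregated: int = 0
    messages: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.messages.append(message)


def _read_raw(path, dialect: Dialect, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    if dialect.columns:
        df = df.rename(columns=dict(dialect.columns))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing required column(s) {missing}")
    return df


def _to_number(df: pd.DataFrame, column: str, path) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.str.strip() != "")
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise PanelFormatError(f"{path}: line {line}: cannot parse {column}={raw[bad].iloc[0]!r}")
    return out


def _check_enum(df: pd.DataFrame, column: str, allowed: tuple[str, ...], path) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise PanelFormatError(f"{path}: line {line}: invalid {column}={df[column][bad].iloc[0]!r}")


def read_access_panel(path, dialect: Dialect = Dialect()) -> tuple[pd.DataFrame, LoadReport]:
    """Read and validate an access-rate panel.

    Returns the panel with rates as proportions and a :class:`LoadReport`.
    Rows with a missing rate are dropped and counted; out-of-range rates,
    service/ladder mismatches and duplicate keys raise
    :class:`PanelFormatError`.
    """
    report = LoadReport()
    df = _read_raw(path, dialect, ACCESS_COLUMNS[:1] + ACCESS_COLUMNS[1:])
    df = df[[c for c in df.columns if c in set(ACCESS_COLUMNS) | {"country_name"}]]
    if df.empty:
        report.log(f"read {path}: 0 records")
        empty = df.reindex(columns=ACCESS_COLUMNS)
        empty["year"] = empty["year"].astype(int) if len(empty) else pd.Series(dtype=int)
        empty["rate"] = pd.Series(dtype=float)
        return empty, report

    df["year"] = _to_number(df, "year", path)
    bad_year = df["year"].isna()
    if bad_year.any():
        line = int(df.index[bad_year][0]) + 2
        raise PanelFormatError(f"{path}: line {line}: missing year")
    df["year"] = df["year"].astype(int)

    _check_enum(df, "service", SERVICES, path)
    _check_enum(df, "area", AREAS, path)
    _check_enum(df, "ladder", LADDERS, path)

    mismatch = ((df["ladder"] == "surface_water") & (df["service"] != "drinking_water")) | (
        (df["ladder"] == "open_defecation") & (df["service"] != "sanitation")
    )
    if mismatch.any():
        line = int(df.index[mismatch][0]) + 2
        raise PanelFormatError(
            f"{path}: line {line}: ladder {df['ladder'][mismatch].iloc[0]!r} "
            f"incompatible with service {df['service'][mismatch].iloc[0]!r}"
        )

    df["rate"] = _to_number(df, "rate", path)
    missing_rate = df["rate"].isna()
    report.n_dropped_missing = int(missing_rate.sum())
    df = df[~missing_rate].copy()

    hi = 100.0 if dialect.rate_unit == "percent" else 1.0
    if dialect.strict_bounds:
        out_of_range = (df["rate"] < 0) | (df["rate"] > hi)
        if out_of_range.any():
            line = int(df.index[out_of_range][0]) + 2
            raise PanelFormatError(
                f"{path}: line {line}: rate {df['rate'][out_of_range].iloc[0]} "
                f"outside [0, {hi:g}] ({dialect.rate_unit} mode)"
            )
    if dialect.rate_unit == "percent":
        df["rate"] = df["rate"] / 100.0

    dup = df.duplicated(subset=ACCESS_KEY, keep=False)
    if dup.any():
        key = df.loc[dup, ACCESS_KEY].iloc[0].tolist()
        raise PanelFormatError(f"{path}: duplicate access key {key}")

    report.n_read = len(df)
    report.log(
        f"read {path}: {report.n_read} records, {report.n_dropped_missing} dropped (missing rate)"
    )
    return df.reset_index(drop=True), report


def read_covariates(path, dialect: Dialect = Dialect()) -> tuple[pd.DataFrame, LoadReport]:
    """Read and validate a covariate panel on its raw scale.

    Non-positive values of factors destined for a log transform are excluded
    with a warning rather than raising, since they merely shrink the
    complete-case set.
    """
    report = LoadReport()
    df = _read_raw(path, dialect, COVARIATE_COLUMNS)
    df = df[[c for c in df.columns if c in COVARIATE_COLUMNS]]
    if df.empty:
        report.log(f"read {path}: 0 records")
        empty = df.reindex(columns=COVARIATE_COLUMNS)
        empty["year"] = pd.Series(dtype=int)
        empty["value"] = pd.Series(dtype=float)
        return empty, report

    df["year"] = _to_number(df, "year", path).astype(int)
    _check_enum(df, "factor", FACTORS, path)
    df["value"] = _to_number(df, "value", path)

    missing = df["value"].isna()
    report.n_dropped_missing = int(missing.sum())
    df = df[~missing].copy()

    urban = df["factor"] == "urban_pop_rate"
    bad_urban = urban & ((df["value"] < 0) | (df["value"] > 100))
    if bad_urban.any():
        line = int(df.index[bad_urban][0]) + 2
        raise PanelFormatError(
            f"{path}: line {line}: urban_pop_rate {df['value'][bad_urban].iloc[0]} outside [0, 100]"
        )

    nonpos = df["factor"].isin(POSITIVE_FACTORS) & (df["value"] <= 0)
    report.n_excluded_nonpositive = int(nonpos.sum())
    if nonpos.any():
        for _, row in df[nonpos].iterrows():
            msg = (
                f"excluded non-positive {row['factor']}={row['value']} for "
                f"{row['country_code']} {row['year']} (cannot be log-transformed)"
            )
            warnings.warn(msg, stacklevel=2)
            report.log(msg)
        df = df[~nonpos].copy()

    dup = df.duplicated(subset=COVARIATE_KEY, keep=False)
    if dup.any():
        key = df.loc[dup, COVARIATE_KEY].iloc[0].tolist()
        raise PanelFormatError(f"{path}: duplicate covariate key {key}")

    report.n_read = len(df)
    report.log(
        f"read {path}: {report.n_read} records, {report.n_dropped_missing} dropped, "
        f"{report.n_excluded_nonpositive} excluded non-positive"
    )
    return df.reset_index(drop=True), report


def carry_democracy_2006_to_2000(
    cov: pd.DataFrame, report: LoadReport | None = None
) -> tuple[pd.DataFrame, int]:
    """Copy each country's 2006 democracy-index value to year 2000.

    The democracy index starts in 2006, so its 2006 value stands in for
    2000.  Existing 2000 values are left untouched; no other factor or year
    is modified.  Returns the augmented panel and the number of carried
    records.
    """
    dem = cov[cov["factor"] == "democracy_index"]
    have_2000 = set(dem.loc[dem["year"] == 2000, "country_code"])
    src = dem[(dem["year"] == 2006) & ~dem["country_code"].isin(have_2000)]
    carried = src.copy()
    carried["year"] = 2000
    out = pd.concat([cov, carried], ignore_index=True)
    if report is not None:
        report.n_carried = len(carried)
        report.log(f"carried democracy index 2006->2000 for {len(carried)} countries")
    return out, len(carried)


def aggregate_basic_or_higher(
    access: pd.DataFrame,
    policy: str = "cumulative",
    tolerance: float = 1e-9,
    report: LoadReport | None = None,
) -> pd.DataFrame:
    """Derive one ``basic_or_higher`` row per (country, year, service, area).

    Policies
    --------
    ``cumulative`` (default)
        Use the ``at_least_basic`` row where present — in JMP-style ladders
        it is the cumulative category equal to basic + safely managed — and
        fall back to ``safely_managed + basic`` otherwise.
    ``sum_components``
        Always sum ``safely_managed + basic``.

    A *summed* aggregate exceeding ``1 + tolerance`` raises — it signals
    double-counting or inconsistent ladder input.  Cumulative rows are passed
    through as observed data (their bounds were validated at read time under
    the declared dialect).  Keys that already carry a ``basic_or_higher`` row
    are skipped.  Only the newly derived rows are returned.
    """
    if policy not in ("cumulative", "sum_components"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    key = ["country_code", "year", "service", "area"]
    sub = access[access["ladder"].isin(["safely_managed", "basic", "at_least_basic"])]
    wide = sub.pivot_table(index=key, columns="ladder", values="rate", aggfunc="first")
    existing = set(map(tuple, access.loc[access["ladder"] == "basic_or_higher", key].to_numpy()))

    rows = []
    for idx, r in wide.iterrows():
        if tuple(idx) in existing:
            continue
        alb = r.get("at_least_basic", np.nan)
        sm = r.get("safely_managed", np.nan)
        ba = r.get("basic", np.nan)
        if policy == "cumulative" and not np.isnan(alb):
            value = alb
        elif not (np.isnan(sm) or np.isnan(ba)):
            value = sm + ba
            if value > 1.0 + tolerance:
                raise PanelFormatError(
                    f"basic_or_higher aggregate {value:.6g} exceeds 1 for key {tuple(idx)}"
                )
        else:
            continue
        rows.append(dict(zip(key, idx)) | {"ladder": "basic_or_higher", "rate": float(value)})

    out = pd.DataFrame(rows, columns=key + ["ladder", "rate"])
    if report is not None:
        report.n_aggregated = len(out)
        report.log(f"aggregated basic_or_higher for {len(out)} keys (policy={policy})")
    return out


def with_basic_or_higher(access: pd.DataFrame, policy: str = "cumulative") -> pd.DataFrame:
    """Return the access panel with derived ``basic_or_higher`` rows appended."""
    extra = aggregate_basic_or_higher(access, policy=policy)
    if extra.empty:
        return access.copy()
    return pd.concat([access, extra], ignore_index=True)


def write_result_table(table: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a result table (fit summary or improvement table) as delimited text.

    Floats are written with full ``repr`` precision so the matching reader
    restores them bit-exactly.
    """
    table.to_csv(path, sep=delimiter, index=False)


def read_result_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read back a table written by :func:`write_result_table`."""
    return pd.read_csv(path, sep=delimiter)
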