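"""Covariate transformation, normalization and analysis-dataset assembly.

Right-skewed monetary and hydrological factors (per capita GDP, GDP PPP,
renewable internal freshwater resources) are log-transformed; the urban
population rate and democracy index enter untransformed.  Every factor
column is then z-scored over the stacked analysis rows, so coefficients are
per-standard-deviation effects on the logit scale and the year dummy stays
interpretable as a pure cross-year contrast.  Because z-scoring absorbs any
affine rescaling, the choice of log base is irrelevant to the final dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import FACTORS, POSITIVE_FACTORS

#: Default transform per factor.
DEFAULT_TRANSFORMS = {f: ("log10" if f in POSITIVE_FACTORS else "identity") for f in FACTORS}


class DatasetError(ValueError):
    """The requested analysis dataset cannot be assembled."""


@dataclass(frozen=True)
class FactorSpec:
    """One explanatory factor: its name, transform and screening role."""

    factor: str
    transform: str | None = None
    role: str = "candidate"

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.transform is None:
            object.__setattr__(self, "transform", DEFAULT_TRANSFORMS[self.factor])
        if self.transform not in ("log10", "ln", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")


def default_factor_specs(factors: list[str]) -> list[FactorSpec]:
    return [FactorSpec(f) for f in factors]


def transform_factor(values, transform: str) -> np.ndarray:
    """Apply the declared elementwise transform to raw factor values."""
    x = np.asarray(values, dtype=float)
    if transform == "identity":
        return x.copy()
    if np.any(x <= 0):
        raise ValueError(f"non-positive value under {transform}; exclude at read time")
    return np.log10(x) if transform == "log10" else np.log(x)


def zscore(values) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, sd 1 (n−1 denominator).

    Returns ``(normalized, center, scale)``; raises on constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    center = float(np.mean(x))
    scale = float(np.std(x, ddof=1))
    if scale == 0.0:
        raise ValueError("constant input: zero variance, cannot normalize")
    return (x - center) / scale, center, scale


@dataclass
class AnalysisDataset:
    """Stacked complete-case design for one model fit.

    ``X`` holds normalized factor columns in declared order; ``x_dummy`` is
    the 0/1 year indicator (``None`` for the improvement regression, which
    has no year contrast).  ``normalization_params`` records the (center,
    scale) applied to each factor for reuse and audit.
    """

    service: str
    quality: str
    area: str
    year_pair: tuple[int, int] | None
    countries: np.ndarray
    years: np.ndarray | None
    y: np.ndarray
    X: np.ndarray
    x_dummy: np.ndarray | None
    factor_names: list[str]
    transforms: dict[str, str] = field(default_factory=dict)
    normalization_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_countries_per_year: dict[int, int] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def design_matrix(self, include_dummy: bool | None = None) -> np.ndarray:
        """Intercept + factor columns (+ dummy), as fit() consumes them."""
        cols = [np.ones(self.n_rows), *self.X.T]
        if include_dummy is None:
            include_dummy = self.x_dummy is not None
        if include_dummy:
            if self.x_dummy is None:
                raise ValueError("dataset has no dummy column")
            cols.append(self.x_dummy)
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        """Row-per-observation snapshot for audit output."""
        data = {"country_code": self.countries}
        if self.years is not None:
            data["year"] = self.years
        data["y"] = self.y
        for j, name in enumerate(self.factor_names):
            data[name] = self.X[:, j]
        if self.x_dummy is not None:
            data["x_dummy"] = self.x_dummy
        return pd.DataFrame(data)


def build_dataset(
    access: pd.DataFrame,
    cov: pd.DataFrame,
    service: str,
    quality: str,
    area: str,
    year_pair: tuple[int, int],
    factors: list[FactorSpec],
    complete_case: str = "country_year",
    pooled_normalization: bool = True,
    min_rows: int = 10,
) -> AnalysisDataset:
    """Assemble the stacked two-year complete-case dataset for one model.

    Rows are country-years with an observed outcome and every requested
    factor.  ``complete_case='country_year'`` lets a country contribute a
    single year; ``'both_years'`` requires both.  Factors are transformed and
    then z-scored, pooled over the stacked rows by default (per-year with
    ``pooled_normalization=False``).  Rows are ordered earlier year first,
    countries alphabetical, so the dummy is a 0-block followed by a 1-block.
    """
    if not factors:
        raise DatasetError("no factors requested")
    y_prev, y_later = year_pair
    out = access[
        (access["service"] == service)
        & (access["ladder"] == quality)
        & (access["area"] == area)
        & (access["year"].isin([y_prev, y_later]))
    ][["country_code", "year", "rate"]]
    if out.empty:
        raise DatasetError(
            f"no access rows for service={service}, ladder={quality}, area={area}, years={year_pair}"
        )

    names = [f.factor for f in factors]
    cw = (
        cov[(cov["factor"].isin(names)) & (cov["year"].isin([y_prev, y_later]))]
        .pivot_table(index=["country_code", "year"], columns="factor", values="value", aggfunc="first")
        .reset_index()
    )
    for name in names:
        if name not in cw.columns:
            raise DatasetError(f"factor {name!r} absent from covariate panel for years {year_pair}")

    merged = out.merge(cw, on=["country_code", "year"], how="inner").dropna(subset=names)
    if complete_case == "both_years":
        counts = merged.groupby("country_code")["year"].nunique()
        keep = counts[counts == 2].index
        merged = merged[merged["country_code"].isin(keep)]
    elif complete_case != "country_year":
        raise ValueError(f"unknown complete_case policy {complete_case!r}")

    merged = merged.sort_values(["year", "country_code"]).reset_index(drop=True)
    if len(merged) < min_rows:
        raise DatasetError(
            f"only {len(merged)} complete rows (< {min_rows}); model not identifiable in practice"
        )

    transforms = {f.factor: f.transform for f in factors}
    X = np.empty((len(merged), len(factors)))
    norm_params: dict[str, tuple[float, float]] = {}
    for j, f in enumerate(factors):
        t = transform_factor(merged[f.factor].to_numpy(), f.transform)
        if pooled_normalization:
            X[:, j], c, s = zscore(t)
            norm_params[f.factor] = (c, s)
        else:
            col = np.empty_like(t)
            for yr in (y_prev, y_later):
                m = merged["year"].to_numpy() == yr
                col[m], _, _ = zscore(t[m])
            X[:, j] = col
            norm_params[f.factor] = (float("nan"), float("nan"))

    dummy = (merged["year"].to_numpy() == y_later).astype(float)
    per_year = {
        int(yr): int((merged["year"] == yr).sum()) for yr in (y_prev, y_later)
    }
    return AnalysisDataset(
        service=service,
        quality=quality,
        area=area,
        year_pair=(y_prev, y_later),
        countries=merged["country_code"].to_numpy(),
        years=merged["year"].to_numpy(),
        y=merged["rate"].to_numpy(dtype=float),
        X=X,
        x_dummy=dummy,
        factor_names=names,
        transforms=transforms,
        normalization_params=norm_params,
        n_countries_per_year=per_year,
    )


def compute_vif(X: np.ndarray, labels: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per explanatory column.

    VIF_j = 1 / (1 − R²_j), with R²_j from an ordinary least-squares fit of
    column j on the remaining columns plus an intercept.  Perfect
    collinearity is reported as ``inf``, not raised.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n < 3:
        raise ValueError("need at least 3 rows for VIF")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant column: VIF undefined")
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    index = labels if labels is not None else list(range(k))
    return pd.Series(out, index=index, name="vif")
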