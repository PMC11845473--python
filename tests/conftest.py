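import numpy as np
import pandas as pd
import pytest

from washtrends import (
    FactorSpec,
    McmcConfig,
    ScenarioConfig,
    build_dataset,
    generate_study,
    with_basic_or_higher,
)

MODEL_FACTORS = ("gdp_pc", "urban_pop_rate", "democracy_index")


def write_csv(path, text):
    path.write_text(text.strip() + "\n")
    return path


@pytest.fixture
def access_csv(tmp_path):
    """Tiny hand-built access panel in percent units."""
    return write_csv(
        tmp_path / "access.csv",
        """
country_code,year,service,area,ladder,rate
ALB,2000,drinking_water,total,at_least_basic,88.2
ALB,2000,drinking_water,total,safely_managed,60.0
ALB,2000,drinking_water,total,basic,28.2
ALB,2020,drinking_water,total,at_least_basic,95.1
BEN,2000,drinking_water,total,at_least_basic,60.4
BEN,2020,drinking_water,total,at_least_basic,71.2
ALB,2000,sanitation,total,open_defecation,1.5
""",
    )


@pytest.fixture(scope="session")
def small_study():
    """Session-scoped synthetic study small enough for fast pipeline tests."""
    config = ScenarioConfig(n_countries=60, seed=11)
    access, cov, truth = generate_study(config)
    return with_basic_or_higher(access), cov, truth


@pytest.fixture(scope="session")
def small_dataset(small_study):
    access, cov, _ = small_study
    return build_dataset(
        access, cov, "drinking_water", "basic_or_higher", "total", (2000, 2020),
        [FactorSpec(f) for f in MODEL_FACTORS],
    )


@pytest.fixture
def fast_mcmc():
    """Reduced chain geometry for tests that only need a rough posterior."""
    return McmcConfig(iterations=2000, warmup=500, chains=2, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def toy_improvement_access():
    """Six-country national panel with hand-computable improvement values."""
    rows = []
    # (code, c_2000, c_2020): p2 = (c_2020 - c_2000) / c_2020
    cases = [
        ("AAA", 0.50, 0.80),   # p2 = 0.375
        ("BBB", 0.80, 0.80),   # p2 = 0.0
        ("CCC", 0.00, 0.60),   # p2 = 1.0
        ("DDD", 0.42, 0.40),   # p2 = -0.05 (to float rounding): retained (strict <)
        ("EEE", 0.72, 0.60),   # p2 = -0.2: excluded
        ("FFF", 0.50, 0.00),   # undefined (zero denominator)
    ]
    for code, c0, c1 in cases:
        for year, rate in ((2000, c0), (2020, c1)):
            rows.append(
                {
                    "country_code": code,
                    "year": year,
                    "service": "drinking_water",
                    "area": "total",
                    "ladder": "basic_or_higher",
                    "rate": rate,
                }
            )
    return pd.DataFrame(rows)
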