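import numpy as np
import pandas as pd
import pytest

from countysvi import CountyPanel, SyntheticConfig, generate_panel
from countysvi.panel import FEATURE_NAMES


def make_minimal_frame(rows):
    """Build a canonical panel frame from (fips, year, pop, suicides) plus
    bland, invariant-satisfying feature values."""
    base_features = {
        "Population": 50.0,
        "%Female": 50.0,
        "%White": 80.0,
        "%AfricanAmerican": 12.0,
        "%OtherRaces": 8.0,
        "MedianAge": 40.0,
        "MedianIncome": 55.0,
        "%Poverty": 14.0,
        "%Unemployed": 5.0,
        "%SomeCollege": 60.0,
        "SocialAssociationRate": 11.0,
        "%SingleParentHouseholds": 30.0,
        "ViolentCrimeRate": 250.0,
        "OpioidDispensingRate": 60.0,
        "%Uninsured": 10.0,
        "MentallyUnhealthyDays": 4.0,
        "%ExcessiveDrinking": 18.0,
    }
    assert set(base_features) == set(FEATURE_NAMES)
    records = []
    for fips, year, pop, suicides in rows:
        rec = {
            "fips": fips,
            "name": f"County {fips}",
            "state": "PA",
            "year": year,
            "population": pop,
            "suicides": suicides,
            **base_features,
        }
        rec["Population"] = pop / 1000.0
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def small_panel():
    """60 counties, 3 years, default planted effects."""
    panel, truth = generate_panel(SyntheticConfig(n_counties=60, years=(2010, 2011, 2012), seed=7))
    return panel, truth


@pytest.fixture(scope="session")
def medium_panel():
    """400 counties, full decade — enough rows for the fit protocol."""
    panel, truth = generate_panel(SyntheticConfig(n_counties=400, seed=11))
    return panel, truth


@pytest.fixture(scope="session")
def toy_trend_panel():
    """Four counties with hand-set 2010 -> 2019 counts 10->11, 10->16, 10->9, 10->10."""
    rows = []
    ends = {"10001": 11, "10002": 16, "10003": 9, "10004": 10}
    for fips, last in ends.items():
        rows.append((fips, 2010, 100000, 10))
        rows.append((fips, 2019, 100000, last))
    return CountyPanel(make_minimal_frame(rows))


@pytest.fixture(scope="session")
def fitted_small_tree():
    """A tiny boosted model on 3 features for oracle comparisons:
    depth 2, few trees, 20 query rows, 50 background rows."""
    import xgboost as xgb

    rng = np.random.default_rng(3)
    X = rng.normal(size=(120, 3))
    y = X[:, 0] * 1.5 - np.abs(X[:, 1]) + 0.5 * X[:, 2] * X[:, 0] + rng.normal(0, 0.1, 120)
    model = xgb.XGBRegressor(
        n_estimators=15, max_depth=2, learning_rate=0.3, tree_method="hist", n_jobs=1, random_state=0
    )
    model.fit(X.astype(np.float32), y)
    Xq = pd.DataFrame(X[:20], columns=["a", "b", "c"])
    bg = pd.DataFrame(X[20:70], columns=["a", "b", "c"])
    return model, Xq, bg
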