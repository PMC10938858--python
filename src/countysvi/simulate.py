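"""Synthetic county-panel generator with planted effects.

Real county suicide counts and covariates cannot be redistributed, so
every downstream stage is exercised on panels drawn from a documented
generative model that mimics the structure of the public data: 3,140
counties observed over 2010–2019, demographic marginals at realistic
orders of magnitude, a shared latent deprivation factor inducing
collinearity among the socio-economic and health features, and suicide
counts that are Poisson with population exposure.

The log suicide rate of county c in year t is

    log r_ct = log(base_rate) + sum_f beta_f * z_cf
               + (t - t0) * log(1 + trend) + eps_c,

with z_cf the within-panel z-score of feature f, eps_c ~ N(0, sigma_eps)
a county-level noise term, and counts S_ct ~ Poisson(r_ct * P_ct / 1e5).
Population enters only through the Poisson exposure, never through beta:
that is what makes total population the dominant explanatory feature for
raw counts without planting it twice.

Planted directions follow the qualitative epidemiology the analysis is
meant to recover: higher %White and higher median age raise the rate,
higher %AfricanAmerican and %Female lower it; the 12 remaining non-
population features get small nuisance effects drawn once per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import FEATURE_NAMES, CountyPanel


class ConfigError(ValueError):
    """Invalid synthetic-panel configuration."""


#: Strong planted effects (log-rate change per 1 SD of the feature).
DEFAULT_STRONG_BETA: dict[str, float] = {
    "%White": +0.20,
    "MedianAge": +0.15,
    "%Female": -0.15,
    "%AfricanAmerican": -0.20,
}

#: Range of the once-per-seed nuisance effects for the other 12 features.
NUISANCE_BETA_RANGE: tuple[float, float] = (-0.05, 0.05)

_USPS = (
    "AL AK AZ AR CA CO CT DE FL GA HI ID IL IN IA KS KY LA ME MD MA MI MN MS "
    "MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD TN TX UT VT VA WA WV WI WY"
).split()

# Socio-economic / health marginals: (mean, scale, low clip, high clip,
# sign of the deprivation loading).  Units follow the source registries:
# income in thousand $, association rate per 10k, crime per 100k, opioid
# prescriptions per 100 persons, mentally-unhealthy days per month.
_DEPRIVATION_FEATURES: dict[str, tuple[float, float, float, float, float]] = {
    "MedianIncome": (55.0, 14.0, 20.0, 150.0, -1.0),
    "%Poverty": (15.0, 6.0, 2.0, 60.0, +1.0),
    "%Unemployed": (5.5, 2.0, 0.5, 30.0, +1.0),
    "%SomeCollege": (58.0, 11.0, 15.0, 95.0, -1.0),
    "SocialAssociationRate": (11.0, 4.5, 0.0, 60.0, -1.0),
    "%SingleParentHouseholds": (32.0, 9.0, 2.0, 80.0, +1.0),
    "ViolentCrimeRate": (250.0, 180.0, 0.0, 2000.0, +1.0),
    "OpioidDispensingRate": (60.0, 22.0, 0.0, 300.0, +1.0),
    "%Uninsured": (11.0, 4.5, 1.0, 50.0, +1.0),
    "MentallyUnhealthyDays": (3.8, 0.8, 0.5, 10.0, +1.0),
    "%ExcessiveDrinking": (18.0, 3.0, 5.0, 40.0, -1.0),
}


@dataclass
class SyntheticConfig:
    """Generator settings.  Defaults define the standard study conditions.

    beta maps feature name -> log-rate effect per 1 SD; Population may not
    appear (it acts through exposure only).  ``latent_strength`` is the
    correlation between each socio-economic/health feature and the shared
    deprivation factor.
    """

    n_counties: int = 3140
    years: tuple[int, ...] = tuple(range(2010, 2020))
    seed: int = 0
    beta: dict[str, float] | None = None
    base_rate: float = 15.0  # suicides per 100,000 person-years
    sigma_eps: float = 0.05  # SD of county-level log-rate noise
    trend: float = 0.0  # multiplicative annual drift in the rate
    latent_strength: float = 0.6

    def __post_init__(self) -> None:
        if self.n_counties <= 0:
            raise ConfigError("n_counties must be positive")
        if len(self.years) == 0:
            raise ConfigError("years must be non-empty")
        if self.base_rate <= 0:
            raise ConfigError("base_rate must be positive")
        if self.sigma_eps < 0:
            raise ConfigError("sigma_eps must be non-negative")
        if not (0.0 <= self.latent_strength <= 1.0):
            raise ConfigError("latent_strength must be in [0, 1]")
        if self.beta is not None:
            allowed = set(FEATURE_NAMES) - {"Population"}
            bad = set(self.beta) - allowed
            if bad:
                raise ConfigError(f"beta keys not allowed: {sorted(bad)}")
        self.years = tuple(int(y) for y in self.years)


@dataclass
class PlantedTruth:
    """Ground truth carried alongside a generated panel for recovery tests."""

    beta: dict[str, float]
    true_rate: pd.DataFrame = field(repr=False)  # fips, year, rate_per_100k
    direction: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.direction:
            self.direction = {f: int(np.sign(b)) for f, b in self.beta.items()}


def realized_beta(config: SyntheticConfig) -> dict[str, float]:
    """The full effect map for a config: explicit overrides, the default
    strong quartet, and seed-determined nuisance draws for the rest."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5EED]))
    lo, hi = NUISANCE_BETA_RANGE
    beta: dict[str, float] = {}
    for f in FEATURE_NAMES:
        if f == "Population":
            continue
        if config.beta is not None and f in config.beta:
            beta[f] = float(config.beta[f])
        elif config.beta is None and f in DEFAULT_STRONG_BETA:
            beta[f] = DEFAULT_STRONG_BETA[f]
        elif config.beta is None:
            beta[f] = float(rng.uniform(lo, hi))
        else:
            beta[f] = 0.0
    return beta


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Draw-until-inside truncation; exact for our mild truncations."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def generate_panel(config: SyntheticConfig) -> tuple[CountyPanel, PlantedTruth]:
    """Draw a county panel and its planted truth.  Bit-reproducible per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0DE]))
    n = config.n_counties
    years = np.asarray(config.years)
    beta = realized_beta(config)

    fips = np.array([f"{i + 1:05d}" for i in range(n)])
    names = np.array([f"Synth County {i + 1}" for i in range(n)])
    states = np.array([_USPS[i % len(_USPS)] for i in range(n)])

    population = np.exp(rng.normal(10.3, 1.3, size=n))
    population = np.clip(population, 100.0, 1e7).round()

    feats = pd.DataFrame(index=np.arange(n))
    feats["Population"] = population / 1000.0  # census-style thousands
    feats["%Female"] = _truncated_normal(rng, 50.4, 2.2, 20.0, 60.0, n)
    race = rng.dirichlet((8.0, 1.5, 0.5), size=n) * 100.0
    feats["%White"] = race[:, 0]
    feats["%AfricanAmerican"] = race[:, 1]
    feats["%OtherRaces"] = race[:, 2]
    feats["MedianAge"] = _truncated_normal(rng, 41.0, 5.4, 20.0, 65.0, n)

    deprivation = rng.normal(size=n)  # shared latent factor
    rho = config.latent_strength
    for f, (mean, scale, lo, hi, sign) in _DEPRIVATION_FEATURES.items():
        noise = rng.normal(size=n)
        latent = sign * rho * deprivation + np.sqrt(1.0 - rho**2) * noise
        feats[f] = np.clip(mean + scale * latent, lo, hi)

    # Within-panel z-scores drive the planted log-rate effects.
    lin = np.zeros(n)
    for f, b in beta.items():
        col = feats[f].to_numpy()
        sd = col.std(ddof=0)
        if b != 0.0 and sd > 0:
            lin += b * (col - col.mean()) / sd

    eps = rng.normal(0.0, config.sigma_eps, size=n) if config.sigma_eps > 0 else np.zeros(n)
    log_rate0 = np.log(config.base_rate) + lin + eps

    records = []
    truth_rows = []
    for t_index, year in enumerate(years):
        rate = np.exp(log_rate0 + t_index * np.log1p(config.trend))
        mu = rate * population / 1e5
        suicides = rng.poisson(mu)
        records.append(
            pd.DataFrame(
                {
                    "fips": fips,
                    "name": names,
                    "state": states,
                    "year": int(year),
                    "population": population,
                    "suicides": suicides,
                    **{f: feats[f].to_numpy() for f in FEATURE_NAMES},
                }
            )
        )
        truth_rows.append(pd.DataFrame({"fips": fips, "year": int(year), "rate_per_100k": rate}))

    frame = pd.concat(records, ignore_index=True)
    panel = CountyPanel(frame)
    truth = PlantedTruth(beta=beta, true_rate=pd.concat(truth_rows, ignore_index=True))
    return panel, truth


def planted_truth_summary(truth: PlantedTruth) -> list[tuple[str, float, int]]:
    """Features ordered by descending |beta|, name-alphabetical on ties.

    Returns (feature, beta, direction) triples; deterministic regardless
    of the beta map's insertion order.
    """
    items = sorted(truth.beta.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [(f, b, truth.direction.get(f, int(np.sign(b)))) for f, b in items]


def write_truth(truth: PlantedTruth, sink) -> None:
    """Machine-readable truth sidecar (JSON header + rate table CSV)."""
    import json

    payload = {
        "beta": truth.beta,
        "direction": truth.direction,
        "true_rate_csv": truth.true_rate.to_csv(index=False, float_format="%.10g", lineterminator="\n"),
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
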