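"""County-level trend and distribution statistics.

Percent change in annual suicide counts over the study window, the
fraction of counties at or above change thresholds, per-county average
rate per 100,000, national rate by year, and the shade bins used for
rate maps.  Counties with a zero first-year count have no defined
percent change; they are excluded from the threshold fractions and
listed in an exclusion report so the denominator choice stays auditable
(public mortality registries suppress small counts, so the real-data
denominator is ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import RATE_BINS, BinSpec, CountyPanel


class TrendError(ValueError):
    """Undefined or ill-posed trend computation."""


def percent_change(first: float, last: float) -> float:
    """100 × (last − first) / first; undefined when first is 0."""
    if first <= 0:
        raise TrendError(f"percent change undefined for first-year count {first}")
    return 100.0 * (last - first) / first


@dataclass
class TrendSummary:
    per_county: dict[str, float]  # fips -> percent change first->last year
    frac_ge: dict[float, float]  # threshold (%) -> fraction of counties at/above
    n_counties_evaluated: int
    national_rate_by_year: dict[int, float]  # suicides per 100,000
    excluded: list[str] = field(default_factory=list)  # zero first-year count

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"fips": list(self.per_county), "percent_change": list(self.per_county.values())}
        )
        return df.sort_values("fips").reset_index(drop=True)


def national_rate_by_year(panel: CountyPanel) -> dict[int, float]:
    """Population-weighted national suicide rate per 100,000, by year."""
    g = panel.frame.groupby("year")[["suicides", "population"]].sum()
    return {int(y): float(r.suicides / r.population * 1e5) for y, r in g.iterrows()}


def trend_summary(
    panel: CountyPanel, thresholds: Sequence[float] = (10.0, 50.0)
) -> TrendSummary:
    """Percent-change statistics between the panel's first and last year.

    ``frac_ge[t]`` is the fraction of counties whose percent change
    strictly exceeds t — a county sitting exactly at the threshold does
    not count.  Fractions are over counties with a positive first-year
    count; the excluded counties are reported, never silently dropped.
    """
    years = panel.years
    if len(years) < 2:
        raise TrendError("trend summary needs a panel spanning at least 2 years")
    first_y, last_y = years[0], years[-1]
    df = panel.frame
    first = df[df["year"] == first_y].set_index("fips")["suicides"]
    last = df[df["year"] == last_y].set_index("fips")["suicides"]
    common = first.index.intersection(last.index)

    per_county: dict[str, float] = {}
    excluded: list[str] = []
    for fips in common:
        f, l = int(first[fips]), int(last[fips])
        if f <= 0:
            excluded.append(fips)
        else:
            per_county[fips] = percent_change(f, l)

    changes = np.asarray(list(per_county.values()), dtype=float)
    n_eval = len(changes)
    frac_ge = {
        float(t): float((changes > t).sum() / n_eval) if n_eval else float("nan")
        for t in thresholds
    }
    return TrendSummary(
        per_county=per_county,
        frac_ge=frac_ge,
        n_counties_evaluated=n_eval,
        national_rate_by_year=national_rate_by_year(panel),
        excluded=sorted(excluded),
    )


def average_rate_per_100k(panel: CountyPanel, fips: str) -> float:
    """Mean over panel years of the county's annual rate per 100,000."""
    sub = panel.frame[panel.frame["fips"] == fips]
    missing = sorted(set(panel.years) - set(sub["year"]))
    if missing:
        raise TrendError(f"county {fips} missing year(s) {missing}")
    rates = sub["suicides"] / sub["population"] * 1e5
    return float(rates.mean())


def average_rates(panel: CountyPanel) -> dict[str, float]:
    """Vectorized average annual rate per 100,000 for every county."""
    df = panel.frame.copy()
    counts = df.groupby("fips")["year"].count()
    incomplete = counts[counts != len(panel.years)]
    if len(incomplete):
        raise TrendError(f"counties missing years: {list(incomplete.index[:10])}")
    df["rate"] = df["suicides"] / df["population"] * 1e5
    return {str(k): float(v) for k, v in df.groupby("fips")["rate"].mean().items()}


def bin_rates(
    values: Mapping[str, float], bins: BinSpec = RATE_BINS
) -> dict[str, str]:
    """Assign each county's average rate to a shade bin (top bin open)."""
    keys = list(values)
    arr = np.asarray([values[k] for k in keys], dtype=float)
    if np.any(arr < 0):
        raise TrendError("negative rate passed to bin_rates")
    labels = bins.assign(arr) if len(arr) else np.array([], dtype=object)
    return {k: str(l) for k, l in zip(keys, labels)}
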