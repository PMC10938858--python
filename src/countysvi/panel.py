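"""County-year panel: schema, validation, CSV I/O and choropleth export.

The unit of analysis is the US county, keyed by its 5-digit FIPS code
(2-digit state + 3-digit county).  A panel holds one record per
(fips, year) with the county's population, suicide count and the 17
county-level characteristics grouped as Demographics / Socio-economic /
Health.  FIPS codes are always stored as zero-padded strings — several
states have leading zeros and integer keys silently break GeoJSON joins.

Missing feature values are rejected, never imputed.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical feature order (Demographics, Socio-economic, Health).
FEATURE_NAMES: tuple[str, ...] = (
    "Population",
    "%Female",
    "%White",
    "%AfricanAmerican",
    "%OtherRaces",
    "MedianAge",
    "MedianIncome",
    "%Poverty",
    "%Unemployed",
    "%SomeCollege",
    "SocialAssociationRate",
    "%SingleParentHouseholds",
    "ViolentCrimeRate",
    "OpioidDispensingRate",
    "%Uninsured",
    "MentallyUnhealthyDays",
    "%ExcessiveDrinking",
)

#: Percentage-valued features, constrained to [0, 100].
PERCENT_FEATURES: tuple[str, ...] = tuple(f for f in FEATURE_NAMES if f.startswith("%"))

#: Non-negative rate features.
RATE_FEATURES: tuple[str, ...] = (
    "SocialAssociationRate",
    "ViolentCrimeRate",
    "OpioidDispensingRate",
    "MentallyUnhealthyDays",
)

META_COLUMNS: tuple[str, ...] = ("fips", "name", "state", "year", "population", "suicides")

#: Canonical CSV column order.
CANONICAL_COLUMNS: tuple[str, ...] = META_COLUMNS + FEATURE_NAMES

_FIPS_RE = re.compile(r"^\d{5}$")
_STATE_RE = re.compile(r"^[A-Z]{2}$")


class PanelError(ValueError):
    """Base class for panel construction and I/O failures."""


class SchemaError(PanelError):
    """A mandatory column is absent or unmappable."""


class IntegrityError(PanelError):
    """Duplicate (fips, year) keys or other structural corruption."""


class ValidationError(PanelError):
    """One or more records violate the panel invariants.

    Carries *every* violation found, not only the first.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        preview = "; ".join(self.violations[:5])
        more = f" (+{len(self.violations) - 5} more)" if len(self.violations) > 5 else ""
        super().__init__(f"{len(self.violations)} invalid record(s): {preview}{more}")


def normalize_fips(value: object) -> str:
    """Zero-pad a FIPS code to the canonical 5-character string form."""
    s = str(value).strip()
    if s.endswith(".0"):  # float contamination from permissive CSV readers
        s = s[:-2]
    s = s.zfill(5)
    if not _FIPS_RE.match(s):
        raise ValidationError([f"invalid FIPS code {value!r}"])
    return s


def _collect_violations(df: pd.DataFrame) -> list[str]:
    """All invariant violations in a panel frame, one message per offence."""
    v: list[str] = []
    for idx, row in df.iterrows():
        key = f"({row['fips']}, {row['year']})"
        if not _FIPS_RE.match(str(row["fips"])):
            v.append(f"{key}: malformed fips")
        if not _STATE_RE.match(str(row["state"])):
            v.append(f"{key}: state {row['state']!r} is not a 2-letter USPS code")
        if not np.isfinite(row["population"]) or row["population"] <= 0:
            v.append(f"{key}: population must be > 0, got {row['population']}")
        s = row["suicides"]
        if not np.isfinite(s) or s < 0 or float(s) != int(s):
            v.append(f"{key}: suicides must be a non-negative integer, got {s}")
        for f in FEATURE_NAMES:
            x = row[f]
            if not np.isfinite(x):
                v.append(f"{key}: feature {f} missing or non-finite")
        for f in PERCENT_FEATURES:
            x = row[f]
            if np.isfinite(x) and not (0.0 <= x <= 100.0):
                v.append(f"{key}: {f}={x} outside [0, 100]")
        race = row["%White"] + row["%AfricanAmerican"] + row["%OtherRaces"]
        if np.isfinite(race) and race > 100.5:  # 0.5 slack for published rounding
            v.append(f"{key}: race shares sum to {race:.3f} > 100.5")
        age = row["MedianAge"]
        if np.isfinite(age) and not (0.0 < age < 120.0):
            v.append(f"{key}: MedianAge={age} outside (0, 120)")
        for f in RATE_FEATURES:
            x = row[f]
            if np.isfinite(x) and x < 0:
                v.append(f"{key}: {f}={x} negative")
    return v


@dataclass
class CountyPanel:
    """A validated tidy county-year table.

    Attributes
    ----------
    frame : DataFrame with the canonical columns, sorted by (fips, year).
    feature_names : the 17 feature columns in canonical order.
    rejected : audit report of rows dropped during permissive reading,
        as (source row index, reason) pairs.
    """

    frame: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"panel frame lacks columns: {missing}")
        dup = df.duplicated(subset=["fips", "year"])
        if dup.any():
            keys = df.loc[dup, ["fips", "year"]].itertuples(index=False, name=None)
            raise IntegrityError(f"duplicate (fips, year) keys: {sorted(set(keys))[:10]}")
        violations = _collect_violations(df)
        if violations:
            raise ValidationError(violations)
        df = df[list(CANONICAL_COLUMNS)].sort_values(["fips", "year"], kind="mergesort")
        df = df.reset_index(drop=True)
        df["year"] = df["year"].astype(int)
        df["population"] = df["population"].astype(float)
        df["suicides"] = df["suicides"].astype(int)
        object.__setattr__(self, "frame", df)

    # -- convenience views -------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def counties(self) -> list[str]:
        return sorted(self.frame["fips"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())

    def county_meta(self) -> pd.DataFrame:
        """One row per county: fips, name, state."""
        return (
            self.frame[["fips", "name", "state"]]
            .drop_duplicates("fips")
            .sort_values("fips")
            .reset_index(drop=True)
        )


def read_panel(
    source,
    schema: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
) -> CountyPanel:
    """Read and validate a panel CSV.

    Parameters
    ----------
    source : path or text stream with a header row.
    schema : optional map of file column name -> canonical column name.
    strict : when True (default), any invariant violation raises
        :class:`ValidationError` listing every offence.  When False,
        offending rows are dropped and reported in ``panel.rejected``.
    """
    df = pd.read_csv(source, dtype={"fips": str})
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    df = df[list(CANONICAL_COLUMNS)].copy()

    for col in ("year", "population", "suicides") + FEATURE_NAMES:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() and strict:
            rows = list(df.index[bad][:5])
            raise PanelError(f"non-numeric value in column {col!r} at row(s) {rows}")
        df[col] = coerced

    df["fips"] = df["fips"].map(lambda s: str(s).strip().zfill(5))
    df["state"] = df["state"].astype(str).str.strip().str.upper()

    dup = df.duplicated(subset=["fips", "year"])
    if dup.any():
        keys = df.loc[dup, ["fips", "year"]].itertuples(index=False, name=None)
        raise IntegrityError(f"duplicate (fips, year) keys: {sorted(set(keys))[:10]}")

    if strict:
        return CountyPanel(df)

    violations = _collect_violations(df)
    bad_idx: dict[int, str] = {}
    for msg in violations:
        key = msg.split(":")[0]
        for idx, row in df.iterrows():
            if f"({row['fips']}, {row['year']})" == key:
                bad_idx.setdefault(idx, msg)
    kept = df.drop(index=list(bad_idx))
    panel = CountyPanel(kept)
    panel.rejected = sorted(bad_idx.items())
    return panel


def write_panel(panel: CountyPanel, sink) -> int:
    """Write a panel in canonical form; returns the number of data rows.

    Canonical form: canonical column order, rows sorted by (fips, year),
    floats rendered with 10 significant digits so read/write round-trips
    are value-identity.
    """
    df = panel.frame
    text = df.to_csv(index=False, float_format="%.10g", lineterminator="\n")
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    return len(df)


# ---------------------------------------------------------------------------
# Binning and choropleth export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinSpec:
    """Half-open bins [e_k, e_{k+1}) over ascending edges.

    ``top_open`` appends a final [last_edge, inf) bin labelled ">=last";
    otherwise the final bin is [e_{n-2}, e_{n-1}] closed at the top, as
    used for index values on [0, 1].
    """

    edges: tuple[float, ...]
    top_open: bool = False

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("bin edges must be strictly ascending, length >= 2")
        object.__setattr__(self, "edges", e)

    @property
    def labels(self) -> list[str]:
        def fmt(x: float) -> str:
            return f"{x:g}"

        labels = [f"{fmt(a)}–{fmt(b)}" for a, b in zip(self.edges, self.edges[1:])]
        if self.top_open:
            labels.append(f"≥{fmt(self.edges[-1])}")
        return labels

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Vector of bin labels; raises on values outside the spec's domain."""
        x = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError("cannot bin non-finite values")
        if np.any(x < self.edges[0]):
            raise ValueError(f"value below first edge {self.edges[0]}")
        if not self.top_open and np.any(x > self.edges[-1]):
            raise ValueError(f"value above closed top edge {self.edges[-1]}")
        idx = np.searchsorted(self.edges, x, side="right") - 1
        n_inner = len(self.edges) - 1
        if self.top_open:
            idx = np.minimum(idx, n_inner)  # >= last edge -> open top bin
        else:
            idx = np.minimum(idx, n_inner - 1)  # x == top edge -> last closed bin
        return np.asarray(self.labels)[idx]


#: Vulnerability-index bins: [0,0.2), ..., [0.8,1] (top closed).
SVI_BINS = BinSpec(edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0), top_open=False)

#: Average-rate shade bins: [0,10), width-5 steps, then ≥35.
RATE_BINS = BinSpec(edges=(0.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0), top_open=True)


@dataclass
class ChoroplethExport:
    """FIPS-keyed table ready to join onto county GeoJSON, plus the list
    of requested counties with no value (never silently dropped)."""

    table: pd.DataFrame  # columns fips, value, bin
    unmapped: list[str] = field(default_factory=list)

    def to_csv(self, sink) -> None:
        self.table.to_csv(sink, index=False, float_format="%.10g", lineterminator="\n")


def export_choropleth(
    values: Mapping[str, float],
    bins: BinSpec = SVI_BINS,
    requested_fips: Iterable[str] | None = None,
) -> ChoroplethExport:
    """Build a fips/value/bin table for map joins.

    ``requested_fips`` lets the caller demand coverage of a county list;
    counties without a value are returned in the ``unmapped`` report.
    """
    keys = [normalize_fips(k) for k in values]
    vals = np.asarray([float(values[k]) for k in values], dtype=float)
    order = np.argsort(keys, kind="mergesort")
    keys = [keys[i] for i in order]
    vals = vals[order]
    labels = bins.assign(vals) if len(vals) else np.array([], dtype=object)
    table = pd.DataFrame({"fips": keys, "value": vals, "bin": labels})
    unmapped: list[str] = []
    if requested_fips is not None:
        have = set(keys)
        unmapped = sorted(normalize_fips(f) for f in requested_fips if normalize_fips(f) not in have)
    return ChoroplethExport(table=table, unmapped=unmapped)


def panel_from_text(text: str, **kwargs) -> CountyPanel:
    """Read a panel from an in-memory CSV string (test convenience)."""
    return read_panel(io.StringIO(text), **kwargs)
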