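"""Monetary valuation of indicator declines.

Two services are valued per cell as the difference of net present values
between the historical and the future period:

* Habitat — a single per-hectare habitat service value (HSV) obtained by
  benefit transfer: valuation records are cleaned, grouped by major biome,
  per-service means are summed within each biome, and the across-biome mean
  (inflation-corrected to 2015) is the baseline. Under discounting the
  baseline is prolongated to the historical central year 1999
  (``HSV_1999 = HSV_2015 * (1+d)^16``) and discounted to the future central
  year 2085 (``HSV_2085 = HSV_2015 / (1+d)^70``). The habitat indicator is
  1 for the historical period (the reference biome equals itself) and
  stability/100 for the future.
* Climate regulation — the social cost of carbon (SCC, $/tCO2) times
  period-mean sequestration. Discounted variant: damage-function averages at
  2% rate, year 2015 (historical) and 2085 (future). Undiscounted variant:
  the 2085 value at 0% rate held constant for both periods.

Four valuation variants arise from (global | national prices) x (2% | no
discounting); national prices scale by country GDP per capita relative to
the world average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CLIMATE_SERVICE, PROVISIONING_SERVICES, RECORD_COLUMNS

HISTORICAL_SPAN = 2015 - 1999   # prolongation exponent, years
FUTURE_SPAN = 2085 - 2015       # discounting exponent, years

QUANTILE_LOW = 0.05
QUANTILE_HIGH = 0.95


# ---------------------------------------------------------------------------
# record cleaning and the habitat baseline

def clean_records(raw: pd.DataFrame,
                  climate_service: str = CLIMATE_SERVICE,
                  provisioning_services: tuple[str, ...] = PROVISIONING_SERVICES,
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean a benefit-transfer record table.

    Drops, in order: rows with any missing field; exact duplicate rows
    (first occurrence kept); climate-regulation rows (valued separately via
    the SCC); provisioning-service rows (managed-forest products); then rows
    whose value falls outside the inclusive [5%, 95%] quantile band of the
    remaining values (linear-interpolation quantiles). Returns the cleaned
    table and a report counting each drop reason.
    """
    missing_cols = set(RECORD_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise ValueError(f"record table lacks columns {sorted(missing_cols)}")
    report: dict[str, int] = {"n_input": len(raw)}
    df = raw.copy()

    has_missing = df[list(RECORD_COLUMNS)].isna().any(axis=1)
    report["n_missing"] = int(has_missing.sum())
    df = df[~has_missing]

    dup = df.duplicated(keep="first")
    report["n_duplicates"] = int(dup.sum())
    df = df[~dup]

    is_climate = df["service"] == climate_service
    report["n_climate_regulation"] = int(is_climate.sum())
    df = df[~is_climate]

    is_prov = df["service"].isin(provisioning_services)
    report["n_provisioning"] = int(is_prov.sum())
    df = df[~is_prov]

    if df.empty:
        raise ValueError("no records remain after service exclusions")
    v = df["value_usd_per_ha_yr"].to_numpy(dtype=float)
    lo, hi = np.quantile(v, [QUANTILE_LOW, QUANTILE_HIGH], method="linear")
    in_band = (v >= lo) & (v <= hi)
    report["n_outlier_trimmed"] = int((~in_band).sum())
    df = df[in_band]
    if df.empty:
        raise ValueError("no records remain after quantile trimming")
    report["n_retained"] = len(df)
    return df.reset_index(drop=True), report


def habitat_baseline(records: pd.DataFrame, inflation_factor: float = 1.0,
                     ) -> float:
    """Benefit-transfer HSV baseline in 2015 $/ha/yr.

    Per biome group, service means are summed (total-economic-value style);
    the result is the across-biome mean times the inflation factor to 2015.
    Biome groups without records simply do not enter the mean.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    per_service = records.groupby(["biome", "service"])["value_usd_per_ha_yr"].mean()
    per_biome = per_service.groupby(level="biome").sum()
    return float(per_biome.mean() * inflation_factor)


# ---------------------------------------------------------------------------
# discounting algebra (net present values of the habitat service)

def prolongate_hsv(hsv_2015: float, d: float,
                   span: int = HISTORICAL_SPAN) -> float:
    """Project the 2015 baseline back to the historical central year 1999."""
    if d < 0:
        raise ValueError("discount rate must be >= 0")
    return hsv_2015 * (1.0 + d) ** span


def discount_hsv(hsv_2015: float, d: float, span: int = FUTURE_SPAN) -> float:
    """Discount the 2015 baseline to the future central year 2085."""
    if d < 0:
        raise ValueError("discount rate must be >= 0")
    return hsv_2015 / (1.0 + d) ** span


@dataclass(frozen=True)
class HabitatServiceValue:
    """Resolved per-hectare habitat values for one discounting variant."""

    hsv_2015: float
    hsv_historical: float
    hsv_future: float
    discount_rate: float

    def __post_init__(self) -> None:
        if not self.hsv_2015 > 0:
            raise ValueError("hsv_2015 must be > 0")
        if self.discount_rate > 0:
            if not (self.hsv_historical > self.hsv_2015 > self.hsv_future):
                raise ValueError("discounted HSVs must satisfy hist > 2015 > future")
        elif not (self.hsv_historical == self.hsv_2015 == self.hsv_future):
            raise ValueError("without discounting all HSVs must be equal")

    @classmethod
    def resolve(cls, hsv_2015: float, d: float) -> "HabitatServiceValue":
        return cls(hsv_2015=hsv_2015,
                   hsv_historical=prolongate_hsv(hsv_2015, d),
                   hsv_future=discount_hsv(hsv_2015, d),
                   discount_rate=d)


# ---------------------------------------------------------------------------
# carbon prices

@dataclass(frozen=True)
class CarbonPrice:
    """SCC pair applied to the historical and future period, $/tCO2."""

    scc_historical: float
    scc_future: float
    ssp: str
    discount_rate: float

    def __post_init__(self) -> None:
        if not (self.scc_historical > 0 and self.scc_future > 0):
            raise ValueError("SCC values must be > 0")
        if self.discount_rate == 0 and self.scc_historical != self.scc_future:
            raise ValueError("undiscounted variant holds the SCC constant")


def _scc_cell(table: pd.DataFrame, year: int, ssp: str, rate: float) -> float:
    sel = table[(table["year"] == year) & (table["ssp"] == ssp)
                & (np.isclose(table["discount_rate"], rate))]
    if sel.empty:
        raise ValueError(
            f"SCC table has no entry for year={year}, ssp={ssp!r}, rate={rate}")
    return float(sel["scc_usd_per_tco2"].mean())  # average across damage functions


def resolve_scc(table: pd.DataFrame, ssp: str, discounted: bool,
                rate: float = 0.02) -> CarbonPrice:
    """Pick the SCC pair for one valuation variant.

    Discounted: damage-function means at the given rate for 2015 (closest
    available year to the historical period) and 2085 (future central year).
    Undiscounted: the 2085 value at 0% rate, held constant for both periods.
    """
    if discounted:
        return CarbonPrice(scc_historical=_scc_cell(table, 2015, ssp, rate),
                           scc_future=_scc_cell(table, 2085, ssp, rate),
                           ssp=ssp, discount_rate=rate)
    v = _scc_cell(table, 2085, ssp, 0.0)
    return CarbonPrice(scc_historical=v, scc_future=v, ssp=ssp, discount_rate=0.0)


# ---------------------------------------------------------------------------
# per-cell costs

def habitat_cost(stability, hsv: HabitatServiceValue, price_factor=1.0):
    """Raw (signed) habitat cost in $/ha/yr.

    NPV difference between the historical period (habitat indicator 1 by
    construction) and the future period (indicator stability/100), scaled by
    the price factor. Positive = cost to society. Accepts scalars or arrays;
    callers floor at zero when reporting "costs".
    """
    stability = np.asarray(stability, dtype=float)
    if np.any(stability < 0) or np.any(stability > 100):
        raise ValueError("stability must lie in [0, 100]")
    out = np.asarray(price_factor, dtype=float) * (
        hsv.hsv_historical - hsv.hsv_future * stability / 100.0)
    return float(out) if out.ndim == 0 else out


def climate_cost(seq_ref, seq_fut, price: CarbonPrice, price_factor=1.0):
    """Raw (signed) climate-regulation cost in $/ha/yr.

    Period sequestration valued at the period SCC and differenced; positive
    when the valued future sink is smaller than the valued historical sink.
    """
    seq_ref = np.asarray(seq_ref, dtype=float)
    seq_fut = np.asarray(seq_fut, dtype=float)
    if not (np.all(np.isfinite(seq_ref)) and np.all(np.isfinite(seq_fut))):
        raise ValueError("sequestration inputs must be finite")
    out = np.asarray(price_factor, dtype=float) * (
        price.scc_historical * seq_ref - price.scc_future * seq_fut)
    return float(out) if out.ndim == 0 else out


def floor_costs(raw):
    """Positive part of a raw cost surface — the reported 'cost'."""
    return np.maximum(np.asarray(raw, dtype=float), 0.0)


# ---------------------------------------------------------------------------
# price schemes

def national_factor(country_gdppc: float, world_gdppc: float) -> float:
    """Per-country price factor: GDP per capita over the world average."""
    if not (country_gdppc > 0 and world_gdppc > 0):
        raise ValueError("GDP per capita values must be > 0")
    return country_gdppc / world_gdppc


@dataclass(frozen=True)
class PriceScheme:
    """Global (uniform) or national (GDP-scaled) price factors."""

    mode: str                       # "global" | "national"
    factors: pd.Series              # per-country factor, index = country

    def __post_init__(self) -> None:
        if self.mode not in ("global", "national"):
            raise ValueError("mode must be 'global' or 'national'")
        if np.any(self.factors.to_numpy() <= 0):
            raise ValueError("price factors must be > 0")

    @classmethod
    def resolve(cls, mode: str, country_table: pd.DataFrame) -> "PriceScheme":
        idx = country_table["country"]
        if mode == "global":
            return cls(mode, pd.Series(1.0, index=idx))
        f = [national_factor(r.gdp_per_capita, r.world_gdp_per_capita)
             for r in country_table.itertuples()]
        return cls(mode, pd.Series(f, index=idx))

    def factor_map(self, country_map: np.ndarray,
                   countries: tuple[str, ...]) -> np.ndarray:
        """Per-cell price factors from an integer country-index map."""
        lut = self.factors.reindex(list(countries)).to_numpy(dtype=float)
        if np.any(~np.isfinite(lut)):
            raise ValueError("price scheme lacks a factor for some country")
        return lut[country_map]


@dataclass(frozen=True)
class ValuationVariant:
    """One of the four variants: price mode x discounting."""

    price_mode: str        # "global" | "national"
    discount_rate: float   # 0.0 or 0.02

    @property
    def discounted(self) -> bool:
        return self.discount_rate > 0

    @property
    def name(self) -> str:
        return f"{self.price_mode}-{'d2' if self.discounted else 'd0'}"


DEFAULT_VARIANTS = (
    ValuationVariant("global", 0.0),
    ValuationVariant("global", 0.02),
    ValuationVariant("national", 0.0),
    ValuationVariant("national", 0.02),
)
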