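"""Synthetic inputs with controlled ground truth.

Stands in for the two data sources the analysis needs but cannot ship:
gridded dynamic-vegetation-model output (PFT composition and net ecosystem
exchange per cell and year) and the economic source tables (ecosystem-service
valuation records, a social-cost-of-carbon table, national GDP figures).

The landscape generator draws spatially coherent biome regions on an
abstract lattice, holds the biome constant through the 30-year reference
period, and in the future period flips each cell-year's biome independently
with a per-cell probability (i.i.d. Bernoulli flips, so the downstream
stability statistic is exactly binomial and analytically checkable). The
realized — not nominal — flip fractions and NEE period means are recorded as
ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .biomes import BiomeScheme, DEFAULT_ROSTER
from .indicators import carbon_to_co2_per_ha

# ---------------------------------------------------------------------------
# seeding

def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from one root seed.

    Keeps e.g. the landscape realization identical across valuation
    variants while decoupling it from the economic-table draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# grids and scenarios

DEFAULT_COUNTRIES: tuple[str, ...] = (
    "BZ", "CO", "CR", "SV", "GT", "HN", "MX", "NI", "PA")


def block_country_map(n_rows: int, n_cols: int,
                      countries: tuple[str, ...] = DEFAULT_COUNTRIES) -> np.ndarray:
    """Contiguous rectangular country blocks covering the lattice."""
    n = len(countries)
    nb = int(np.ceil(np.sqrt(n)))
    row_band = np.minimum(np.arange(n_rows) * nb // n_rows, nb - 1)
    col_band = np.minimum(np.arange(n_cols) * nb // n_cols, nb - 1)
    idx = row_band[:, None] * nb + col_band[None, :]
    return np.minimum(idx, n - 1)


@dataclass
class GridSpec:
    """Abstract analysis lattice: no projection, constant cell area."""

    n_rows: int = 100
    n_cols: int = 100
    cell_area_ha: float = 100.0
    countries: tuple[str, ...] = DEFAULT_COUNTRIES
    country_map: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_area_ha > 0:
            raise ValueError("cell_area_ha must be > 0")
        if self.country_map is None:
            self.country_map = block_country_map(self.n_rows, self.n_cols,
                                                 tuple(self.countries))
        self.country_map = np.asarray(self.country_map)
        if self.country_map.shape != (self.n_rows, self.n_cols):
            raise ValueError("country_map shape must match the grid")
        if self.country_map.min() < 0 or self.country_map.max() >= len(self.countries):
            raise ValueError("country_map indices out of range")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise, rank-normalised to uniform (0, 1)."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    ranks = z.ravel().argsort().argsort()
    return ((ranks + 0.5) / z.size).reshape(shape)


@dataclass
class ScenarioSpec:
    """Per-cell future-period forcing of biome flips and NEE trends."""

    name: str
    flip_rate_map: np.ndarray
    nee_trend_map: np.ndarray
    ssp: str = "SSP1"
    n_years_reference: int = 30
    n_years_future: int = 30

    def __post_init__(self) -> None:
        self.flip_rate_map = np.asarray(self.flip_rate_map, dtype=float)
        self.nee_trend_map = np.asarray(self.nee_trend_map, dtype=float)
        if self.n_years_reference < 1 or self.n_years_future < 1:
            raise ValueError("year counts must be >= 1")
        if np.any(self.flip_rate_map < 0) or np.any(self.flip_rate_map > 1):
            raise ValueError("flip rates must lie in [0, 1]")
        if self.flip_rate_map.shape != self.nee_trend_map.shape:
            raise ValueError("flip and trend maps must share a shape")

    @classmethod
    def preset(cls, name: str, grid: GridSpec) -> "ScenarioSpec":
        """Scenario surrogate for one GCM × SSP combination.

        Mild-forcing (SSP126-style) presets use low flip rates, so most of
        the area stays above 50% stability, but widespread negative NEE
        trends (weaker CO2 fertilization); strong-forcing (SSP370-style)
        presets flip more but show fewer cells with reduced uptake.
        """
        rng = substream(grid.seed, f"scenario:{name}")
        upper = name.upper()
        strong = "370" in upper
        ssp = "SSP3" if strong else "SSP1"
        sigma = max(min(grid.shape) / 12.0, 1.0)
        u_flip = _smooth_field(rng, grid.shape, sigma)
        u_trend = _smooth_field(rng, grid.shape, sigma)
        if strong:
            # more flips; net uptake increases over most of the area
            # (CO2-fertilization analogue) but with stronger extremes
            flip = np.clip(0.02 + 0.75 * u_flip ** 1.8, 0.0, 1.0)
            co2_trend = 2.5 * (0.70 - u_trend)
        else:
            flip = np.clip(0.01 + 0.70 * u_flip ** 2.0, 0.0, 1.0)
            co2_trend = 2.0 * (0.40 - u_trend)
        # co2_trend is the change in CO2 uptake (t CO2/ha/yr); stored as the
        # equivalent NEE change (kgC/m²/yr, atmospheric sign convention)
        nee_trend = -co2_trend / (3.67 * 10.0)
        return cls(name=name, flip_rate_map=flip, nee_trend_map=nee_trend, ssp=ssp)


DEFAULT_SCENARIOS = ("GFDL-SSP126", "IPSL-SSP126", "GFDL-SSP370", "IPSL-SSP370")


# ---------------------------------------------------------------------------
# landscape

#: Per-biome PFT archetypes (LAI by roster PFT) and precipitation
#: seasonality. Multiplicative LAI noise of ±10% and additive seasonality
#: noise of ±0.05 never cross the default scheme's thresholds, so the
#: classifier recovers the intended biome exactly.
ARCHETYPES: dict[str, tuple[dict[str, float], float]] = {
    "tropical_rain_forest": ({"TrBE": 4.5, "TrBR": 0.3, "TeBE": 0.2, "TeNE": 0.1,
                              "C4G": 0.2, "C3G": 0.1}, 0.30),
    "tropical_dry_forest": ({"TrBE": 0.4, "TrBR": 3.4, "TeBE": 0.2, "TeNE": 0.1,
                             "C4G": 0.5, "C3G": 0.1}, 1.00),
    "tropical_needleleaf_forest": ({"TrBE": 0.2, "TrBR": 0.3, "TeBE": 3.0,
                                    "TeNE": 0.2, "C4G": 0.4, "C3G": 0.2}, 1.20),
    "temperate_evergreen_forest": ({"TrBE": 0.2, "TrBR": 0.1, "TeBE": 3.0,
                                    "TeNE": 0.3, "C4G": 0.1, "C3G": 0.4}, 0.40),
    "montane_forest": ({"TrBE": 0.1, "TrBR": 0.1, "TeBE": 0.4, "TeNE": 3.2,
                        "C4G": 0.1, "C3G": 0.5}, 0.50),
    "savanna": ({"TrBE": 0.9, "TrBR": 0.3, "TeBE": 0.05, "TeNE": 0.05,
                 "C4G": 2.0, "C3G": 0.3}, 1.10),
    "grassland": ({"TrBE": 0.1, "TrBR": 0.05, "TeBE": 0.03, "TeNE": 0.02,
                   "C4G": 2.2, "C3G": 0.6}, 0.90),
    "barren": ({"TrBE": 0.02, "TrBR": 0.02, "TeBE": 0.02, "TeNE": 0.02,
                "C4G": 0.01, "C3G": 0.01}, 1.30),
}

#: Landscape composition of the reference map (forest-dominated region).
BIOME_PROPORTIONS: dict[str, float] = {
    "tropical_rain_forest": 0.34,
    "tropical_dry_forest": 0.16,
    "tropical_needleleaf_forest": 0.06,
    "temperate_evergreen_forest": 0.08,
    "montane_forest": 0.12,
    "savanna": 0.10,
    "grassland": 0.09,
    "barren": 0.05,
}

#: Period-mean NEE by biome (kgC/m²/yr, negative = uptake).
BIOME_NEE: dict[str, float] = {
    "tropical_rain_forest": -0.060,
    "tropical_dry_forest": -0.045,
    "tropical_needleleaf_forest": -0.035,
    "temperate_evergreen_forest": -0.030,
    "montane_forest": -0.040,
    "savanna": -0.020,
    "grassland": -0.010,
    "barren": 0.000,
}

NEE_NOISE_SD = 0.02  # interannual NEE variability, kgC/m²/yr

REFERENCE_YEARS = np.arange(1985, 2015)
FUTURE_YEARS = np.arange(2071, 2101)


@dataclass
class SyntheticTruth:
    """Realized per-cell ground truth of one landscape draw."""

    true_stability: np.ndarray          # fraction in [0, 1]
    true_delta_co2: np.ndarray          # t CO2/ha/yr
    true_reference_biome: np.ndarray    # integer codes into `labels`
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (self.true_stability.shape == self.true_delta_co2.shape
                == self.true_reference_biome.shape):
            raise ValueError("truth field shapes disagree")


@dataclass
class Landscape:
    """Cell-year vegetation-model surrogate output for one scenario."""

    grid: GridSpec
    scenario: ScenarioSpec
    pft_lai: np.ndarray           # (n_years, rows, cols, n_pft), roster order
    seasonality: np.ndarray       # (n_years, rows, cols)
    nee: np.ndarray               # (n_years, rows, cols), kgC/m²/yr
    years: np.ndarray             # (n_years,) calendar years
    is_future: np.ndarray         # (n_years,) bool
    roster: tuple[str, ...]
    truth: SyntheticTruth


def reference_biome_map(grid: GridSpec,
                        scheme: BiomeScheme | None = None) -> np.ndarray:
    """Spatially coherent reference biome codes with the stated proportions."""
    scheme = scheme or BiomeScheme()
    rng = substream(grid.seed, "reference-biomes")
    u = _smooth_field(rng, grid.shape, sigma=max(min(grid.shape) / 10.0, 1.0))
    edges = np.cumsum([BIOME_PROPORTIONS[lab] for lab in scheme.labels])
    bins = np.searchsorted(edges, u, side="right")
    return np.minimum(bins, len(scheme.labels) - 1).astype(np.int64)


def _states_for(codes: np.ndarray, scheme: BiomeScheme,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw noisy archetype PFT states for an array of biome codes."""
    labels = scheme.labels
    base_lai = np.array([[ARCHETYPES[lab][0][p] for p in scheme.roster]
                         for lab in labels])
    base_seas = np.array([ARCHETYPES[lab][1] for lab in labels])
    lai = base_lai[codes] * rng.uniform(0.9, 1.1, size=codes.shape + (len(scheme.roster),))
    seas = base_seas[codes] + rng.uniform(-0.05, 0.05, size=codes.shape)
    return lai, seas


def generate_landscape(grid: GridSpec, scenario: ScenarioSpec,
                       scheme: BiomeScheme | None = None) -> Landscape:
    """Simulate cell-year PFT composition and NEE for one scenario.

    Reference-period biomes are constant per cell; each future year flips to
    a uniformly drawn different biome with probability
    ``scenario.flip_rate_map[cell]``. NEE is biome-dependent in the mean,
    shifted by the scenario trend in the future period, with additive
    Gaussian interannual noise. NEE is deliberately independent of the flip
    realization. Truth fields record the realized draw.
    """
    scheme = scheme or BiomeScheme()
    if scenario.flip_rate_map.shape != grid.shape:
        raise ValueError("scenario maps must match the grid shape")
    rng = substream(grid.seed, f"landscape:{scenario.name}")
    n_ref, n_fut = scenario.n_years_reference, scenario.n_years_future
    ref_codes = reference_biome_map(grid, scheme)
    n_labels = len(scheme.labels)

    # future biome codes: flip -> uniform over the other labels
    flips = rng.random((n_fut,) + grid.shape) < scenario.flip_rate_map
    offset = rng.integers(1, n_labels, size=(n_fut,) + grid.shape)
    fut_codes = np.where(flips, (ref_codes + offset) % n_labels, ref_codes)

    codes = np.concatenate([np.broadcast_to(ref_codes, (n_ref,) + grid.shape),
                            fut_codes], axis=0)
    lai, seas = _states_for(codes, scheme, rng)

    nee_base = np.array([BIOME_NEE[lab] for lab in scheme.labels])[ref_codes]
    nee_ref = nee_base + rng.normal(0.0, NEE_NOISE_SD, (n_ref,) + grid.shape)
    nee_fut = (nee_base + scenario.nee_trend_map
               + rng.normal(0.0, NEE_NOISE_SD, (n_fut,) + grid.shape))
    nee = np.concatenate([nee_ref, nee_fut], axis=0)

    truth = SyntheticTruth(
        # mean of non-flip indicators, not 1 - flips.mean(): bit-identical
        # to the downstream recount of year-by-year biome equality
        true_stability=(~flips).mean(axis=0),
        true_delta_co2=(carbon_to_co2_per_ha(nee_fut.mean(axis=0))
                        - carbon_to_co2_per_ha(nee_ref.mean(axis=0))),
        true_reference_biome=ref_codes,
        labels=scheme.labels,
    )
    years = np.concatenate([
        REFERENCE_YEARS[-n_ref:] if n_ref <= len(REFERENCE_YEARS)
        else np.arange(2015 - n_ref, 2015),
        FUTURE_YEARS[:n_fut] if n_fut <= len(FUTURE_YEARS)
        else np.arange(2071, 2071 + n_fut)])
    is_future = np.concatenate([np.zeros(n_ref, bool), np.ones(n_fut, bool)])
    return Landscape(grid=grid, scenario=scenario, pft_lai=lai,
                     seasonality=seas, nee=nee, years=years,
                     is_future=is_future, roster=scheme.roster, truth=truth)


# ---------------------------------------------------------------------------
# valuation records

VALUATION_BIOME_GROUPS: tuple[str, ...] = (
    "tropical rain forest", "tropical dry forest", "montane forests",
    "temperate forests", "grassland")

#: Habitat-supported services kept in the benefit transfer.
IN_SCOPE_SERVICES: tuple[str, ...] = (
    "recreation", "existence and bequest", "erosion prevention",
    "pollination", "water regulation", "genetic resources")

#: Excluded on principle: climate regulation is valued separately via the
#: social cost of carbon; provisioning services concern managed forests.
CLIMATE_SERVICE = "climate regulation"
PROVISIONING_SERVICES: tuple[str, ...] = (
    "food", "raw materials", "water", "medicinal resources")

RECORD_COLUMNS = ("service", "biome", "value_usd_per_ha_yr", "year")

LOGNORMAL_MU = np.log(180.0)   # body median 180 $/ha/yr
LOGNORMAL_SIGMA = 1.5          # right-skewed body


def generate_valuation_records(
    n: int = 246,
    biomes: tuple[str, ...] = VALUATION_BIOME_GROUPS,
    services: tuple[str, ...] = IN_SCOPE_SERVICES,
    outlier_fraction: float = 0.05,
    n_duplicates: int = 10,
    n_missing: int = 5,
    excluded_service_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw an ESVD-style benefit-transfer record table with known defects.

    The value body is log-normal (right-skewed); a Bernoulli
    ``outlier_fraction`` of in-scope rows is replaced by extreme values
    spanning at least six orders of magnitude (up to 2.25e10 $/ha/yr). Exact
    duplicate rows, rows with a missing value field, and rows carrying
    excluded services (climate regulation, provisioning) are injected on
    disjoint row sets; the returned truth dict holds the realized counts and
    row indices of each defect group.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= outlier_fraction <= 1:
        raise ValueError("outlier_fraction must lie in [0, 1]")
    rng = substream(seed, "valuation-records")
    excluded = (CLIMATE_SERVICE,) + PROVISIONING_SERVICES
    svc = rng.choice(np.array(services), size=n)
    excl_mask = rng.random(n) < excluded_service_fraction
    svc[excl_mask] = rng.choice(np.array(excluded), size=int(excl_mask.sum()))
    values = rng.lognormal(LOGNORMAL_MU, LOGNORMAL_SIGMA, n)
    in_scope = ~excl_mask
    out_mask = (rng.random(n) < outlier_fraction) & in_scope
    # extremes at both ends (near-zero up to 2.25e10 $/ha/yr), split evenly
    # between the tails so each stays within the 5% the trim removes
    n_out = int(out_mask.sum())
    low = rng.random(n_out) < 0.5
    exponents = np.where(low, rng.uniform(-4.0, -1.0, n_out),
                         rng.uniform(6.0, np.log10(2.25e10), n_out))
    values[out_mask] = 10 ** exponents
    df = pd.DataFrame({
        "service": svc,
        "biome": rng.choice(np.array(biomes), size=n),
        "value_usd_per_ha_yr": values,
        "year": rng.integers(1990, 2021, n),
    })
    dup_src = rng.choice(n, size=min(n_duplicates, n), replace=False)
    dups = df.iloc[dup_src].copy()
    miss = pd.DataFrame({
        "service": rng.choice(np.array(services), size=n_missing),
        "biome": rng.choice(np.array(biomes), size=n_missing),
        "value_usd_per_ha_yr": np.nan,
        "year": rng.integers(1990, 2021, n_missing),
    })
    full = pd.concat([df, dups, miss], ignore_index=True)
    truth = {
        "n_body": n,
        "n_duplicates": len(dups),
        "n_missing": n_missing,
        "n_climate": int((svc == CLIMATE_SERVICE).sum()),
        "n_provisioning": int(np.isin(svc, PROVISIONING_SERVICES).sum()),
        "n_outliers": int(out_mask.sum()),
        "duplicate_rows": list(range(n, n + len(dups))),
        "missing_rows": list(range(n + len(dups), len(full))),
        "outlier_rows": list(np.flatnonzero(out_mask)),
    }
    return full, truth


# ---------------------------------------------------------------------------
# social cost of carbon

DEFAULT_SCC_YEARS = tuple(range(2015, 2101, 5))
DEFAULT_SSPS = ("SSP1", "SSP2", "SSP3", "SSP4", "SSP5")
DEFAULT_RATES = (0.0, 0.01, 0.02, 0.03)

SCC_BASE = {"SSP1": 90.0, "SSP2": 110.0, "SSP3": 140.0, "SSP4": 125.0,
            "SSP5": 160.0}  # $/tCO2 at 2015, 0% rate
SCC_GROWTH = 0.015          # /yr — damages accumulate, SCC rises over time
SCC_RATE_SENSITIVITY = 90.0  # e-folding of SCC with the discount rate


def generate_scc_table(
    years=DEFAULT_SCC_YEARS,
    ssps=DEFAULT_SSPS,
    rates=DEFAULT_RATES,
    n_damage_functions: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Social-cost-of-carbon table at 5-year intervals.

    ``scc = base(ssp) * (1+g)^(year-2015) * exp(-lambda*rate) * m(df)`` with
    a fixed multiplier per damage function, so values rise strictly with the
    year within (ssp, rate) and fall strictly with the rate within
    (ssp, year) — the two qualitative properties the valuation relies on.
    """
    years = tuple(int(y) for y in years)
    rates = tuple(float(r) for r in rates)
    if 2015 not in years or 2085 not in years:
        raise ValueError("SCC table must include the years 2015 and 2085")
    if 0.0 not in rates or 0.02 not in rates:
        raise ValueError("SCC table must include discount rates 0 and 0.02")
    if n_damage_functions < 1:
        raise ValueError("need at least one damage function")
    rng = substream(seed, "scc-table")
    mult = np.sort(rng.lognormal(0.0, 0.25, n_damage_functions))
    rows = []
    for ssp in ssps:
        for year in years:
            for rate in rates:
                for d in range(n_damage_functions):
                    scc = (SCC_BASE[ssp] * (1 + SCC_GROWTH) ** (year - 2015)
                           * np.exp(-SCC_RATE_SENSITIVITY * rate) * mult[d])
                    rows.append((year, ssp, rate, f"DF{d + 1}", scc))
    return pd.DataFrame(rows, columns=["year", "ssp", "discount_rate",
                                       "damage_function", "scc_usd_per_tco2"])


# ---------------------------------------------------------------------------
# countries

#: 2020-era magnitudes: per-capita GDP in $ and population in millions.
COUNTRY_BASE = {
    "BZ": (4440.0, 0.40), "CO": (5330.0, 50.9), "CR": (12130.0, 5.1),
    "SV": (3800.0, 6.5), "GT": (4600.0, 16.9), "HN": (2410.0, 9.9),
    "MX": (8330.0, 128.9), "NI": (1910.0, 6.6), "PA": (12370.0, 4.3),
}
WORLD_GDPPC = 10900.0  # world-average per-capita GDP, 2020-era $


def generate_country_table(countries: tuple[str, ...] = DEFAULT_COUNTRIES,
                           seed: int = 0) -> pd.DataFrame:
    """Country table with per-capita GDP, total GDP and the world average.

    Known countries get 2020-era magnitudes jittered by ±5%; unknown labels
    draw a log-normal per-capita GDP around the world average.
    """
    if len(countries) < 1:
        raise ValueError("need at least one country")
    rng = substream(seed, "country-table")
    rows = []
    for c in countries:
        if c in COUNTRY_BASE:
            gdppc, pop_m = COUNTRY_BASE[c]
            gdppc *= rng.uniform(0.95, 1.05)
        else:
            gdppc = WORLD_GDPPC * rng.lognormal(0.0, 0.5)
            pop_m = rng.uniform(1.0, 50.0)
        rows.append((c, gdppc, gdppc * pop_m * 1e6))
    df = pd.DataFrame(rows, columns=["country", "gdp_per_capita", "gdp_total"])
    df["world_gdp_per_capita"] = WORLD_GDPPC
    return df
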