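"""Spatial and political aggregation of indicator and cost surfaces.

Covers the bivariate stability × ΔCO2 map classes, economic hot spots
(cells where both services decline), cost-class summaries, and per-country
cost totals with GDP fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STABILITY_BREAK = 50.0   # percent
DELTA_CO2_BREAK = 0.0    # t CO2/ha/yr

#: Bivariate map classes at the 50% / 0 breaks. Names describe the quadrant;
#: the conventional map colours are magenta, orange, blue, green in this
#: order. Boundary cells (stability exactly 50, delta exactly 0) count as
#: stable / non-declining.
BIVARIATE_LABELS: tuple[str, ...] = (
    "unstable_declining_co2",    # BS < 50, ΔCO2 < 0   (magenta)
    "unstable_increasing_co2",   # BS < 50, ΔCO2 >= 0  (orange)
    "stable_declining_co2",      # BS >= 50, ΔCO2 < 0  (blue)
    "stable_increasing_co2",     # BS >= 50, ΔCO2 >= 0 (green)
)

#: Hot-spot cost classes in $/ha/yr; the top class is open-ended (> 2500).
DEFAULT_COST_EDGES: tuple[float, ...] = (0.0, 500.0, 1000.0, 2500.0)

#: Biomes counted as forest for affected-area denominators.
FOREST_BIOMES: tuple[str, ...] = (
    "tropical_rain_forest", "tropical_dry_forest",
    "tropical_needleleaf_forest", "temperate_evergreen_forest",
    "montane_forest")


def bivariate_classify(stability, delta_co2) -> np.ndarray:
    """Four-way class codes (index into BIVARIATE_LABELS) per cell."""
    stability = np.asarray(stability, dtype=float)
    delta_co2 = np.asarray(delta_co2, dtype=float)
    if stability.shape != delta_co2.shape:
        raise ValueError("stability and delta_co2 shapes differ")
    stable = stability >= STABILITY_BREAK
    nondecl = delta_co2 >= DELTA_CO2_BREAK
    return (2 * stable + nondecl).astype(np.int64)


def bivariate_area_fractions(classes: np.ndarray) -> dict[str, float]:
    """Fraction of cells in each bivariate class (sums to 1)."""
    n = classes.size
    return {lab: float((classes == k).sum()) / n
            for k, lab in enumerate(BIVARIATE_LABELS)}


def hotspot_mask(habitat_cost_raw: np.ndarray,
                 climate_cost_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cells where both services show losses, and their summed cost.

    The mask is true where both *raw* (pre-floor) costs are strictly
    positive; the summed surface is habitat + climate cost on masked cells
    and 0 elsewhere.
    """
    h = np.asarray(habitat_cost_raw, dtype=float)
    c = np.asarray(climate_cost_raw, dtype=float)
    if h.shape != c.shape:
        raise ValueError("cost surfaces are not aligned")
    mask = (h > 0) & (c > 0)
    return mask, np.where(mask, h + c, 0.0)


def cost_class_summary(summed_cost: np.ndarray, mask: np.ndarray,
                       cell_area_ha: float,
                       edges: tuple[float, ...] = DEFAULT_COST_EDGES,
                       ) -> pd.DataFrame:
    """Area and average cost per hot-spot cost class.

    ``edges`` are the lower bounds of the closed-below classes; the last
    class is open above its edge. Empty classes report area 0 and an absent
    (NaN) mean.
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("class edges must be strictly increasing")
    vals = np.asarray(summed_cost, dtype=float)[np.asarray(mask, dtype=bool)]
    bounds = edges + (np.inf,)
    rows = []
    for lo, hi in zip(bounds, bounds[1:]):
        sel = vals[(vals >= lo) & (vals < hi)]
        label = f">{lo:g}" if np.isinf(hi) else f"{lo:g}-{hi:g}"
        rows.append((label, lo, hi, sel.size * cell_area_ha,
                     float(sel.mean()) if sel.size else np.nan))
    return pd.DataFrame(rows, columns=["cost_class", "lower", "upper",
                                       "area_ha", "average_cost"])


@dataclass
class RegionSummary:
    """Study-region totals for one scenario × valuation variant."""

    habitat_cost_total: float       # $/yr
    climate_cost_total: float       # $/yr
    hotspot_cost_total: float       # $/yr
    hotspot_area_fraction: float


def country_summary(habitat_cost_raw: np.ndarray,
                    climate_cost_raw: np.ndarray,
                    country_map: np.ndarray,
                    countries: tuple[str, ...],
                    country_table: pd.DataFrame,
                    cell_area_ha: float,
                    forest_mask: np.ndarray | None = None,
                    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
                    ) -> tuple[pd.DataFrame, RegionSummary]:
    """Per-country cost totals, GDP fractions and distribution summaries.

    Totals sum floored per-cell costs times the cell area ($/yr). The
    affected-area fraction relates cells with positive cost in either
    service to the country's forest cells (all cells when no forest mask is
    given). Distribution summaries describe per-cell summed costs over
    affected cells.
    """
    h = np.asarray(habitat_cost_raw, dtype=float)
    c = np.asarray(climate_cost_raw, dtype=float)
    if not (h.shape == c.shape == country_map.shape):
        raise ValueError("cost surfaces and country map are not aligned")
    if country_map.max() >= len(countries) or country_map.min() < 0:
        raise ValueError("country map refers to an unknown country")
    gdp = country_table.set_index("country")["gdp_total"]
    missing = set(countries) - set(gdp.index)
    if missing:
        raise ValueError(f"country table lacks GDP for {sorted(missing)}")
    if forest_mask is None:
        forest_mask = np.ones_like(country_map, dtype=bool)

    h_cost = np.maximum(h, 0.0)
    c_cost = np.maximum(c, 0.0)
    affected = (h > 0) | (c > 0)
    hs_mask, hs_cost = hotspot_mask(h, c)

    rows = []
    for k, name in enumerate(countries):
        in_c = country_map == k
        ht = float(h_cost[in_c].sum()) * cell_area_ha
        ct = float(c_cost[in_c].sum()) * cell_area_ha
        n_forest = int((in_c & forest_mask).sum())
        n_aff = int((in_c & affected & forest_mask).sum())
        cell_costs = (h_cost + c_cost)[in_c & affected]
        qs = (np.quantile(cell_costs, quantiles) if cell_costs.size
              else np.full(len(quantiles), np.nan))
        rows.append({
            "country": name,
            "habitat_cost_usd_yr": ht,
            "climate_cost_usd_yr": ct,
            "total_cost_usd_yr": ht + ct,
            "cost_pct_gdp": 100.0 * (ht + ct) / float(gdp[name]),
            "affected_area_fraction": (n_aff / n_forest) if n_forest else np.nan,
            **{f"cell_cost_q{int(q * 100)}": float(v)
               for q, v in zip(quantiles, qs)},
        })
    table = pd.DataFrame(rows)
    region = RegionSummary(
        habitat_cost_total=float(h_cost.sum()) * cell_area_ha,
        climate_cost_total=float(c_cost.sum()) * cell_area_ha,
        hotspot_cost_total=float(hs_cost.sum()) * cell_area_ha,
        hotspot_area_fraction=float(hs_mask.mean()),
    )
    return table, region
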