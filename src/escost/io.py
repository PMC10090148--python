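"""Readers/writers, run configuration and the end-to-end pipeline driver.

Gridded data travels as NetCDF3 (via the SciPy backend, so no extra
libraries are needed) or as long-format CSV; tables are CSV, configuration
is YAML, and each run writes a JSON manifest recording the seed, a hash of
the configuration and every output path, so any output is reproducible from
manifest + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .aggregate import (FOREST_BIOMES, RegionSummary, bivariate_area_fractions,
                        bivariate_classify, cost_class_summary, country_summary,
                        hotspot_mask)
from .biomes import BiomeScheme, reference_biome_codes
from .indicators import IndicatorSurface, compute_indicators
from .synthetic import (DEFAULT_SCENARIOS, GridSpec, Landscape, ScenarioSpec,
                        generate_country_table, generate_landscape,
                        generate_scc_table, generate_valuation_records)
from .valuation import (DEFAULT_VARIANTS, HabitatServiceValue, PriceScheme,
                        ValuationVariant, clean_records, climate_cost,
                        floor_costs, habitat_baseline, habitat_cost,
                        resolve_scc)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# gridded I/O

def write_landscape_netcdf(land: Landscape, path) -> None:
    """Write a landscape's cell-year cubes to a NetCDF3 file."""
    ds = xr.Dataset(
        {
            "lai": (("year", "row", "col", "pft"), land.pft_lai),
            "precip_seasonality": (("year", "row", "col"), land.seasonality),
            "nee": (("year", "row", "col"), land.nee),
            "is_future": (("year",), land.is_future.astype(np.int32)),
        },
        coords={"year": land.years.astype(np.int32)},
        attrs={"roster": ",".join(land.roster),
               "scenario": land.scenario.name,
               "cell_area_ha": land.grid.cell_area_ha},
    )
    ds.to_netcdf(path, engine="scipy")


def read_landscape_netcdf(path) -> dict:
    """Read a landscape NetCDF back into plain arrays.

    Raises on malformed files instead of returning partial data.
    """
    try:
        with xr.open_dataset(path, engine="scipy") as ds:
            required = {"lai", "precip_seasonality", "nee", "is_future"}
            missing = required - set(ds.variables)
            if missing:
                raise ValueError(f"landscape file lacks variables {sorted(missing)}")
            out = {
                "lai": ds["lai"].to_numpy(),
                "seasonality": ds["precip_seasonality"].to_numpy(),
                "nee": ds["nee"].to_numpy(),
                "years": ds["year"].to_numpy(),
                "is_future": ds["is_future"].to_numpy().astype(bool),
                "roster": tuple(ds.attrs["roster"].split(",")),
            }
    except (OSError, ValueError, KeyError) as exc:
        raise ValueError(f"cannot read landscape file {path}: {exc}") from exc
    return out


def landscape_to_frame(land: Landscape) -> pd.DataFrame:
    """Long-format cell-year table (one row per cell-year, wide PFT columns)."""
    ny, nr, nc, npft = land.pft_lai.shape
    year, row, col = np.meshgrid(land.years, np.arange(nr), np.arange(nc),
                                 indexing="ij")
    df = pd.DataFrame({"year": year.ravel(), "row": row.ravel(),
                       "col": col.ravel()})
    for i, pft in enumerate(land.roster):
        df[f"lai_{pft}"] = land.pft_lai[..., i].ravel()
    df["precip_seasonality"] = land.seasonality.ravel()
    df["nee"] = land.nee.ravel()
    df["is_future"] = np.repeat(land.is_future, nr * nc)
    return df


def frame_to_arrays(df: pd.DataFrame) -> dict:
    """Rebuild cell-year cubes from the long-format CSV layout."""
    required = {"year", "row", "col", "precip_seasonality", "nee", "is_future"}
    if not required <= set(df.columns):
        raise ValueError(f"landscape table lacks columns {sorted(required - set(df.columns))}")
    roster = tuple(c[4:] for c in df.columns if c.startswith("lai_"))
    if not roster:
        raise ValueError("landscape table has no lai_* columns")
    years = np.unique(df["year"].to_numpy())
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1
    if len(df) != len(years) * nr * nc:
        raise ValueError("landscape table is truncated or has duplicate cells")
    d = df.sort_values(["year", "row", "col"])
    shape = (len(years), nr, nc)
    lai = np.stack([d[f"lai_{p}"].to_numpy().reshape(shape) for p in roster],
                   axis=-1)
    is_future = d.groupby("year")["is_future"].first().to_numpy().astype(bool)
    return {"lai": lai,
            "seasonality": d["precip_seasonality"].to_numpy().reshape(shape),
            "nee": d["nee"].to_numpy().reshape(shape),
            "years": years, "is_future": is_future, "roster": roster}


def write_biome_codes(codes: np.ndarray, labels: tuple[str, ...], path) -> None:
    """Integer biome raster with its label legend, as NetCDF3."""
    ds = xr.Dataset({"biome": (("row", "col"), codes.astype(np.int32))},
                    attrs={"labels": ",".join(labels)})
    ds.to_netcdf(path, engine="scipy")


def read_biome_codes(path) -> tuple[np.ndarray, tuple[str, ...]]:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds["biome"].to_numpy().astype(np.int64), tuple(
            ds.attrs["labels"].split(","))


def indicators_from_arrays(data: dict, scheme: BiomeScheme) -> IndicatorSurface:
    """Classify a landscape's arrays and compute the indicator surface."""
    codes = scheme.classify_arrays(data["lai"], data["seasonality"])
    fut = data["is_future"]
    ref_codes = reference_biome_codes(codes[~fut])
    return compute_indicators(ref_codes, codes[fut],
                              data["nee"][~fut], data["nee"][fut])


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """End-to-end run configuration (the YAML schema mirrors the fields)."""

    n_rows: int = 100
    n_cols: int = 100
    cell_area_ha: float = 100.0
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    variants: tuple[ValuationVariant, ...] = DEFAULT_VARIANTS
    n_records: int = 246
    outlier_fraction: float = 0.05
    inflation_factor: float = 1.0
    scheme_path: str | None = None
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "variants" in doc:
            doc["variants"] = tuple(
                ValuationVariant(v["price_mode"], float(v["discount_rate"]))
                for v in doc["variants"])
        if "scenarios" in doc:
            doc["scenarios"] = tuple(doc["scenarios"])
        return cls(**doc)

    def canonical(self) -> dict:
        d = asdict(self)
        d["variants"] = [{"price_mode": v.price_mode,
                          "discount_rate": v.discount_rate}
                         for v in self.variants]
        d["scenarios"] = list(self.scenarios)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline driver

@dataclass
class VariantResult:
    """Cost surfaces and aggregates for one scenario × valuation variant."""

    scenario: str
    variant: ValuationVariant
    habitat_cost_raw: np.ndarray
    climate_cost_raw: np.ndarray
    hotspot_mask: np.ndarray
    hotspot_cost: np.ndarray
    cost_classes: pd.DataFrame
    country_table: pd.DataFrame
    region: RegionSummary


@dataclass
class RunResult:
    manifest: dict
    hsv_2015: float
    cleaning_report: dict
    indicators: dict[str, IndicatorSurface]
    truths: dict[str, object]
    bivariate_fractions: dict[str, dict[str, float]]
    variant_results: dict[tuple[str, str], VariantResult]
    grid: GridSpec
    country_data: pd.DataFrame


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute synth → biomes → indicators → valuation → aggregate.

    Deterministic given ``config.seed``: all randomness flows from that one
    root seed through named substreams, so the landscape realization is
    shared across valuation variants.
    """
    with _stage("config"):
        if config.scheme_path is not None:
            if not Path(config.scheme_path).exists():
                raise FileNotFoundError(f"biome scheme file not found: "
                                        f"{config.scheme_path}")
            scheme = BiomeScheme.from_yaml(config.scheme_path)
        else:
            scheme = BiomeScheme()
        grid = GridSpec(n_rows=config.n_rows, n_cols=config.n_cols,
                        cell_area_ha=config.cell_area_ha, seed=config.seed)

    with _stage("economic-tables"):
        raw_records, _ = generate_valuation_records(
            n=config.n_records, outlier_fraction=config.outlier_fraction,
            seed=config.seed)
        clean, report = clean_records(raw_records)
        hsv_2015 = habitat_baseline(clean, config.inflation_factor)
        scc = generate_scc_table(seed=config.seed)
        country_data = generate_country_table(tuple(grid.countries),
                                              seed=config.seed)

    indicators: dict[str, IndicatorSurface] = {}
    truths: dict[str, object] = {}
    bivar: dict[str, dict[str, float]] = {}
    variant_results: dict[tuple[str, str], VariantResult] = {}
    forest_codes = [i for i, lab in enumerate(scheme.labels)
                    if lab in FOREST_BIOMES]

    for scen_name in config.scenarios:
        with _stage(f"landscape:{scen_name}"):
            scen = ScenarioSpec.preset(scen_name, grid)
            land = generate_landscape(grid, scen, scheme)
        with _stage(f"indicators:{scen_name}"):
            surf = indicators_from_arrays(
                {"lai": land.pft_lai, "seasonality": land.seasonality,
                 "nee": land.nee, "is_future": land.is_future}, scheme)
            indicators[scen_name] = surf
            truths[scen_name] = land.truth
            classes = bivariate_classify(surf.stability, surf.delta_co2)
            bivar[scen_name] = bivariate_area_fractions(classes)
        forest_mask = np.isin(surf.reference_biome, forest_codes)
        for variant in config.variants:
            with _stage(f"valuation:{scen_name}:{variant.name}"):
                hsv = HabitatServiceValue.resolve(hsv_2015,
                                                  variant.discount_rate)
                price = resolve_scc(scc, scen.ssp, variant.discounted)
                scheme_p = PriceScheme.resolve(variant.price_mode, country_data)
                fmap = scheme_p.factor_map(grid.country_map,
                                           tuple(grid.countries))
                h_raw = habitat_cost(surf.stability, hsv, fmap)
                c_raw = climate_cost(surf.co2_seq_reference,
                                     surf.co2_seq_future, price, fmap)
            with _stage(f"aggregate:{scen_name}:{variant.name}"):
                mask, summed = hotspot_mask(h_raw, c_raw)
                classes_df = cost_class_summary(summed, mask,
                                                grid.cell_area_ha)
                ctab, region = country_summary(
                    h_raw, c_raw, grid.country_map, tuple(grid.countries),
                    country_data, grid.cell_area_ha, forest_mask=forest_mask)
                variant_results[(scen_name, variant.name)] = VariantResult(
                    scenario=scen_name, variant=variant,
                    habitat_cost_raw=h_raw, climate_cost_raw=c_raw,
                    hotspot_mask=mask, hotspot_cost=summed,
                    cost_classes=classes_df, country_table=ctab,
                    region=region)

    manifest = {
        "package": "escost",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.canonical(),
        "scenarios": list(config.scenarios),
        "variants": [v.name for v in config.variants],
        "outputs": [],
    }
    result = RunResult(manifest=manifest, hsv_2015=hsv_2015,
                       cleaning_report=report, indicators=indicators,
                       truths=truths, bivariate_fractions=bivar,
                       variant_results=variant_results, grid=grid,
                       country_data=country_data)
    if config.output_dir is not None:
        with _stage("write-outputs"):
            _write_outputs(result, config)
    return result


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[str] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        paths.append(str(p))

    for scen, surf in result.indicators.items():
        df = pd.DataFrame({
            "row": np.repeat(np.arange(surf.stability.shape[0]),
                             surf.stability.shape[1]),
            "col": np.tile(np.arange(surf.stability.shape[1]),
                           surf.stability.shape[0]),
            "country": np.array(result.grid.countries)[
                result.grid.country_map].ravel(),
            "stability_pct": surf.stability.ravel(),
            "co2_seq_reference": surf.co2_seq_reference.ravel(),
            "co2_seq_future": surf.co2_seq_future.ravel(),
            "delta_co2": surf.delta_co2.ravel(),
        })
        save_csv(df, f"indicators_{scen}.csv")
    for (scen, vname), vr in result.variant_results.items():
        save_csv(vr.country_table, f"costs_by_country_{scen}_{vname}.csv")
        save_csv(vr.cost_classes, f"cost_classes_{scen}_{vname}.csv")
    region = {
        f"{scen}:{vname}": {
            "habitat_cost_total_usd_yr": vr.region.habitat_cost_total,
            "climate_cost_total_usd_yr": vr.region.climate_cost_total,
            "hotspot_cost_total_usd_yr": vr.region.hotspot_cost_total,
            "hotspot_area_fraction": vr.region.hotspot_area_fraction,
        }
        for (scen, vname), vr in result.variant_results.items()
    }
    region["bivariate_area_fractions"] = result.bivariate_fractions
    p = out / "region_summary.json"
    p.write_text(json.dumps(region, indent=2, sort_keys=True))
    paths.append(str(p))

    result.manifest["outputs"] = sorted(paths)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
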