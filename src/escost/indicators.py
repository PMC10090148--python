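"""Ecosystem-service indicators: CO2 sequestration and biome stability.

Two indicators are computed per cell and 30-year period:

* CO2 sequestration — period-mean net ecosystem exchange (NEE, kgC/m²/yr,
  atmospheric sign convention: negative = net uptake) converted to
  t CO2/ha/yr with uptake positive.
* Biome stability — the percentage of future-period years whose classified
  biome equals the cell's reference-period modal biome:
  ``stability = 100 * (# matching years) / n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Carbon -> CO2 mass ratio. Fixed at the conventional rounded value used in
#: practice-oriented reporting (not the exact 44.01/12.011 = 3.664).
CO2_PER_C: float = 3.67

#: kgC/m² -> tC/ha (1 kg/m² = 10 t/ha).
KG_M2_TO_T_HA: float = 10.0


def carbon_to_co2_per_ha(nee):
    """Convert NEE in kgC/m²/yr to CO2 sequestration in t CO2/ha/yr.

    The sign is flipped so that net uptake (negative NEE under the
    atmospheric convention) becomes a positive sequestration. Accepts
    scalars or arrays.
    """
    nee = np.asarray(nee, dtype=float)
    if not np.all(np.isfinite(nee)):
        raise ValueError("NEE must be finite")
    out = -nee * KG_M2_TO_T_HA * CO2_PER_C
    return float(out) if out.ndim == 0 else out


def period_mean_co2(series, period: str | None = None):
    """Arithmetic mean of an annual CO2-sequestration series (t CO2/ha/yr).

    ``series`` has years on axis 0; trailing axes (cells) are preserved.
    ``period`` is a label carried through for reporting only.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError(f"empty series for period {period!r}")
    return series.mean(axis=0)


def biome_stability(reference, future):
    """Percent of future years whose biome equals the reference biome.

    Parameters
    ----------
    reference
        Scalar label/code, or an array of per-cell reference biomes.
    future
        Sequence of future-year labels (1-D), or an array with years on
        axis 0 and cells on the trailing axes.
    """
    future = np.asarray(future)
    if future.size == 0:
        raise ValueError("future series is empty")
    ref = np.asarray(reference)
    match = future == ref  # broadcasts reference over the year axis
    out = 100.0 * match.mean(axis=0)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class IndicatorSurface:
    """Per-cell indicator fields for one scenario.

    Attributes
    ----------
    stability
        Biome stability in percent, in [0, 100].
    co2_seq_reference, co2_seq_future
        Period-mean CO2 sequestration, t CO2/ha/yr (uptake positive).
    delta_co2
        ``co2_seq_future - co2_seq_reference``, t CO2/ha/yr.
    reference_biome
        Integer biome codes of the reference-period modal biome.
    """

    stability: np.ndarray
    co2_seq_reference: np.ndarray
    co2_seq_future: np.ndarray
    delta_co2: np.ndarray
    reference_biome: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.stability, dtype=float)
        if np.any(s < 0) or np.any(s > 100):
            raise ValueError("stability must lie in [0, 100]")
        if not np.allclose(self.delta_co2,
                           self.co2_seq_future - self.co2_seq_reference):
            raise ValueError("delta_co2 must equal co2_seq_future - co2_seq_reference")


def compute_indicators(reference_codes: np.ndarray,
                       future_codes: np.ndarray,
                       nee_reference: np.ndarray,
                       nee_future: np.ndarray) -> IndicatorSurface:
    """Assemble the indicator surface from classified biomes and NEE cubes.

    ``future_codes``, ``nee_reference`` and ``nee_future`` carry years on
    axis 0; ``reference_codes`` is the per-cell modal reference biome.
    """
    stability = biome_stability(reference_codes, future_codes)
    co2_ref = period_mean_co2(carbon_to_co2_per_ha(nee_reference), "reference")
    co2_fut = period_mean_co2(carbon_to_co2_per_ha(nee_future), "future")
    return IndicatorSurface(
        stability=np.asarray(stability, dtype=float),
        co2_seq_reference=co2_ref,
        co2_seq_future=co2_fut,
        delta_co2=co2_fut - co2_ref,
        reference_biome=np.asarray(reference_codes),
    )
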