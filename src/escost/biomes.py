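"""Rule-based biome classification of simulated vegetation composition.

Dynamic-vegetation-model output arrives as per-cell abundances (leaf area
index) of plant functional types (PFTs). Each cell-year is mapped to one of
eight biomes by an ordered rule table evaluated top to bottom; the first
matching rule wins and a catch-all default guarantees totality.

The scheme follows the common LAI-dominance convention: a cell is forest
when its summed woody LAI reaches a threshold (default 2.5), savanna above a
lower woody threshold (default 0.5), grassland when grasses outweigh woody
vegetation, barren otherwise. Forests split by the identity of the dominant
woody PFT, with one special case: tropical needleleaf forest (pine-oak
formations) is not simulated as its own PFT, so it is diagnosed from
temperate-broadleaf-evergreen dominance combined with strongly seasonal
precipitation (coefficient of variation of monthly precipitation above a
threshold, default 0.8).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

WOODY_PFTS: tuple[str, ...] = ("TrBE", "TrBR", "TeBE", "TeNE")
GRASS_PFTS: tuple[str, ...] = ("C4G", "C3G")
DEFAULT_ROSTER: tuple[str, ...] = WOODY_PFTS + GRASS_PFTS


@dataclass(frozen=True)
class PFTState:
    """Per-cell, per-year vegetation state.

    Parameters
    ----------
    abundances
        Mapping PFT name -> LAI (dimensionless, >= 0).
    precip_seasonality
        Coefficient of variation of monthly precipitation (>= 0).
    """

    abundances: Mapping[str, float]
    precip_seasonality: float

    def __post_init__(self) -> None:
        for pft, v in self.abundances.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"abundance of {pft!r} must be finite and >= 0, got {v}")
        if not np.isfinite(self.precip_seasonality) or self.precip_seasonality < 0:
            raise ValueError("precip_seasonality must be finite and >= 0")


@dataclass(frozen=True)
class Rule:
    """One row of the biomization table.

    All stated conditions must hold for the rule to fire; ``None`` means
    "no constraint". ``dominant_woody`` requires the named PFT to carry the
    maximum LAI among woody PFTs (ties resolved by roster order).
    """

    biome: str
    woody_min: float | None = None
    woody_max: float | None = None
    dominant_woody: str | None = None
    grass_exceeds_woody: bool = False
    seasonality_min: float | None = None
    seasonality_max: float | None = None


#: Default eight-biome scheme. Rule order matters: the tropical-needleleaf
#: rule must precede the plain temperate-evergreen rule, which it refines.
DEFAULT_RULES: tuple[Rule, ...] = (
    Rule("tropical_needleleaf_forest", woody_min=2.5, dominant_woody="TeBE",
         seasonality_min=0.8),
    Rule("tropical_rain_forest", woody_min=2.5, dominant_woody="TrBE"),
    Rule("tropical_dry_forest", woody_min=2.5, dominant_woody="TrBR"),
    Rule("temperate_evergreen_forest", woody_min=2.5, dominant_woody="TeBE"),
    Rule("montane_forest", woody_min=2.5, dominant_woody="TeNE"),
    Rule("savanna", woody_min=0.5),
    Rule("grassland", grass_exceeds_woody=True),
)

DEFAULT_LABEL = "barren"


class BiomeScheme:
    """Ordered biomization rule table with a catch-all default label."""

    def __init__(
        self,
        rules: Sequence[Rule] = DEFAULT_RULES,
        default_label: str = DEFAULT_LABEL,
        roster: Sequence[str] = DEFAULT_ROSTER,
        woody_pfts: Sequence[str] = WOODY_PFTS,
        grass_pfts: Sequence[str] = GRASS_PFTS,
    ) -> None:
        if not rules:
            raise ValueError("scheme must contain at least one rule")
        self.rules = tuple(rules)
        self.default_label = default_label
        self.roster = tuple(roster)
        self.woody_pfts = tuple(p for p in woody_pfts if p in self.roster)
        self.grass_pfts = tuple(p for p in grass_pfts if p in self.roster)
        for r in self.rules:
            if r.dominant_woody is not None and r.dominant_woody not in self.woody_pfts:
                raise ValueError(f"rule references unknown woody PFT {r.dominant_woody!r}")
        # labels in precedence (rule) order, default last
        seen: list[str] = []
        for r in self.rules:
            if r.biome not in seen:
                seen.append(r.biome)
        if default_label not in seen:
            seen.append(default_label)
        self.labels: tuple[str, ...] = tuple(seen)
        self._code = {lab: i for i, lab in enumerate(self.labels)}

    # -- scalar path ------------------------------------------------------

    def _aggregates(self, state: PFTState) -> tuple[float, float, str]:
        for pft in state.abundances:
            if pft not in self.roster:
                raise ValueError(f"unknown PFT {pft!r}; roster is {self.roster}")
        woody = sum(state.abundances.get(p, 0.0) for p in self.woody_pfts)
        grass = sum(state.abundances.get(p, 0.0) for p in self.grass_pfts)
        dom = max(self.woody_pfts, key=lambda p: state.abundances.get(p, 0.0))
        return woody, grass, dom

    def _matches(self, rule: Rule, woody: float, grass: float, dom: str,
                 seasonality: float) -> bool:
        if rule.woody_min is not None and not woody >= rule.woody_min:
            return False
        if rule.woody_max is not None and not woody < rule.woody_max:
            return False
        if rule.dominant_woody is not None and dom != rule.dominant_woody:
            return False
        if rule.grass_exceeds_woody and not grass > woody:
            return False
        if rule.seasonality_min is not None and not seasonality > rule.seasonality_min:
            return False
        if rule.seasonality_max is not None and not seasonality <= rule.seasonality_max:
            return False
        return True

    def classify(self, state: PFTState) -> str:
        """Classify one vegetation state; always returns a label."""
        woody, grass, dom = self._aggregates(state)
        for rule in self.rules:
            if self._matches(rule, woody, grass, dom, state.precip_seasonality):
                return rule.biome
        return self.default_label

    # -- vectorised path --------------------------------------------------

    def classify_arrays(self, lai: np.ndarray, seasonality: np.ndarray) -> np.ndarray:
        """Classify a stack of states.

        Parameters
        ----------
        lai
            Array of shape ``(..., n_pft)`` ordered as ``self.roster``.
        seasonality
            Array of shape ``(...)`` matching the leading dims of ``lai``.

        Returns
        -------
        Integer label codes (index into ``self.labels``), shape ``(...)``.
        """
        lai = np.asarray(lai, dtype=float)
        seasonality = np.asarray(seasonality, dtype=float)
        if lai.shape[-1] != len(self.roster):
            raise ValueError(
                f"last axis of lai must have length {len(self.roster)} (roster order)")
        if np.any(lai < 0):
            raise ValueError("LAI values must be >= 0")
        widx = [self.roster.index(p) for p in self.woody_pfts]
        gidx = [self.roster.index(p) for p in self.grass_pfts]
        woody = lai[..., widx].sum(axis=-1)
        grass = lai[..., gidx].sum(axis=-1)
        # argmax over woody PFTs; ties resolve to the first (roster order),
        # matching the scalar path's max()
        dom = np.argmax(lai[..., widx], axis=-1)
        dom_names = np.array(self.woody_pfts)[dom]

        out = np.full(woody.shape, self._code[self.default_label], dtype=np.int64)
        unassigned = np.ones(woody.shape, dtype=bool)
        for rule in self.rules:
            m = unassigned.copy()
            if rule.woody_min is not None:
                m &= woody >= rule.woody_min
            if rule.woody_max is not None:
                m &= woody < rule.woody_max
            if rule.dominant_woody is not None:
                m &= dom_names == rule.dominant_woody
            if rule.grass_exceeds_woody:
                m &= grass > woody
            if rule.seasonality_min is not None:
                m &= seasonality > rule.seasonality_min
            if rule.seasonality_max is not None:
                m &= seasonality <= rule.seasonality_max
            out[m] = self._code[rule.biome]
            unassigned &= ~m
        return out

    # -- (de)serialisation ------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "roster": list(self.roster),
            "woody_pfts": list(self.woody_pfts),
            "grass_pfts": list(self.grass_pfts),
            "default_label": self.default_label,
            "rules": [{k: v for k, v in asdict(r).items() if v not in (None, False)}
                      for r in self.rules],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BiomeScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rules = [Rule(**r) for r in doc["rules"]]
        return cls(rules=rules, default_label=doc["default_label"],
                   roster=doc["roster"], woody_pfts=doc["woody_pfts"],
                   grass_pfts=doc["grass_pfts"])


def classify_biome(state: PFTState, scheme: BiomeScheme | None = None) -> str:
    """Map one PFT state to a biome label under ``scheme`` (default scheme if None)."""
    return (scheme or BiomeScheme()).classify(state)


def reference_biome(series: Sequence[str] | np.ndarray,
                    scheme: BiomeScheme | None = None) -> str:
    """Modal biome of a reference-period label series.

    Biomes are categorical, so the period's representative biome is the most
    frequent label; ties break toward the label whose rule appears earlier
    in the scheme (a deterministic, order-free convention).
    """
    labels = list(series)
    if not labels:
        raise ValueError("reference series is empty")
    scheme = scheme or BiomeScheme()
    counts = Counter(labels)
    best = max(counts.values())
    order = {lab: i for i, lab in enumerate(scheme.labels)}
    tied = [lab for lab, c in counts.items() if c == best]
    return min(tied, key=lambda lab: order.get(lab, len(order)))


def reference_biome_codes(codes: np.ndarray) -> np.ndarray:
    """Vectorised modal biome over axis 0 of an integer label-code cube.

    Ties break toward the smaller code, which is the earlier rule in the
    scheme — the same convention as :func:`reference_biome`.
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("reference series is empty")
    n_labels = int(codes.max()) + 1
    counts = np.stack([(codes == k).sum(axis=0) for k in range(n_labels)])
    return np.argmax(counts, axis=0)  # argmax ties -> smallest code
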