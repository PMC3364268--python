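"""Species energy densities and per-sample standing-stock metrics.

Energy density per gram dry weight comes from bomb calorimetry of pooled
tissue pellets; a species' value is the grand mean over all its pellet
replicates. The drop sampler encloses 1 m² of flooded marsh, so per-sample
counts are densities (ind m⁻²) directly, pooled wet weights convert to dry
biomass (g DW m⁻²) through the allometric models, and the per-area energy
standing stock (cal m⁻²) is the biomass-weighted sum of species energy
densities.

Standing stock is restricted to the dominant resident species (the default
set is the six small fishes and the grass shrimp community that make up the
bulk of marsh-surface abundance), applied consistently to all three metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np

__all__ = [
    "DOMINANT_SPECIES",
    "PelletRecord",
    "SpeciesEnergyDensity",
    "CatchRecord",
    "SampleMetrics",
    "mean_energy_density",
    "sample_metrics",
]

#: Dominant resident nekton included in standing-stock metrics by default.
DOMINANT_SPECIES: tuple[str, ...] = (
    "Palaemonetes paludosus",
    "Heterandria formosa",
    "Gambusia affinis",
    "Lucania parva",
    "Poecilia latipinna",
    "Cyprinodon variegatus",
)


@dataclass(frozen=True)
class PelletRecord:
    """One bomb-calorimeter replicate: a 1 g DW pooled-tissue pellet."""

    species: str
    replicate: str
    energy: float  # cal g^-1 DW

    def __post_init__(self) -> None:
        if not (np.isfinite(self.energy) and self.energy > 0):
            raise ValueError("pellet energy must be positive and finite")


@dataclass(frozen=True)
class SpeciesEnergyDensity:
    species: str
    mean_energy: float  # cal g^-1 DW
    se: Optional[float]
    n_pellets: int


@dataclass(frozen=True)
class CatchRecord:
    """Per-species pooled catch from one 1 m² drop sample."""

    sample_id: str
    species: str
    count: int
    wet_weight_g: float

    def __post_init__(self) -> None:
        if self.count < 0 or self.wet_weight_g < 0:
            raise ValueError("count and wet weight must be non-negative")


@dataclass(frozen=True)
class SampleMetrics:
    """Standing stock in one sample: density, dry biomass, energy per m²."""

    sample_id: str
    density: float                      # ind m^-2
    biomass_dw: float                   # g DW m^-2
    energy_density: float               # cal m^-2
    by_species_density: Dict[str, float] = field(default_factory=dict)
    by_species_biomass: Dict[str, float] = field(default_factory=dict)
    by_species_energy: Dict[str, float] = field(default_factory=dict)


def mean_energy_density(pellets: Sequence[PelletRecord]) -> SpeciesEnergyDensity:
    """Arithmetic mean (and SE) of pellet replicates for one species.

    SE is ``None`` when only one pellet was analyzed.
    """
    if len(pellets) == 0:
        raise ValueError("no pellet records")
    species = {p.species for p in pellets}
    if len(species) != 1:
        raise ValueError(f"pellets mix species: {sorted(species)}")
    vals = np.array([p.energy for p in pellets])
    se = (float(vals.std(ddof=1) / np.sqrt(len(vals)))
          if len(vals) > 1 else None)
    return SpeciesEnergyDensity(next(iter(species)), float(vals.mean()),
                                se, len(vals))


def sample_metrics(
    catch: Sequence[CatchRecord],
    models: Mapping[str, "AllometricModel"],
    energies: Mapping[str, SpeciesEnergyDensity],
    included_species: Optional[Set[str]] = None,
) -> SampleMetrics:
    """Standing-stock metrics for one sample from its catch records.

    Only species in ``included_species`` (default: the dominant residents)
    contribute — to density, biomass and energy alike, so the three metrics
    describe the same assemblage. Every included species present in the
    catch must have both an allometric model and an energy density.
    """
    from .allometry import predict_dry_weight  # deferred: avoids cycle at import

    included = set(DOMINANT_SPECIES) if included_species is None \
        else set(included_species)
    sample_ids = {c.sample_id for c in catch}
    if len(sample_ids) > 1:
        raise ValueError(f"catch mixes samples: {sorted(sample_ids)}")
    sid = next(iter(sample_ids)) if sample_ids else ""

    dens: Dict[str, float] = {}
    biom: Dict[str, float] = {}
    ener: Dict[str, float] = {}
    for rec in catch:
        if rec.species not in included:
            continue
        if rec.species not in models:
            raise KeyError(f"no allometric model for {rec.species!r}")
        if rec.species not in energies:
            raise KeyError(f"no energy density for {rec.species!r}")
        dw = predict_dry_weight(models[rec.species], rec.wet_weight_g,
                                rec.count)
        dens[rec.species] = dens.get(rec.species, 0.0) + rec.count
        biom[rec.species] = biom.get(rec.species, 0.0) + dw
    for sp, dw in biom.items():
        ener[sp] = dw * energies[sp].mean_energy

    return SampleMetrics(
        sample_id=sid,
        density=float(sum(dens.values())),
        biomass_dw=float(sum(biom.values())),
        energy_density=float(sum(ener.values())),
        by_species_density=dens,
        by_species_biomass=biom,
        by_species_energy=ener,
    )
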