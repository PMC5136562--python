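"""Intra- and inter-specific divergence parameters.

Six summary statistics characterize a marker's divergence structure:

* ``avg_intra``     — mean over all defined conspecific pairwise distances (pooled);
* ``theta``         — per-species mean conspecific distance, averaged over
                      species with >= 2 individuals;
* ``coalescent_depth`` — per-species *maximum* conspecific distance, averaged
                      over species with >= 2 individuals;
* ``avg_inter``     — mean over all defined heterospecific pairwise distances (pooled);
* ``theta_prime``   — per-species mean distance to all heterospecific
                      individuals, averaged over species;
* ``smallest_inter`` — per-species minimum distance to any heterospecific
                      individual, averaged over species.

Singleton species contribute to the inter-specific quantities but not the
intra-specific ones. Undefined (NaN) pairs are excluded from numerator and
denominator alike. Raw values are substitutions/site; the combined
:class:`DivergenceSummary` reports percentages, the convention of published
marker-comparison tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .errors import UndefinedSummaryError


@dataclass(frozen=True)
class SpeciesIntra:
    mean: float
    max: float
    n_pairs: int


@dataclass(frozen=True)
class SpeciesInter:
    mean_to_others: float
    min_to_others: float
    n_pairs: int


@dataclass(frozen=True)
class IntraspecificStats:
    """Pooled and per-species conspecific distance summaries (subs/site)."""

    avg_intra: float
    theta: float
    coalescent_depth: float
    per_species: dict[str, SpeciesIntra]


@dataclass(frozen=True)
class InterspecificStats:
    """Pooled and per-species heterospecific distance summaries (subs/site)."""

    avg_inter: float
    theta_prime: float
    smallest_inter: float
    per_species: dict[str, SpeciesInter]


@dataclass(frozen=True)
class DivergenceSummary:
    """The six divergence parameters, expressed in percent."""

    avg_intra: float
    theta: float
    coalescent_depth: float
    avg_inter: float
    theta_prime: float
    smallest_inter: float
    n_species_multi: int
    n_species_total: int


def _pair_values(values: np.ndarray, idx: list[int]) -> list[float]:
    out = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            v = values[idx[a], idx[b]]
            if not math.isnan(v):
                out.append(float(v))
    return out


def intraspecific_stats(dm: DistanceMatrix) -> IntraspecificStats:
    """Pooled mean, theta and coalescent depth over multi-individual species."""
    by_sp = dm.species_indices()
    per_species: dict[str, SpeciesIntra] = {}
    pooled: list[float] = []
    for sp, idx in by_sp.items():
        if len(idx) < 2:
            continue
        vals = _pair_values(dm.values, idx)
        if not vals:
            continue  # all conspecific pairs undefined
        per_species[sp] = SpeciesIntra(float(np.mean(vals)), float(np.max(vals)), len(vals))
        pooled.extend(vals)
    if not per_species:
        raise UndefinedSummaryError(
            "no species with >= 2 individuals and a defined conspecific pair"
        )
    return IntraspecificStats(
        avg_intra=float(np.mean(pooled)),
        theta=float(np.mean([s.mean for s in per_species.values()])),
        coalescent_depth=float(np.mean([s.max for s in per_species.values()])),
        per_species=per_species,
    )


def interspecific_stats(dm: DistanceMatrix) -> InterspecificStats:
    """Pooled mean, theta-prime and smallest interspecific distance."""
    by_sp = dm.species_indices()
    if len(by_sp) < 2:
        raise UndefinedSummaryError("interspecific statistics need >= 2 species")
    species = list(by_sp)
    per_species: dict[str, SpeciesInter] = {}
    pooled: list[float] = []
    for sp in species:
        own = by_sp[sp]
        other = [i for s2 in species if s2 != sp for i in by_sp[s2]]
        vals = [
            float(dm.values[i, j])
            for i in own
            for j in other
            if not math.isnan(dm.values[i, j])
        ]
        if vals:
            per_species[sp] = SpeciesInter(float(np.mean(vals)), float(np.min(vals)), len(vals))
    if not per_species:
        raise UndefinedSummaryError("no defined heterospecific pair")
    # pooled mean runs over unordered heterospecific pairs, each counted once
    for a_i, sp in enumerate(species):
        own = by_sp[sp]
        for sp2 in species[a_i + 1 :]:
            for i in own:
                for j in by_sp[sp2]:
                    v = dm.values[i, j]
                    if not math.isnan(v):
                        pooled.append(float(v))
    return InterspecificStats(
        avg_inter=float(np.mean(pooled)),
        theta_prime=float(np.mean([s.mean_to_others for s in per_species.values()])),
        smallest_inter=float(np.mean([s.min_to_others for s in per_species.values()])),
        per_species=per_species,
    )


def divergence_summary(dm: DistanceMatrix) -> DivergenceSummary:
    """Combine both statistic families on the percent scale."""
    intra = intraspecific_stats(dm)
    inter = interspecific_stats(dm)
    by_sp = dm.species_indices()
    return DivergenceSummary(
        avg_intra=100.0 * intra.avg_intra,
        theta=100.0 * intra.theta,
        coalescent_depth=100.0 * intra.coalescent_depth,
        avg_inter=100.0 * inter.avg_inter,
        theta_prime=100.0 * inter.theta_prime,
        smallest_inter=100.0 * inter.smallest_inter,
        n_species_multi=sum(1 for idx in by_sp.values() if len(idx) >= 2),
        n_species_total=len(by_sp),
    )
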