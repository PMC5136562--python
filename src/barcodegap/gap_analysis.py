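"""Barcoding-gap assessment: global distance distributions and the local gap.

The *global* assessment compares the relative-frequency distributions of
intraspecific and interspecific K2P distances on shared histogram bins; the
overlap fraction is the summed bin-wise minimum of the two relative
frequencies (1 = identical distributions, 0 = disjoint supports at this bin
width).

The *local gap* is the per-species discrimination criterion: a species with
more than one individual is successfully discriminated when the minimum
interspecific distance involving any of its individuals is strictly larger
than its maximum intraspecific distance. Ties fail. Singleton species are
not evaluated but still serve as heterospecific neighbors of evaluated
species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import InsufficientDataError, UndefinedSummaryError


@dataclass(frozen=True)
class DistanceDistributions:
    bin_edges: np.ndarray
    intra_freq: np.ndarray  # relative frequencies, sum to 1
    inter_freq: np.ndarray
    overlap_fraction: float
    global_gap: bool


@dataclass(frozen=True)
class SpeciesGap:
    species: str
    n_individuals: int
    max_intra: float
    min_inter: float
    gap: bool


@dataclass(frozen=True)
class LocalGapResult:
    per_species: dict[str, SpeciesGap]
    resolution_rate: float
    n_evaluated: int

    @property
    def per_species_gap(self) -> dict[str, bool]:
        return {sp: rec.gap for sp, rec in self.per_species.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": r.species,
                    "n_individuals": r.n_individuals,
                    "max_intra": r.max_intra,
                    "min_inter": r.min_inter,
                    "gap": r.gap,
                }
                for r in self.per_species.values()
            ]
        )


@dataclass(frozen=True)
class GapAssessment:
    distributions: DistanceDistributions
    local: LocalGapResult


def distance_distributions(dm: DistanceMatrix, bin_width: float = 0.005) -> DistanceDistributions:
    """Histogram intra vs inter distances on shared bins and measure overlap."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intra = dm.intra_distances()
    inter = dm.inter_distances()
    if intra.size == 0 or inter.size == 0:
        raise UndefinedSummaryError(
            "gap assessment needs at least one defined intra and inter pair"
        )
    top = float(max(intra.max(), inter.max()))
    n_bins = max(1, int(math.ceil(top / bin_width + 1e-9)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    if edges[-1] <= top:  # guard the right edge against rounding
        edges = np.append(edges, edges[-1] + bin_width)
    intra_freq = np.histogram(intra, bins=edges)[0] / intra.size
    inter_freq = np.histogram(inter, bins=edges)[0] / inter.size
    overlap = float(np.minimum(intra_freq, inter_freq).sum())
    return DistanceDistributions(
        bin_edges=edges,
        intra_freq=intra_freq,
        inter_freq=inter_freq,
        overlap_fraction=overlap,
        global_gap=bool(inter.min() > intra.max()),
    )


def local_gap_resolution(dm: DistanceMatrix) -> LocalGapResult:
    """Per-species local barcoding gap verdicts and the resolution rate."""
    by_sp = dm.species_indices()
    per_species: dict[str, SpeciesGap] = {}
    for sp, idx in by_sp.items():
        if len(idx) < 2:
            continue
        intra = [
            dm.values[idx[a], idx[b]]
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
            if not math.isnan(dm.values[idx[a], idx[b]])
        ]
        other = [i for s2, jx in by_sp.items() if s2 != sp for i in jx]
        inter = [
            dm.values[i, j] for i in idx for j in other if not math.isnan(dm.values[i, j])
        ]
        if not intra or not inter:
            continue  # cannot evaluate this species
        max_intra = float(np.max(intra))
        min_inter = float(np.min(inter))
        per_species[sp] = SpeciesGap(
            sp, len(idx), max_intra, min_inter, gap=min_inter > max_intra
        )
    if not per_species:
        raise InsufficientDataError("no multi-individual species with defined distances")
    n_eval = len(per_species)
    n_gap = sum(1 for r in per_species.values() if r.gap)
    return LocalGapResult(per_species, n_gap / n_eval, n_eval)


def assess_gap(dm: DistanceMatrix, bin_width: float = 0.005) -> GapAssessment:
    return GapAssessment(distance_distributions(dm, bin_width), local_gap_resolution(dm))


def histogram_frame(dist: DistanceDistributions) -> pd.DataFrame:
    """Long-form histogram table, ready for plotting or CSV export."""
    return pd.DataFrame(
        {
            "bin_left": dist.bin_edges[:-1],
            "bin_right": dist.bin_edges[1:],
            "intra_freq": dist.intra_freq,
            "inter_freq": dist.inter_freq,
        }
    )
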