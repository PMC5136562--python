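"""Synthetic multi-marker radiation datasets for barcode-evaluation testing.

The generator emulates the data structure of a recently radiated plant genus
sampled for barcoding: ~40 species with 1–8 individuals each, several
markers sharing one species tree but evolving at very different rates (slow
plastid coding gene through fast nuclear spacer), low interspecific
divergence, overlapping intraspecific variation, cryptic species pairs with
identical species-level sequences, and a distant outgroup taxon.

Model: a Yule (pure-birth) species tree is drawn and rescaled so the mean
terminal ("stem") branch equals ``stem_divergence`` expected
substitutions/site at rate multiplier 1. A random ancestral sequence evolves
along the tree under a two-rate substitution process: each mutation event
hits a uniformly chosen site and is a transition with probability
kappa/(kappa+2), otherwise one of the two transversions — the generating
process the K2P estimator assumes. Within species, individuals are
independent mutation draws from the species-level sequence (star genealogy)
at rate ``intra_divergence``. Sequences are emitted already aligned: no
indel process, so simulated homology is the alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sequence_io import AlignedMarkerSet, SampleRecord, write_aligned_fasta

_BASES = "ACGT"


@dataclass(frozen=True)
class MarkerModel:
    """One simulated locus: name, aligned length (bp) and relative rate."""

    name: str
    length: int
    rate_multiplier: float = 1.0


#: Four markers mirroring the canonical plant-barcode rate spectrum:
#: slow plastid coding gene, faster plastid coding gene, plastid spacer,
#: fast nuclear ribosomal spacer (relative rates 1:3:5:12).
DEFAULT_MARKERS = (
    MarkerModel("rbcL_like", 1187, 1.0),
    MarkerModel("matK_like", 815, 3.0),
    MarkerModel("trnH_psbA_like", 1001, 5.0),
    MarkerModel("ITS_like", 827, 12.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 40
    individuals_per_species: tuple[int, int] = (2, 6)
    markers: tuple[MarkerModel, ...] = DEFAULT_MARKERS
    kappa: float = 2.0
    stem_divergence: float = 0.0008  # expected subs/site on a species stem, rate 1
    intra_divergence: float = 0.0015  # expected subs/site individual vs species seq
    n_cryptic_pairs: int = 2
    n_singletons: int = 13
    include_outgroup: bool = True
    outgroup_divergence: float = 0.03  # subs/site root->outgroup, rate 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        lo, hi = self.individuals_per_species
        if not (2 <= lo <= hi):
            raise ConfigError("individuals_per_species must satisfy 2 <= lo <= hi")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        if self.stem_divergence < 0 or self.intra_divergence < 0:
            raise ConfigError("divergences must be >= 0")
        if 2 * self.n_cryptic_pairs + self.n_singletons > self.n_species:
            raise ConfigError(
                "2*n_cryptic_pairs + n_singletons exceeds n_species "
                f"({2 * self.n_cryptic_pairs}+{self.n_singletons} > {self.n_species})"
            )
        if not self.markers:
            raise ConfigError("at least one marker model required")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth behind a simulated dataset."""

    species_of: dict[str, str]
    cryptic_pairs: tuple[tuple[str, str], ...]  # species-name pairs, zero stem divergence
    singletons: frozenset[str]  # species with exactly one individual
    outgroup_species: str | None

    def cryptic_species(self) -> frozenset[str]:
        return frozenset(s for pair in self.cryptic_pairs for s in pair)

    def to_frame(self) -> pd.DataFrame:
        cryptic = self.cryptic_species()
        return pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "species": sp,
                    "singleton": sp in self.singletons,
                    "cryptic": sp in cryptic,
                    "outgroup": sp == self.outgroup_species,
                }
                for sid, sp in sorted(self.species_of.items())
            ]
        )


@dataclass
class SimulationResult:
    config: SimulationConfig
    marker_sets: tuple[AlignedMarkerSet, ...]
    truth: TruthTable
    species_tree_newick: str
    #: per marker: realized substitution-event counts, split by process
    #: ("tree" = species-tree branches, "intra" = within-species draws,
    #: "outgroup" = root->outgroup branch)
    mutation_events: dict[str, dict[str, int]]


# --- species tree ----------------------------------------------------------


class _SimNode:
    __slots__ = ("name", "children", "start", "_blen")

    def __init__(self, name=None, start=0.0):
        self.name = name
        self.children: list[tuple["_SimNode", float]] = []
        self.start = start


def _yule_tree(n_species: int, rng: np.random.Generator) -> tuple[_SimNode, dict[str, float]]:
    """Pure-birth tree with unit speciation rate; returns (root, stem lengths)."""
    root = _SimNode(start=0.0)
    active: list[_SimNode] = [root]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(0, k)))
        left, right = _SimNode(start=t), _SimNode(start=t)
        node.children = [(left, 0.0), (right, 0.0)]
        node._blen = t - node.start  # branch above `node` is fixed now
        active += [left, right]
    # let the youngest lineages accrue some terminal length
    t += rng.exponential(1.0 / n_species)
    stems: dict[str, float] = {}
    for i, leaf in enumerate(active):
        leaf.name = f"sp{i:02d}"
        leaf._blen = t - leaf.start  # type: ignore[attr-defined]
        stems[leaf.name] = leaf._blen
    # attach stored branch lengths into child tuples
    def fix(node: _SimNode) -> None:
        node.children = [(c, getattr(c, "_blen", 0.0)) for c, _ in node.children]
        for c, _ in node.children:
            fix(c)

    fix(root)
    return root, stems


def _scale_tree(node: _SimNode, factor: float) -> None:
    node.children = [(c, bl * factor) for c, bl in node.children]
    for c, _ in node.children:
        _scale_tree(c, factor)


def _tree_newick(node: _SimNode) -> str:
    def render(n: _SimNode) -> str:
        if not n.children:
            return n.name
        inner = ",".join(f"{render(c)}:{bl:.8f}" for c, bl in n.children)
        return f"({inner})"

    return render(node) + ";"


# --- sequence evolution ----------------------------------------------------


def _mutate(seq: np.ndarray, n_events: int, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_events`` point mutations; transition w.p. kappa/(kappa+2).

    Codes: A=0, C=1, G=2, T=3. Transition partner is ``base ^ 2``; the two
    transversions are ``base ^ 1`` and ``base ^ 3``. Repeated hits at one
    site are allowed (multiple substitutions, as the K2P model corrects for).
    """
    if n_events == 0:
        return seq.copy()
    out = seq.copy()
    sites = rng.integers(0, len(seq), size=n_events)
    p_ts = kappa / (kappa + 2.0)
    draws = rng.random(n_events)
    picks = rng.integers(0, 2, size=n_events)
    for s, u, pick in zip(sites, draws, picks):
        base = int(out[s])
        if u < p_ts:
            out[s] = base ^ 2
        else:
            out[s] = base ^ (1 if pick == 0 else 3)
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


# --- main entry ------------------------------------------------------------


def simulate_radiation(cfg: SimulationConfig) -> SimulationResult:
    """Generate aligned multi-marker data plus ground truth; deterministic per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    root, stems = _yule_tree(cfg.n_species, rng)
    mean_stem = float(np.mean(list(stems.values())))
    scale = cfg.stem_divergence / mean_stem if mean_stem > 0 else 0.0
    _scale_tree(root, scale)
    tree_newick = _tree_newick(root)

    species = sorted(stems)  # sp00..spNN
    # role assignment: cryptic pairs first, then singletons, from a shuffle
    shuffled = list(species)
    rng.shuffle(shuffled)
    cryptic_pairs = tuple(
        (shuffled[2 * i], shuffled[2 * i + 1]) for i in range(cfg.n_cryptic_pairs)
    )
    singleton_species = frozenset(
        shuffled[2 * cfg.n_cryptic_pairs : 2 * cfg.n_cryptic_pairs + cfg.n_singletons]
    )
    lo, hi = cfg.individuals_per_species
    n_indiv = {
        sp: 1 if sp in singleton_species else int(rng.integers(lo, hi + 1))
        for sp in species
    }

    species_name = {sp: f"Oberonia_synth{int(sp[2:]):02d}" for sp in species}
    outgroup_species = "Dendrobium_outgroup" if cfg.include_outgroup else None

    marker_sets = []
    mutation_events: dict[str, dict[str, int]] = {}
    for marker in cfg.markers:
        L = marker.length
        mult = marker.rate_multiplier
        events = {"tree": 0, "intra": 0, "outgroup": 0}
        root_seq = rng.integers(0, 4, size=L).astype(np.uint8)

        tip_seqs: dict[str, np.ndarray] = {}

        def evolve(node: _SimNode, seq: np.ndarray) -> None:
            for child, blen in node.children:
                n_mut = int(rng.poisson(blen * mult * L))
                events["tree"] += n_mut
                child_seq = _mutate(seq, n_mut, cfg.kappa, rng)
                if child.children:
                    evolve(child, child_seq)
                else:
                    tip_seqs[child.name] = child_seq

        evolve(root, root_seq)

        # cryptic pairs: second member shares the first member's sequence
        for a, b in cryptic_pairs:
            tip_seqs[b] = tip_seqs[a].copy()

        # within-species variation: star genealogy off the species sequence;
        # the marker rate multiplier applies to the species-tree process only,
        # so intraspecific depth is an independent knob
        records = []
        for sp in species:
            for j in range(1, n_indiv[sp] + 1):
                n_mut = int(rng.poisson(cfg.intra_divergence * L))
                events["intra"] += n_mut
                seq = _mutate(tip_seqs[sp], n_mut, cfg.kappa, rng)
                records.append(
                    SampleRecord(f"{sp}_i{j}", species_name[sp], _codes_to_str(seq))
                )
        if cfg.include_outgroup:
            n_mut = int(rng.poisson(cfg.outgroup_divergence * mult * L))
            events["outgroup"] += n_mut
            og = _mutate(root_seq, n_mut, cfg.kappa, rng)
            records.append(SampleRecord("og_i1", outgroup_species, _codes_to_str(og)))
        marker_sets.append(AlignedMarkerSet(marker.name, tuple(records)))
        mutation_events[marker.name] = events

    species_of = {r.sample_id: r.species for r in marker_sets[0].records}
    truth = TruthTable(
        species_of=species_of,
        cryptic_pairs=tuple(
            (species_name[a], species_name[b]) for a, b in cryptic_pairs
        ),
        singletons=frozenset(species_name[sp] for sp in singleton_species),
        outgroup_species=outgroup_species,
    )
    return SimulationResult(cfg, tuple(marker_sets), truth, tree_newick, mutation_events)


def realized_divergence_report(result: SimulationResult) -> pd.DataFrame:
    """Realized mean intra/inter K2P distances per marker (outgroup excluded)."""
    from .distances import pairwise_matrix

    rows = []
    for ms, marker in zip(result.marker_sets, result.config.markers):
        ingroup = [
            r for r in ms.records if r.species != result.truth.outgroup_species
        ]
        dm = pairwise_matrix(AlignedMarkerSet(ms.marker_name, tuple(ingroup)))
        intra = dm.intra_distances()
        inter = dm.inter_distances()
        rows.append(
            {
                "marker": ms.marker_name,
                "rate_multiplier": marker.rate_multiplier,
                "realized_avg_intra": float(intra.mean()) if intra.size else np.nan,
                "realized_avg_inter": float(inter.mean()) if inter.size else np.nan,
                "expected_intra": result.config.intra_divergence * 2,
                "n_undefined_pairs": len(dm.undefined_pairs),
            }
        )
    return pd.DataFrame(rows)


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Emit per-marker FASTA, truth TSV, species tree and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ms in result.marker_sets:
        write_aligned_fasta(ms, outdir / f"{ms.marker_name}.fasta")
    result.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    (outdir / "species_tree.nwk").write_text(result.species_tree_newick + "\n")
    cfg = asdict(result.config)
    cfg["markers"] = [asdict(m) for m in result.config.markers]
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
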