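"""Neighbor-joining trees, bootstrap supports, and species monophyly scoring.

The tree-based species-discrimination criterion: a species is *successfully
identified* when all of its individuals form a monophyletic group whose
subtending node has bootstrap support above a threshold (0.70 by default;
0.95 is the conventional alternative for posterior-probability-style
supports and is available as a configuration choice).

NJ is the classical Saitou–Nei agglomeration on the K2P distance matrix.
Determinism contract: ties in the Q-criterion are broken by the
lexicographically smallest pair of current node labels (an internal node is
labeled by its smallest descendant leaf), and negative branch lengths are
clipped to zero with the deficit transferred to the sister edge. Bootstrap
supports are bipartition frequencies over column-resampled replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix, k2p_matrix_from_codes, encode_alignment
from .errors import BarcodeGapError, InsufficientDataError, RootingError
from .sequence_io import AlignedMarkerSet

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Minimal node used during NJ agglomeration (converted to dendropy afterwards)
class _Node:
    __slots__ = ("name", "children", "label")

    def __init__(self, name=None, children=None, label=None):
        self.name = name  # leaf name, None for internal
        self.children = children or []  # list of (child, branch_length)
        self.label = label  # sort key: smallest descendant leaf label

    def leafset(self) -> frozenset[str]:
        if self.name is not None:
            return frozenset((self.name,))
        out = set()
        for c, _ in self.children:
            out |= c.leafset()
        return frozenset(out)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.name is not None:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.10f}" for c, bl in self.children)
        return f"({inner})"


def _clip_pair(li: float, lj: float) -> tuple[float, float]:
    """Clip a negative branch to 0, moving the deficit to the sister edge."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _nj_agglomerate(values: np.ndarray, labels: list[str]) -> _Node:
    nodes = [_Node(name=l, label=l) for l in labels]
    M = values.astype(float).copy()
    while len(nodes) > 3:
        k = len(nodes)
        r = M.sum(axis=0)
        Q = (k - 2) * M - r[:, None] - r[None, :]
        # evaluate the upper triangle only: Q[i,j] and Q[j,i] can differ in
        # the last ulp (float summation order), which would break tie search
        iu, ju = np.triu_indices(k, 1)
        qv = Q[iu, ju]
        qmin = qv.min()
        hits = np.flatnonzero(qv == qmin)
        pairs = sorted(
            (tuple(sorted((nodes[iu[h]].label, nodes[ju[h]].label))), int(iu[h]), int(ju[h]))
            for h in hits
        )
        _, i, j = pairs[0]
        d_ij = M[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = d_ij - li
        li, lj = _clip_pair(li, lj)
        new = _Node(
            children=[(nodes[i], li), (nodes[j], lj)],
            label=min(nodes[i].label, nodes[j].label),
        )
        d_new = 0.5 * (M[i] + M[j] - d_ij)
        keep = [m for m in range(k) if m not in (i, j)]
        M2 = np.empty((k - 1, k - 1))
        M2[: k - 2, : k - 2] = M[np.ix_(keep, keep)]
        M2[-1, : k - 2] = d_new[keep]
        M2[: k - 2, -1] = d_new[keep]
        M2[-1, -1] = 0.0
        M = M2
        nodes = [nodes[m] for m in keep] + [new]
    if len(nodes) == 3:
        d01, d02, d12 = M[0, 1], M[0, 2], M[1, 2]
        l0 = max(0.0, (d01 + d02 - d12) / 2.0)
        l1 = max(0.0, (d01 + d12 - d02) / 2.0)
        l2 = max(0.0, (d02 + d12 - d01) / 2.0)
        root = _Node(
            children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)],
            label=min(n.label for n in nodes),
        )
    else:  # exactly 2 nodes (only via degenerate internal calls)
        root = _Node(children=[(nodes[0], M[0, 1] / 2), (nodes[1], M[0, 1] / 2)],
                     label=min(n.label for n in nodes))
    return root


def _node_bipartitions(root: _Node, all_leaves: frozenset[str], ref: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, normalized away from ref."""
    bips: set[frozenset[str]] = set()

    def walk(node: _Node) -> frozenset[str]:
        if node.name is not None:
            return frozenset((node.name,))
        below = set()
        for c, _ in node.children:
            below |= walk(c)
        side = frozenset(below)
        if node is not root and 2 <= len(side) <= len(all_leaves) - 2:
            bips.add(_normalize(side, all_leaves, ref))
        return side

    walk(root)
    return bips


def _normalize(side: frozenset[str], all_leaves: frozenset[str], ref: str) -> frozenset[str]:
    return all_leaves - side if ref in side else side


# --------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """An (unrooted) NJ tree with optional bootstrap supports.

    ``supports`` maps normalized bipartitions (the side not containing the
    lexicographically smallest leaf) to support fractions in [0, 1].
    """

    tree: dendropy.Tree
    supports: dict[frozenset[str], float] | None = None
    outgroup: tuple[str, ...] | None = None
    dropped_samples: tuple[str, ...] = ()
    n_replicates_used: int = 0

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tree.taxon_namespace)

    @property
    def ref_leaf(self) -> str:
        return min(self.leaves)

    def topology_bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions present in the tree topology."""
        leaves = self.leaves
        ref = self.ref_leaf
        bips: set[frozenset[str]] = set()
        for node in self.tree.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(leaves) - 2:
                bips.add(_normalize(side, leaves, ref))
        return bips

    def clade_support(self, leafset: frozenset[str]) -> float | None:
        """Support of the edge separating ``leafset`` from everything else.

        Trivial splits (single leaf, or all-but-one) are always present and
        get support 1.0. Returns None when supports were never computed.
        """
        leaves = self.leaves
        if len(leafset) <= 1 or len(leaves - leafset) <= 1:
            return 1.0 if self.supports is not None else None
        if self.supports is None:
            return None
        return self.supports.get(_normalize(leafset, leaves, self.ref_leaf))

    def to_newick(self) -> str:
        """Newick string with supports (when present) as internal node labels."""
        leaves = self.leaves
        ref = self.ref_leaf
        seed = self.tree.seed_node

        def render(node) -> str:
            if node.is_leaf():
                return node.taxon.label
            inner = ",".join(
                f"{render(c)}:{(c.edge.length or 0.0):.10f}" for c in node.child_nodes()
            )
            label = ""
            if self.supports is not None and node is not seed:
                side = frozenset(lf.taxon.label for lf in node.leaf_iter())
                if 2 <= len(side) <= len(leaves) - 2:
                    sup = self.supports.get(_normalize(side, leaves, ref))
                    if sup is not None:
                        label = f"{sup:.4f}"
            return f"({inner}){label}"

        return render(seed) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, newick: str, outgroup: tuple[str, ...] | None = None) -> "Phylogeny":
        """Parse a newick tree, reading internal node labels as supports.

        Labels > 1 are interpreted as percentages and divided by 100.
        """
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        leaves = frozenset(t.label for t in tree.taxon_namespace)
        ref = min(leaves)
        supports: dict[frozenset[str], float] = {}
        any_support = False
        for node in tree.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            try:
                sup = float(node.label)
            except ValueError:
                continue
            if sup > 1.0:
                sup /= 100.0
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(leaves) - 2:
                supports[_normalize(side, leaves, ref)] = sup
                any_support = True
        return cls(tree=tree, supports=supports if any_support else None, outgroup=outgroup)


@dataclass(frozen=True)
class MonophylyVerdict:
    species: str
    status: str  # supported_monophyletic | unsupported_monophyletic | non_monophyletic | singleton
    support: float | None
    n_individuals: int


@dataclass(frozen=True)
class MonophylyResult:
    verdicts: tuple[MonophylyVerdict, ...]
    resolution_rate: float
    n_evaluated: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "species": v.species,
                    "n_individuals": v.n_individuals,
                    "status": v.status,
                    "support": v.support,
                }
                for v in self.verdicts
            ]
        )


# --------------------------------------------------------------------------


def complete_case_samples(dm: DistanceMatrix) -> tuple[DistanceMatrix, tuple[str, ...]]:
    """Drop the fewest samples needed to remove every undefined pair.

    Greedy: repeatedly remove the sample participating in the most undefined
    pairs (ties broken by label). Returns (submatrix, dropped_ids).
    """
    ids = list(dm.sample_ids)
    values = dm.values.copy()
    dropped: list[str] = []
    while True:
        nan_counts = np.isnan(values).sum(axis=1)
        if nan_counts.sum() == 0:
            break
        worst = min(
            (i for i in range(len(ids)) if nan_counts[i] == nan_counts.max()),
            key=lambda i: ids[i],
        )
        dropped.append(ids[worst])
        keep = [i for i in range(len(ids)) if i != worst]
        values = values[np.ix_(keep, keep)]
        ids = [ids[i] for i in keep]
    if dropped:
        logger.warning("dropped %d sample(s) with undefined distances: %s", len(dropped), dropped)
    if len(ids) < 3:
        raise InsufficientDataError("fewer than 3 samples remain after dropping undefined pairs")
    sub = dm.submatrix(ids)
    return sub, tuple(dropped)


def nj_tree(dm: DistanceMatrix, outgroup: tuple[str, ...] | None = None) -> Phylogeny:
    """Saitou–Nei neighbor joining on a (complete) distance matrix."""
    if dm.n_samples < 3:
        raise InsufficientDataError("NJ needs at least 3 samples")
    dm_complete, dropped = complete_case_samples(dm)
    root = _nj_agglomerate(dm_complete.values, list(dm_complete.sample_ids))
    tree = dendropy.Tree.get(data=root.newick(), schema="newick", preserve_underscores=True)
    return Phylogeny(tree=tree, outgroup=outgroup, dropped_samples=dropped)


def bootstrap_supports(
    ms: AlignedMarkerSet,
    n_replicates: int = 1000,
    seed: int = 0,
    outgroup: tuple[str, ...] | None = None,
) -> Phylogeny:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement per replicate; each replicate's
    K2P+NJ tree votes for the reference tree's bipartitions. Replicates with
    undefined distances are dropped (aborting if more than 10% drop).
    """
    if len(ms.records) < 3:
        raise InsufficientDataError("bootstrap needs at least 3 records")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .distances import pairwise_matrix

    codes = encode_alignment(ms)
    dm = pairwise_matrix(ms)
    dm_complete, dropped_samples = complete_case_samples(dm)
    keep_idx = [list(ms.sample_ids).index(sid) for sid in dm_complete.sample_ids]
    codes = codes[keep_idx]
    labels = list(dm_complete.sample_ids)
    all_leaves = frozenset(labels)
    ref_leaf = min(all_leaves)

    ref_root = _nj_agglomerate(dm_complete.values, labels)
    ref_bips = _node_bipartitions(ref_root, all_leaves, ref_leaf)

    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    counts = {b: 0 for b in ref_bips}
    dropped_reps = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_values, _ = k2p_matrix_from_codes(codes[:, cols])
        if np.isnan(rep_values).any():
            dropped_reps += 1
            continue
        rep_root = _nj_agglomerate(rep_values, labels)
        rep_bips = _node_bipartitions(rep_root, all_leaves, ref_leaf)
        for b in ref_bips & rep_bips:
            counts[b] += 1
    if dropped_reps > 0:
        logger.warning("%d/%d bootstrap replicates dropped (undefined distances)",
                       dropped_reps, n_replicates)
    used = n_replicates - dropped_reps
    if used == 0 or dropped_reps / n_replicates > 0.10:
        raise BarcodeGapError(
            f"bootstrap aborted: {dropped_reps}/{n_replicates} replicates had "
            "undefined (saturated) distances; the alignment is too sparse or divergent"
        )
    supports = {b: counts[b] / used for b in ref_bips}
    tree = dendropy.Tree.get(data=ref_root.newick(), schema="newick", preserve_underscores=True)
    return Phylogeny(
        tree=tree,
        supports=supports,
        outgroup=outgroup,
        dropped_samples=dropped_samples,
        n_replicates_used=used,
    )


def assess_monophyly(
    phylo: Phylogeny,
    species_of: dict[str, str],
    support_threshold: float = 0.70,
) -> MonophylyResult:
    """Per-species monophyly verdicts and the tree-based resolution rate.

    Rooting semantics: with a declared outgroup, a species is monophyletic
    iff the tree contains the split separating exactly its individuals from
    everything else (including the outgroup) — equivalent to an exclusive
    clade in the outgroup-rooted tree. The resolution rate counts
    supported_monophyletic species among multi-individual ingroup species;
    singletons are reported but not evaluated.
    """
    leaves = phylo.leaves
    outgroup = frozenset(phylo.outgroup or ())
    if outgroup - leaves:
        raise RootingError(f"outgroup labels not in tree: {sorted(outgroup - leaves)}")
    og_species = {species_of[s] for s in outgroup if s in species_of}
    ingroup = leaves - outgroup
    by_species: dict[str, set[str]] = {}
    for sid in ingroup:
        by_species.setdefault(species_of[sid], set()).add(sid)
    if og_species & set(by_species):
        raise RootingError(
            f"outgroup species also present in ingroup: {sorted(og_species & set(by_species))}"
        )
    topo = phylo.topology_bipartitions()
    ref = phylo.ref_leaf
    verdicts = []
    n_multi = 0
    n_supported = 0
    for sp in sorted(by_species):
        members = frozenset(by_species[sp])
        if len(members) == 1:
            verdicts.append(MonophylyVerdict(sp, "singleton", None, 1))
            continue
        n_multi += 1
        is_clade = (
            len(leaves - members) <= 1
            or _normalize(members, leaves, ref) in topo
        )
        if not is_clade:
            verdicts.append(MonophylyVerdict(sp, "non_monophyletic", None, len(members)))
            continue
        sup = phylo.clade_support(members)
        if sup is not None and sup > support_threshold:
            n_supported += 1
            verdicts.append(
                MonophylyVerdict(sp, "supported_monophyletic", sup, len(members))
            )
        else:
            verdicts.append(
                MonophylyVerdict(sp, "unsupported_monophyletic", sup, len(members))
            )
    if n_multi == 0:
        raise InsufficientDataError("no multi-individual ingroup species to evaluate")
    return MonophylyResult(tuple(verdicts), n_supported / n_multi, n_multi)
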