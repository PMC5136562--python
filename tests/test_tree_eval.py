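import math

import numpy as np
import pytest

from barcodegap.distances import pairwise_matrix
from barcodegap.errors import BarcodeGapError, InsufficientDataError, RootingError
from barcodegap.tree_eval import (
    Phylogeny,
    assess_monophyly,
    bootstrap_supports,
    complete_case_samples,
    nj_tree,
)
from conftest import make_dm, make_marker_set
from oracles import additive_matrix, random_binary_tree, tree_bipartitions_oracle


def _phylo_bips(ph):
    return ph.topology_bipartitions()


class TestNJ:
    def test_three_taxa_closed_form(self):
        # three-point formulas: l_a = (d_ab + d_ac - d_bc)/2 etc.
        ids = ["a", "b", "c"]
        v = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        ph = nj_tree(make_dm(ids, {"a": "A", "b": "B", "c": "C"}, v))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in ph.tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_exact_recovery_on_additive_five_taxon_matrix(self, rng):
        root, leaves = random_binary_tree(rng, 5)
        D = additive_matrix(root, leaves)
        dm = make_dm(leaves, {l: l for l in leaves}, D)
        ph = nj_tree(dm)
        assert _phylo_bips(ph) == tree_bipartitions_oracle(root, leaves)

    def test_tie_break_is_deterministic(self):
        # fully symmetric 4-taxon matrix: every Q equal; lexicographic pair
        # (t1, t2) must be joined first, giving the t1t2|t3t4 split
        ids = ["t1", "t2", "t3", "t4"]
        v = np.full((4, 4), 1.0)
        np.fill_diagonal(v, 0)
        ph = nj_tree(make_dm(ids, {i: i for i in ids}, v))
        assert _phylo_bips(ph) == {frozenset({"t3", "t4"})}

    def test_too_few_samples(self):
        v = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(InsufficientDataError):
            nj_tree(make_dm(["a", "b"], {"a": "A", "b": "B"}, v))

    def test_agrees_with_skbio_on_random_additive_matrices(self, rng):
        """Independent-library cross-check of the NJ topology."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for _ in range(10):
            n = int(rng.integers(5, 9))
            root, leaves = random_binary_tree(rng, n)
            D = additive_matrix(root, leaves)
            ph = nj_tree(make_dm(leaves, {l: l for l in leaves}, D))
            sk_tree = sk_nj(SkDM(D, ids=leaves))
            ref = min(leaves)
            sk_bips = set()
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    sk_bips.add(frozenset(leaves) - side if ref in side else side)
            assert _phylo_bips(ph) == sk_bips

    def test_undefined_pairs_dropped_greedily(self):
        ids = ["a", "b", "c", "d"]
        v = np.array(
            [
                [0, 0.1, 0.1, math.nan],
                [0.1, 0, 0.1, math.nan],
                [0.1, 0.1, 0, 0.1],
                [math.nan, math.nan, 0.1, 0],
            ]
        )
        dm = make_dm(ids, {i: "sp" + i for i in ids}, v)
        sub, dropped = complete_case_samples(dm)
        assert dropped == ("d",)
        assert set(sub.sample_ids) == {"a", "b", "c"}


def _fixed_clade_alignment(rng, n_exclusive=50):
    """Six taxa; {e,f} share n_exclusive private columns -> near-certain edge."""
    L = 200
    base = rng.choice(list("ACGT"), L)
    seqs = {}
    for name in "abcdef":
        s = base.copy()
        for pos in rng.choice(L, size=6, replace=False):
            s[pos] = rng.choice(list("ACGT"))
        seqs[name] = s
    cols = rng.choice(L, size=n_exclusive, replace=False)
    for pos in cols:
        alt = "T" if base[pos] != "T" else "A"
        seqs["e"][pos] = seqs["f"][pos] = alt
    return make_marker_set(
        "m", [(n, f"sp_{n}", "".join(s)) for n, s in seqs.items()]
    )


class TestBootstrap:
    def test_fixed_clade_gets_full_support(self, rng):
        ms = _fixed_clade_alignment(rng)
        ph = bootstrap_supports(ms, n_replicates=100, seed=3)
        sup = ph.clade_support(frozenset({"e", "f"}))
        assert sup is not None and sup >= 0.95

    def test_single_replicate_supports_are_zero_or_one(self, rng):
        ms = _fixed_clade_alignment(rng)
        ph = bootstrap_supports(ms, n_replicates=1, seed=9)
        assert set(ph.supports.values()) <= {0.0, 1.0}

    def test_same_seed_identical_supports(self, rng):
        ms = _fixed_clade_alignment(rng)
        a = bootstrap_supports(ms, n_replicates=25, seed=7)
        b = bootstrap_supports(ms, n_replicates=25, seed=7)
        assert a.supports == b.supports
        assert a.to_newick() == b.to_newick()

    def test_support_invariant_to_leaf_order_permutation(self, rng):
        ms = _fixed_clade_alignment(rng)
        perm = list(rng.permutation(len(ms.records)))
        ms2 = make_marker_set(
            "m", [(r.sample_id, r.species, r.sequence) for r in (ms.records[i] for i in perm)]
        )
        a = bootstrap_supports(ms, n_replicates=50, seed=4)
        b = bootstrap_supports(ms2, n_replicates=50, seed=4)
        assert a.supports == b.supports


class TestMonophyly:
    def test_supported_clade_counts(self):
        nwk = "(((a1:1,a2:1)0.95:1,(b1:1,b2:1)0.60:1):1,og:5);"
        ph = Phylogeny.from_newick(nwk, outgroup=("og",))
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "og": "OG"}
        res = assess_monophyly(ph, species, support_threshold=0.70)
        status = {v.species: v.status for v in res.verdicts}
        assert status["A"] == "supported_monophyletic"
        assert status["B"] == "unsupported_monophyletic"
        assert res.resolution_rate == pytest.approx(0.5)

    def test_interdigitated_species_non_monophyletic(self):
        nwk = "(((a1:1,b1:1)0.99:1,(a2:1,b2:1)0.99:1):1,og:5);"
        ph = Phylogeny.from_newick(nwk, outgroup=("og",))
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "og": "OG"}
        res = assess_monophyly(ph, species)
        assert all(v.status == "non_monophyletic" for v in res.verdicts)
        assert res.resolution_rate == 0.0

    def test_singletons_flagged_not_evaluated(self):
        nwk = "(((a1:1,a2:1)0.9:1,x1:1):1,og:5);"
        ph = Phylogeny.from_newick(nwk, outgroup=("og",))
        species = {"a1": "A", "a2": "A", "x1": "X", "og": "OG"}
        res = assess_monophyly(ph, species)
        status = {v.species: v.status for v in res.verdicts}
        assert status["X"] == "singleton"
        assert res.n_evaluated == 1

    def test_threshold_rule_at_95_percent_alternative(self):
        nwk = "(((a1:1,a2:1)0.90:1,(b1:1,b2:1)0.99:1):1,og:5);"
        ph = Phylogeny.from_newick(nwk, outgroup=("og",))
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "og": "OG"}
        res = assess_monophyly(ph, species, support_threshold=0.95)
        status = {v.species: v.status for v in res.verdicts}
        assert status == {"A": "unsupported_monophyletic", "B": "supported_monophyletic"}

    def test_outgroup_species_in_ingroup_is_rooting_error(self):
        nwk = "((a1:1,a2:1):1,og:5);"
        ph = Phylogeny.from_newick(nwk, outgroup=("og",))
        species = {"a1": "A", "a2": "A", "og": "A"}
        with pytest.raises(RootingError):
            assess_monophyly(ph, species)

    def test_verdicts_independent_of_branch_lengths(self):
        a = "(((a1:1,a2:1)0.9:1,(b1:2,b2:9)0.8:1):1,og:5);"
        b = "(((a1:9,a2:4)0.9:2,(b1:1,b2:1)0.8:7):2,og:1);"
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "og": "OG"}
        ra = assess_monophyly(Phylogeny.from_newick(a, outgroup=("og",)), species)
        rb = assess_monophyly(Phylogeny.from_newick(b, outgroup=("og",)), species)
        assert [(v.species, v.status) for v in ra.verdicts] == [
            (v.species, v.status) for v in rb.verdicts
        ]


def test_end_to_end_from_alignment(rng):
    """K2P matrix -> NJ -> bootstrap -> monophyly on a tiny clean alignment."""
    ms = _fixed_clade_alignment(rng)
    dm = pairwise_matrix(ms)
    ph = nj_tree(dm)
    assert ph.leaves == frozenset("abcdef")
    ph2 = bootstrap_supports(ms, n_replicates=50, seed=1)
    assert set(ph2.supports) == ph2.topology_bipartitions()
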