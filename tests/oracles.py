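"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive — per-site loops, exhaustive pair
enumeration, sort-based percentiles — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


def k2p_oracle(a: str, b: str):
    """Per-site counting loop + direct formula. Returns (distance|None, n)."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return None, 0
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return None, n
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), n


def p_distance_oracle(a: str, b: str):
    n = d = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in BASES and y in BASES:
            n += 1
            d += x != y
    return None if n == 0 else d / n


def site_summary_oracle(seqs: list[str]):
    """(n_variable, n_parsimony_informative) by per-column hand scan."""
    n_var = n_pi = 0
    for col in zip(*seqs):
        counts = {}
        for c in col:
            if c in BASES:
                counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pi += 1
    return n_var, n_pi


# --- distance-matrix-level oracles (operate on ids/species/values) ---------


def _pairs(ids):
    return itertools.combinations(range(len(ids)), 2)


def divergence_oracle(ids, species, values):
    """The six divergence parameters by exhaustive enumeration.

    Returns dict or None entries when a family is undefined.
    """
    by_sp = {}
    for i, sid in enumerate(ids):
        by_sp.setdefault(species[sid], []).append(i)
    intra_pool, per_sp_mean, per_sp_max = [], [], []
    for sp, idx in by_sp.items():
        vals = [
            values[a][b]
            for a, b in itertools.combinations(idx, 2)
            if not math.isnan(values[a][b])
        ]
        if len(idx) >= 2 and vals:
            intra_pool += vals
            per_sp_mean.append(sum(vals) / len(vals))
            per_sp_max.append(max(vals))
    inter_pool, tp, si = [], [], []
    for sp, idx in by_sp.items():
        other = [i for s2, jx in by_sp.items() if s2 != sp for i in jx]
        vals = [
            values[i][j] for i in idx for j in other if not math.isnan(values[i][j])
        ]
        if vals:
            tp.append(sum(vals) / len(vals))
            si.append(min(vals))
    for a, b in _pairs(ids):
        if species[ids[a]] != species[ids[b]] and not math.isnan(values[a][b]):
            inter_pool.append(values[a][b])
    out = {}
    out["avg_intra"] = sum(intra_pool) / len(intra_pool) if intra_pool else None
    out["theta"] = sum(per_sp_mean) / len(per_sp_mean) if per_sp_mean else None
    out["coalescent_depth"] = sum(per_sp_max) / len(per_sp_max) if per_sp_max else None
    out["avg_inter"] = sum(inter_pool) / len(inter_pool) if inter_pool else None
    out["theta_prime"] = sum(tp) / len(tp) if tp else None
    out["smallest_inter"] = sum(si) / len(si) if si else None
    return out


def local_gap_oracle(ids, species, values):
    """Per-species local-gap verdicts by exhaustive min/max scan."""
    by_sp = {}
    for i, sid in enumerate(ids):
        by_sp.setdefault(species[sid], []).append(i)
    verdicts = {}
    for sp, idx in by_sp.items():
        if len(idx) < 2:
            continue
        intra = [
            values[a][b]
            for a, b in itertools.combinations(idx, 2)
            if not math.isnan(values[a][b])
        ]
        inter = [
            values[i][j]
            for i in idx
            for s2, jx in by_sp.items()
            if s2 != sp
            for j in jx
            if not math.isnan(values[i][j])
        ]
        if intra and inter:
            verdicts[sp] = min(inter) > max(intra)
    return verdicts


def bm_oracle(ids, species, values):
    """Best-match verdict per evaluated query, by nearest-neighbor enumeration."""
    by_sp = {}
    for sid in ids:
        by_sp.setdefault(species[sid], []).append(sid)
    multi = {sp for sp, ss in by_sp.items() if len(ss) >= 2}
    verdicts = {}
    for qi, q in enumerate(ids):
        if species[q] not in multi:
            continue
        dists = [
            (values[qi][j], ids[j])
            for j in range(len(ids))
            if j != qi and not math.isnan(values[qi][j])
        ]
        if not dists:
            continue
        best = min(d for d, _ in dists)
        matches = [sid for d, sid in dists if d == best]
        match_sp = {species[m] for m in matches}
        if match_sp == {species[q]}:
            verdicts[q] = ("correct", best)
        elif species[q] in match_sp:
            verdicts[q] = ("ambiguous", best)
        else:
            verdicts[q] = ("incorrect", best)
    return verdicts


def bcm_oracle(ids, species, values, threshold):
    out = {}
    for q, (verdict, best) in bm_oracle(ids, species, values).items():
        out[q] = ("unidentified", best) if best > threshold else (verdict, best)
    return out


def percentile_oracle(xs, pct):
    """Linear interpolation between order statistics (sort-and-index)."""
    s = sorted(xs)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * pct / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


# --- random fixtures -------------------------------------------------------


def random_labeled_matrix(rng: np.random.Generator, n: int = 30):
    """Random species-labeled distance matrix with ties and undefined pairs.

    Values snap to a coarse grid so exact-distance ties occur; ~5% of pairs
    are set undefined (NaN).
    """
    n_species = int(rng.integers(4, 10))
    ids = [f"q{i:02d}" for i in range(n)]
    species = {sid: f"sp{rng.integers(0, n_species)}" for sid in ids}
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.05:
                v = math.nan
            else:
                v = round(float(rng.integers(0, 40)) / 400.0, 6)
            values[i, j] = values[j, i] = v
    return ids, species, values


def random_binary_tree(rng: np.random.Generator, n_taxa: int):
    """Random topology + positive branch lengths; returns (root, leaf names).

    Nodes are dicts: {"name": str|None, "children": [(node, blen), ...]}.
    """
    nodes = [{"name": f"t{i}", "children": []} for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(
            {
                "name": None,
                "children": [
                    (a, float(rng.uniform(0.05, 1.0))),
                    (b, float(rng.uniform(0.05, 1.0))),
                ],
            }
        )
    return nodes[0], [f"t{i}" for i in range(n_taxa)]


def additive_matrix(root, leaves):
    """Path-length distances between all leaf pairs of a branch-length tree.

    Each leaf's root path is a set of (edge id -> length); the pairwise
    distance is the total length of the symmetric difference of edge sets.
    """
    paths = {}

    def walk(node, acc):
        if node["name"] is not None:
            paths[node["name"]] = acc
        for child, bl in node["children"]:
            walk(child, {**acc, id(child): bl})

    walk(root, {})
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[leaves[i]], paths[leaves[j]]
            keys = set(pa) ^ set(pb)
            d = sum(pa.get(k, 0.0) + pb.get(k, 0.0) for k in keys)
            D[i, j] = D[j, i] = d
    return D


def tree_bipartitions_oracle(root, leaves):
    """Non-trivial splits of an unrooted tree, normalized away from min leaf."""
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    bips = set()

    def leafset(node):
        if node["name"] is not None:
            return frozenset((node["name"],))
        out = frozenset()
        for c, _ in node["children"]:
            out |= leafset(c)
        return out

    def walk(node, is_root):
        side = leafset(node)
        if not is_root and node["name"] is None and 2 <= len(side) <= len(all_leaves) - 2:
            bips.add(all_leaves - side if ref in side else side)
        for c, _ in node["children"]:
            walk(c, False)

    walk(root, True)
    return bips
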