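# Methods

## Distances

Pairwise distances use the Kimura 2-parameter model. For each sequence pair,
columns where either member carries a gap (`-`), missing (`?`) or any IUPAC
ambiguity code are removed first (**pairwise deletion**; ambiguity codes are
kept in storage but treated as missing by every statistic). Over the *n*
remaining comparable sites, with transition fraction *P* (A↔G, C↔T) and
transversion fraction *Q* (all other mismatches among unambiguous bases),

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` (saturation), or when *n* = 0, the
estimator is **undefined**: the pair is stored as NaN, logged, and excluded
from the numerator *and* denominator of every downstream summary. Undefined
distances are never coerced to a large constant — coercion would silently
distort gap statistics and nearest-neighbor verdicts. No gamma rate
heterogeneity is applied; the model is plain K2P.

## Divergence parameters

Six summaries characterize each marker, reported in percent (two decimals in
rendered tables, full precision in machine output):

| parameter | definition | domain |
|---|---|---|
| avg. intra | pooled mean of all conspecific pair distances | species with ≥ 2 individuals |
| theta (Θ) | per-species mean conspecific distance, averaged over species | ≥ 2 individuals |
| coalescent depth | per-species maximum conspecific distance, averaged | ≥ 2 individuals |
| avg. inter | pooled mean of all heterospecific pair distances | ≥ 2 species |
| theta prime (Θ′) | per-species mean distance to heterospecifics, averaged | all species |
| smallest inter | per-species minimum distance to heterospecifics, averaged | all species |

Because the pooled average weights species by their pair counts while theta
weights them equally, both are computed and emitted — they answer different
questions, and the per-species supplements let either pooling be audited.
Caveat: the pooled intra average is *not* guaranteed to lie below the
coalescent depth; a pair-rich divergent species can pull the pooled mean
above the unweighted mean of per-species maxima.

## Barcoding gap

The global assessment bins intra- and inter-specific distances on shared
histogram bins (default width 0.5%, configurable) and reports the overlap
fraction Σ min(rel. intra, rel. inter) plus a global-gap flag
(min inter > max intra). The per-species **local gap** uses strict
inequality — a tie fails — and evaluates only species with ≥ 2 individuals,
while singleton species still serve as heterospecific neighbors. Reports
always carry numerator and denominator alongside each rate, since the
evaluated-species denominator is where published resolution percentages
usually become ambiguous.

## BM / BCM identification

Queries are samples from multi-individual species; singleton-species samples
stay in the reference set as potential (mis)matches, since removing them
would invisibly change the neighbor structure. All non-self samples tied at
the minimum defined distance decide the verdict: all conspecific → correct,
all heterospecific → incorrect, mixed → ambiguous. The BCM threshold is the
95th percentile (linear interpolation between order statistics) of the
pooled intraspecific distance distribution; a best distance exactly at the
threshold counts as within ("close" is inclusive). Unidentified is reported
as an explicit fourth percentage, so the BCM verdict columns need not sum
to 100 on their own.

## Trees and monophyly

Neighbor joining is the classical Saitou–Nei agglomeration on the K2P
matrix. Determinism contract: Q-criterion ties are broken by the
lexicographically smallest pair of node labels (internal nodes are labeled
by their smallest descendant leaf); Q is minimized over the upper triangle
only, because floating-point summation order can make Q[i,j] and Q[j,i]
differ in the last ulp. Negative branch lengths are clipped to zero with the
deficit moved to the sister edge. NJ requires a complete matrix: samples
involved in undefined pairs are dropped greedily (most undefined pairs
first, ties by label) and logged — imputation would fabricate signal.

Bootstrap supports resample alignment columns with replacement, rebuild
K2P + NJ per replicate, and score each internal edge of the reference tree
by the fraction of replicates containing the same bipartition. Replicates
that produce undefined distances are dropped; more than 10% dropped aborts
with diagnostics. The default is 1000 replicates (200 in the bundled
acceptance runs, a problem-size choice that keeps full evaluations at about
a minute while leaving support estimates stable to a few percent).

A species is *supported monophyletic* when the tree contains the split
separating exactly its individuals from everything else — including the
outgroup — with support above the threshold (default 0.70; 0.95 is provided
as the conventional stricter alternative for posterior-style supports).
This unrooted-split formulation is equivalent to the rooted exclusive-clade
definition whenever the root lies outside the species, which the outgroup
guarantees; with no outgroup declared the same split criterion is applied
and coincides with midpoint-style rooting except in the pathological case
of a species clade spanning the root. Singletons are reported but excluded
from the resolution denominator, which counts multi-individual ingroup
species only.

## Synthetic radiations

The simulator emulates a barcoding study of a recently radiated genus: a
Yule species tree rescaled so the mean terminal (stem) branch equals
`stem_divergence` expected substitutions/site; a random ancestral sequence
evolved along it with Poisson(branch × rate × length) mutation events, each
hitting a uniform site and choosing a transition with probability
κ/(κ+2) — the generating process the K2P estimator assumes, so estimator
validation is exact-model; individuals drawn star-genealogically from their
species sequence at `intra_divergence`; cryptic pairs created by copying
one species' sequence onto its partner (zero realized stem divergence);
singletons forced to one individual; and an outgroup evolved directly from
the root sequence on a long branch.

The **marker rate multiplier applies to the species-tree and outgroup
processes only**, not to `intra_divergence`. In real multi-marker tables the
intra/inter ratio varies widely across markers rather than staying constant;
tying intraspecific depth to the marker rate would make the local-gap
criterion scale-invariant and erase the slow-marker failure mode the
simulator exists to reproduce. Realized mutation counts are tracked per
process (tree / intra / outgroup) so rate linearity can be checked on raw
Poisson counters rather than on distance estimates.

Defaults (chosen once to mirror the realistic study regime): 40 species,
2–6 individuals with 13 singletons, four markers of lengths 1187/815/1001/827
bp at rates 1:3:5:12, κ = 2, stem 0.0008 subs/site, intra 0.0015 subs/site,
2 cryptic pairs, outgroup at 0.03 subs/site. Under these settings realized
intraspecific divergence is ≈ 0.3% on all markers and interspecific
divergence spans ≈ 0.7–10% from the slowest to the fastest marker.

What the simulator does **not** model: indels and alignment error (sequences
are emitted pre-aligned), within-species coalescent genealogies and shared
polymorphism, recombination, base-composition heterogeneity, rate variation
across sites, and paralogy. Passing tests therefore demonstrate correctness
of the statistics and the qualitative marker-rate structure, not robustness
to alignment artifacts or incomplete lineage sorting in real data.

## Pipeline and reproducibility

`evaluate_all` runs every marker and declared combination (complete-case
concatenation by default; `pad_missing` fills absent markers with `?`).
Outgroup samples are excluded from distance-based statistics and BM/BCM but
retained in trees for rooting semantics. One master seed drives everything;
per-unit bootstrap seeds are derived as `(seed·1000003 + crc32(name)) mod 2³¹`,
so bundles are byte-identical across reruns. The structured log reports the
silent-exclusion counts (undefined pairs, dropped samples, dropped
replicates) where such analyses typically diverge between implementations.

ITS2-style subregions are cut with explicit half-open 0-based coordinates
(`slice_subregion`); no annotation heuristic is attempted, since boundary
inference is a separate problem with its own error modes.

## Known limitations

- K2P saturation makes distant outgroups fragile on very fast markers; the
  undefined-pair machinery handles it, but heavily saturated datasets will
  see samples dropped from trees.
- BM/BCM tie detection uses exact float equality; ties are intended to
  arise from identical sequences (exactly equal distances), not from
  near-equal distances.
- The local-gap and monophyly denominators count species evaluable in the
  given matrix; markers with missing samples can have different denominators
  for the same nominal species set (the reports print both numbers).
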