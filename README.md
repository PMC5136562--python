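# barcodegap

Evaluation of DNA barcode markers for species discrimination in recently
radiated plant genera — the situation where barcoding is hardest: low
interspecific divergence, intraspecific variation that overlaps it, and
cryptic species complexes.

Given per-marker multiple sequence alignments whose headers carry species
labels (`>Genus_species|sample_id`), the package applies the three standard
evaluation methods, per marker and for multi-locus combinations:

1. **Pairwise-distance method.** Kimura 2-parameter (K2P) distances with
   pairwise deletion; with transition fraction *P* and transversion fraction
   *Q* over comparable sites,

   *d* = −½ ln(1 − 2*P* − *Q*) − ¼ ln(1 − 2*Q*).

   From the distance matrix it computes the six divergence parameters
   (pooled average intra- and inter-specific distance, theta Θ, theta prime
   Θ′, coalescent depth, smallest interspecific distance), the global
   barcoding-gap overlap of the intra/inter distance distributions, and the
   per-species **local gap** criterion: a species is discriminated when its
   minimum interspecific distance is strictly larger than its maximum
   intraspecific distance.
2. **Sequence-similarity method.** Best Match (BM) and Best Close Match
   (BCM) identification tests: each query from a multi-individual species is
   assigned by the species of all tied nearest neighbors
   (correct / ambiguous / incorrect); under BCM, queries whose best distance
   exceeds the 95th percentile of intraspecific distances are unidentified.
3. **Tree-based method.** Neighbor-joining trees from the K2P matrix with
   nonparametric bootstrap; a species is resolved when its individuals form
   a monophyletic group with support above a threshold (default 70%).

A synthetic radiation simulator generates multi-marker test data with
controllable stem and intraspecific divergence, per-marker rate multipliers,
cryptic pairs, singleton species and an outgroup, plus the ground-truth
table — so every statistic can be validated against known structure.

## Worked example

Simulate a 40-species radiation with four markers spanning a 1:3:5:12 rate
spectrum (slow plastid-like through fast nuclear-spacer-like), then evaluate
every marker and two combinations:

```sh
barcodegap simulate --out sim --seed 1
barcodegap evaluate \
    --markers rbcL_like=sim/rbcL_like.fasta --markers matK_like=sim/matK_like.fasta \
    --markers trnH_psbA_like=sim/trnH_psbA_like.fasta --markers ITS_like=sim/ITS_like.fasta \
    --combine rbcL_like+ITS_like --combine rbcL_like+matK_like \
    --outgroup og_i1 --bootstrap-reps 200 --seed 1 --out eval
barcodegap report --bundle eval
```

Typical cross-method resolution for this seed (percent of the 27 evaluated
multi-individual species, or of the 103 evaluated queries for BM/BCM):

| unit                 | local gap | BM correct | monophyly | avg intra | avg inter |
|----------------------|-----------|------------|-----------|-----------|-----------|
| rbcL_like            | 14.81     | 60.19      | 29.63     | 0.30%     | 0.75%     |
| matK_like            | 37.04     | 68.93      | 44.44     | 0.29%     | 2.12%     |
| trnH_psbA_like       | 40.74     | 69.90      | 51.85     | 0.31%     | 3.39%     |
| ITS_like             | 62.96     | 87.38      | 66.67     | 0.27%     | 7.05%     |
| rbcL_like+matK_like  | 40.74     | 76.70      | 51.85     | 0.30%     | 1.30%     |
| rbcL_like+ITS_like   | 51.85     | 87.38      | 70.37     | 0.29%     | 3.27%     |

The pattern to read off: resolution rises with marker rate; the slow
plastid-like marker fails most species (including every cryptic pair,
which no marker can split); combinations containing the fast marker perform
about as well as that marker alone. This is exactly the qualitative
structure reported for real radiations, where plastid barcodes lag nuclear
ITS/ITS2 and the core two-locus plastid barcode underperforms within genera.

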