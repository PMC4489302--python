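# Methods

## Model

`rlfscan` predicts R-loop forming sequences (RLFS) from primary sequence
using a structural grammar on the non-template (R-loop-forming) strand:
an initiation zone (RIZ) of clustered G-tracts, an unconstrained linker,
and a long G-rich elongation zone (REZ). Two RIZ variants are supported:
*m1* (>= 3 tracts of >= 3 contiguous G) and *m2* (>= 2 tracts of >= 4
contiguous G), reflecting the in-vitro observation that two longer G-clusters
suffice to nucleate a hybrid. The grammar is purely compositional: no
thermodynamics, supercoiling, chromatin or transcription-unit context enters
the model, and predictions are therefore cell-type independent.

Assumptions worth keeping in mind when interpreting output:

* R-loop initiation is strand-specific; the scanner treats the two strands
  independently (the minus strand is the reverse complement) and, by
  default, clusters predictions per strand.
* The REZ "supports elongation" in the model purely by G density; a REZ may
  contain further G-clusters without penalty, and nested predictions
  (a second RIZ inside a REZ) are legitimate and retained.
* N bases are permitted anywhere but never count as G and never extend a
  G-tract; RNA input (U) is folded onto T during normalization.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_tract_m1` / `min_tract_m2` | 3 / 4 | minimum contiguous G per tract (n1, n2) |
| `min_clusters_m1` / `min_clusters_m2` | 3 / 2 | minimum tract count per RIZ |
| `gap_min`..`gap_max` | 1..10 nt | spacer length between consecutive tracts |
| `linker_min`..`linker_max` | 0..50 nt | RIZ-to-REZ linker length |
| `rez_min`..`rez_max` | 100..2000 nt | REZ window length |
| `riz_g_min` | 0.50 | minimum RIZ guanine fraction |
| `rez_g_min` | 0.40 | minimum REZ guanine fraction |

These defaults *are* the model; changing them redefines what counts as an
RLFS. They are exposed (library, CLI flags, config file) because parameter
sensitivity analysis is a legitimate use, not because other values are
recommended.

## Algorithm and numerical choices

**RIZ enumeration.** Maximal G-runs are computed once per strand; runs of at
least the model's tract length are tracts, shorter runs are ordinary spacer
content. Tracts are chained left-greedily while the inter-tract distance
stays within `[gap_min, gap_max]`; each chain is a maximal match (extending
it in either direction is impossible by construction), its cluster count is
the number of tracts it contains, and chains failing the cluster count or
the RIZ G-content threshold are discarded. Two consequences of this
enumeration: matches never overlap, and a merged run of G (e.g. two tracts
with no spacer) is a single longer tract — a zero-length gap is not a gap.

**REZ search.** For each RIZ end, every linker length and window length is
considered; windows are scored by exact integer G counts over a prefix-sum
array, so no floating-point accumulation occurs. The scan walks windows from
the longest candidate downward and stops early once no remaining window
could beat the current best, which preserves exact longest-REZ semantics.
Ties among equally long windows are broken toward the smallest linker
(the most compact RLFS); at a fixed linker the window start is fixed, so no
further tie-break is needed. `rez_max` is silently truncated to the
remaining sequence length. G fractions are compared with `>=` on
correctly-rounded quotients, so a window at exactly the threshold (40 G in
100 nt) passes and 39/100 fails; threshold sharpness is asserted in the
test suite.

**Cross-model deduplication.** Both models run independently; records with
identical RIZ and REZ intervals on the same strand are reported once, keeping
the *m1* label, since *m2* is intended as a sensitivity extension that adds
loci rather than relabelling them.

**Coordinates.** All internal intervals are 0-based half-open; minus-strand
hits are mirrored into forward-strand coordinates at assembly. Conversions
to other conventions (1-based inclusive browser coordinates) happen only at
the input boundary (`GenomicInterval.from_one_based_inclusive`, the
`--chrom-start` anchor). Anchoring onto a minus-strand region mirrors
intervals within the anchored span and flips record strands.

**Clustering, overlap, metrics.** Clusters are connected components of the
>= 1-shared-base overlap graph, computed by a sweep over start-sorted
records per sequence and strand (a flag enables strand-blind clustering);
components of size 1 are not clusters. Region-overlap evaluation counts a
reference interval as hit when any prediction shares at least one base,
ignoring strand, because experimental hybrid-region assays are
strand-agnostic. Sensitivity, specificity and accuracy come from the
standard confusion-table formulas; a zero denominator yields NaN rather
than zero. CLI percentages are rounded to the nearest integer; full
precision is printed alongside and kept in machine-readable output.

**Negative-region sampling.** Specificity at genome scale is estimated by
sampling region sets that avoid all reference signal: lengths are drawn with
replacement from the reference set's empirical length distribution,
chromosomes are chosen with probability proportional to feasible placement
space, and placements intersecting an exclusion are rejected (up to 10,000
attempts per region, then a hard error naming the replicate). Sampling is
driven by a single integer seed and is fully reproducible.

## Synthetic data

The `fixtures` module generates the data used by the test suite and the
acceptance script.

*Backgrounds* are random A/T/G/C strings with two deterministic guarantees,
applied symmetrically to G and C so that both strands are covered: no run of
3 or more identical G/C, and every 100-nt window stays strictly below the
REZ G-content threshold. Neither model can fire anywhere in a background,
so any record found on a planted sequence is attributable to the construct.

*Planted constructs* instantiate the grammar exactly: specified tract and
gap lengths, an A/T linker, and a REZ with `round(target * length)` guanines
at random positions. When the linker is short enough (<= `gap_max`) that a
leading REZ tract could chain onto the RIZ, the first `gap_max + 1` REZ
positions are kept G-free so the planted RIZ boundary is stable. Recovery
is asserted by containment (the found RIZ contains the planted RIZ) and
overlap, not equality, because the scanner may legitimately absorb adjacent
background guanines into an edge tract or extend a REZ into flanking
sequence while the window still clears the threshold.

What the synthetic data does **not** emulate: repeat structure, CpG islands,
isochore-scale composition gradients, and realistic gene context. Passing
the planted-recovery suite demonstrates that the scanner implements the
grammar correctly; it says nothing about how often the grammar fires on real
genomes or about biological true-positive rates, which is why the curated
22-locus call table and the region-overlap protocol exist separately.

## Verification strategy

The scanner is cross-validated against an independent brute-force oracle
(exhaustive substring enumeration with a direct grammar check and
containment-based maximality for the RIZ; exhaustive linker x window
enumeration for the REZ) on hundreds of random sequences up to 600 nt, with
zero tolerated discrepancies. Problem sizes in the default test run — 500
oracle sequences, 100 random planted constructs, a 60 kb synthetic
chromosome with 12 planted regions and 100 resampling replicates — were
chosen to exercise every code path at desk scale while keeping the suite
fast; the same operations run unchanged on chromosome-scale input.

## Known limitations

* The model is compositional only; AT-rich R-loops or structures stabilized
  by negative supercoiling are invisible to it.
* The longest-REZ rule reports one record per RIZ; alternative shorter
  elongation zones are not enumerated.
* Genome-wide figures (RefSeq gene positivity, DRIP-seq region overlap on
  hg19) require external reference data and are not reproduced by the
  bundled test data; the operations that compute them are fully implemented
  and exercised on synthetic chromosomes instead.
* The worked-example locus (hg19 chr8:128748315–128753680, the MYC gene)
  needs a one-time reference-genome fetch; the corresponding end-to-end test
  fails without network access.
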