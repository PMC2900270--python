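# Methods

## Scope and model

`fpmap` models the desk-side half of a BAC physical-mapping project on a
single chromosome arm: restriction-fingerprint contig assembly on a
marker-targeted clone subset, anchoring of contigs to genetic maps,
recombination-rate profiling, and segment-scale comparative analysis
against related genomes. The wet-lab half (probe design, hybridisation,
library construction, BLAST searches against genome releases) is out of
scope; its outputs enter as plain-text tables.

All coordinates are 0-based, half-open, on one chromosome; strands are
±1. Every simulator draws from one `numpy.random.Generator` seeded per
call; identical inputs and seed give identical outputs, and the pipeline
writes a manifest with a config hash and per-file checksums so a run can
be verified byte-for-byte.

## Synthetic chromosome and library

`simulate_genome` places restriction sites as a homogeneous Poisson
process and genes in clustered "islands" (uniform island centres, genes
uniform within a 150 kb window), emulating the gene-island organisation of
Triticeae chromosomes. The recombination landscape is a piecewise-constant
coefficient-of-exchange profile that must tile the chromosome exactly; the
default study profile drops from 2.19 cM/Mb (distal) through 1.42
(middle) to 0.09 (proximal), the gradient characteristic of Triticeae
chromosome arms. BAC clones (`simulate_bac_library`) have uniform start
positions and uniform insert lengths in 100–200 kb; clones running off the
end are redrawn, so coverage near the termini is slightly depressed, as in
real libraries.

`simulate_genetic_map` offers two modes. `expected` integrates the CE
profile between markers — deterministic, used wherever exactness matters.
`f2` emulates an F2 mapping population of *n* individuals: each
adjacent-marker distance *d* cM becomes a recombinant fraction *r* =
*d*/100 (identity mapping function; the intervals of interest are a few cM
at most, where Haldane/Kosambi corrections are negligible), recombinant
counts are Binomial(*n*, *r*), and distances are re-estimated from the
counts. Default *n* = 2000, giving ≈0.17 cM standard error on a 0.66 cM
interval — the resolution regime of a well-sized F2 population.

What the generator does **not** emulate: chimeric or contaminated clones,
repeat-induced false fingerprint overlaps, segregation distortion,
missing genotype data, and multi-enzyme HICF chemistry. Passing tests
therefore demonstrate correctness of the algorithms under clean
assumptions, not robustness to every artefact of real fingerprint data.

## Fingerprints, band matching and the Sulston score

A clone's fingerprint is the multiset of its restriction-fragment sizes —
the spans between consecutive sites inside the insert plus the two end
fragments, so a site-free clone still yields one band and fragment lengths
sum exactly to the insert length at zero noise. Sizes map to integer
migration units (bp/10, rounded, minimum 1) before Gaussian noise of a
configurable SD (in the same units) is added.

Band matching is the maximum one-to-one matching with |b₁ − b₂| ≤ t,
computed by a two-pointer sweep over sorted band lists (which attains the
maximum for interval-compatibility graphs; an exhaustive assignment-based
oracle backs this in the tests). The coincidence score is the classic
binomial tail: with band counts n_L ≤ n_H and m matches,
score = P(X ≥ m), X ~ Bin(n_L, p), p = 1 − (1 − 2t/G)^{n_H}.

Two numerical caveats are deliberate and documented rather than hidden:

* **The score is an approximation.** Its independence assumption ignores
  competition among bands for partners. Under the model's own
  assumptions (band positions continuous-uniform on G), the prediction is
  essentially exact for P(≥1 chance match) and overestimates deeper tails
  by up to ~1.5 percentage points for 30-band clones at t=3, G=3000; a
  Monte-Carlo test bounds the error.
* **Tolerance must respect the band-size distribution.** Poisson sites
  give exponential fragment sizes, which crowd the small end of the gel;
  at t=3 the uniform-position model badly understates chance coincidence
  for band-rich fingerprints, eroding the score's discrimination. With
  noise-free synthetic bands the tolerance only needs to absorb rounding,
  so simulation fixtures and the pipeline default use t=1, under which
  unrelated clones essentially never reach the 10⁻¹² cutoff while ≥50 kb
  overlaps essentially always do. The `AssemblyParams` defaults (t=3,
  G=3000, cutoff=10⁻¹², min_shared_bands=1) remain the conventional
  settings for noisy data.

## Contig assembly and consensus bands

Clone pairs passing the score cutoff and a minimum shared-band count form
edges; contigs are connected components, merged in ascending-score order
purely so the clustering trace is reproducible (the partition itself is
order-independent). Contig ids are assigned by descending clone count,
then lexicographically smallest member id. Targeted re-assembly — the
guard against genome-wide false joins — takes the union of all clones of
any initial contig containing a marker-positive clone, plus positive
singletons, and re-runs assembly on that subset only.

Contig size is counted in consensus-band (CB) units: bands pooled across
the contig's clones, merged by single linkage (sorted values chain while
consecutive gaps ≤ t), classes counted. This is a stated proxy for the CB
map a full FPC implementation maintains, exact when distinct fragments
are separated by more than the tolerance and increasingly an undercount as
band density rises (single-linkage chains neighbouring classes). kb sizes
are CB × a library-average kb-per-CB factor: 1.9 kb/CB for the published
library whose table arithmetic the package reproduces, 4.0 kb/CB for the
synthetic library (its mean fragment spacing), always a parameter and
never hard-coded.

Q-clone/DQ handling, end-merging and minimum-tiling-path selection from
FPC are intentionally not reproduced.

## Anchoring, ordering, islands, summaries

A contig anchors to a map position only when (a) one of its clones is
positive for a marker, (b) the marker is on the map, and (c) the marker's
genotype source equals the BAC-library genotype — the same-genotype rule
that makes a hybridisation phenotype on the library comparable to a map
genotype. The underlying band-pattern comparison is not modelled;
genotype-source equality plus positive-clone membership operationalises
it. A marker mapped at two positions in one map is an error.

Ordering uses a configurable evidence-priority hierarchy (own genetic map
first, then e.g. a reference physical map, a related-species genetic map,
model-genome gene order). Each contig is placed by its highest-priority
source; contigs tied on their placing source are interleaved by the next
source that covers them all, otherwise left as an explicit tie group —
ties are never silently broken. Evidence-free contigs are emitted last as
"unplaced".

Gene islands are connected components of the gene–clone bipartite graph
within a contig, counting only gene-class (EST-unigene) markers; two genes
share an island iff a chain of co-positive clones links them. Summary
tables report totals, per-contig averages, minima and maxima with the
print conventions of published map tables: clone and kb averages rounded
half-up to integers, CB to one decimal, and the loci average truncated to
one decimal.

## Recombination metrics

CE = cM/(kb/1000), reported at two decimals (half-up). Marker intervals
resolve their kb distance from within-contig CB spans or, across contig
runs, from the sum of contig sizes neglecting gaps; such composite
distances carry an explicit lower-bound flag and their CE is labelled an
overestimate. `estimate_true_size` inverts CE: genetic length divided by a
reference rate gives the expected physical size, and the shortfall of the
assembled size is the map's gap fraction. The choice of reference rate is
exposed as a parameter because published region-size figures depend on
it; dividing a 49.9 cM region by the 0.87 cM/Mb wheat maximum gives
57.4 Mb, while tripling the observed 21.3 Mb span (the "rate is about
triple" reading) gives ~64 Mb — the function reports the formula's result
for whatever reference the caller supplies rather than asserting any one
published figure. Fold increases between genomes are reported both as the
unrounded ratio and rounded half-up to an integer.

## Synteny and rearrangement scenarios

Ortholog hits are filtered per species with inclusive E-value cutoffs
(defaults 10⁻¹⁰ for rice/Brachypodium-style sequence references, 10⁻²⁰
for barley-style unigene references), keeping the single best hit per
(marker, species), ties broken by reference gene id. Projection lists the
ordered map's markers with their reference positions; block detection
partitions the projection into maximal monotone runs (ties in reference
position are order-preserving; a configurable reference gap limit,
default ∞, can additionally split runs). At a direction conflict the
boundary marker joins the side with the smaller reference gap (ties to
the left), which recovers an embedded reversal with its exact extent; runs
shorter than two markers go to an unassigned set, so a reversal flanked by
a single collinear marker leaves that marker unassigned rather than in a
spurious block. Every descending block yields one inversion call with its
map span and reference interval.

Reversal distances on signed permutations are computed exactly by
breadth-first search from the identity, guarded at n ≤ 8 segments (the
scenario scale; no Hannenhalli–Pevzner machinery is warranted). Scenario
evaluation is consistency checking, not inference: a scenario (per-lineage
reversal lists over a shared ancestral segment order) predicts each
segment's relative orientation for every lineage pair, and the prediction
is compared against an observed table of collinear/inverted/unknown calls,
with "unknown" always consistent. Where observations admit several
minimal scenarios — e.g. a distal discrepancy explainable as either an
inversion or a translocation — the package reports each candidate's
consistency and never selects one. A bounded exhaustive search
(`search_scenarios`, ≤2 reversals per lineage, ≤6 segments) enumerates
consistent scenarios for small cases.

## Problem sizes and tolerances in the test and acceptance suites

The suites run on deliberately small instances: a 6 Mb gradient
chromosome with markers every 300 kb; a 50-clone tiling path (120 kb
clones, 20 kb stagger) on 1.2 Mb; a 100-clone ≈5× library on 3 Mb; 10⁵
Monte-Carlo trials for the score check; all 442 signed permutations of
n ≤ 4 for the reversal-distance oracle. Stochastic recoveries are asserted
within 3 standard errors of their sampling distribution (binomial SE for
F2 distances and Monte-Carlo proportions); deterministic recoveries
(expected-mode CE, tiling components, inversion intervals, scenario
consistency) are asserted exactly.

## Known limitations

* The CB proxy undercounts at high band density (single-linkage chaining).
* The Sulston score's calibration degrades when band values are far from
  uniform; tolerance must be chosen with the noise level and band density
  in mind.
* Block detection assumes one reference chromosome per species;
  translocations across reference chromosomes are out of scope.
* F2 map simulation models recombinant fractions only — no interference,
  no dominance/missing-data patterns.
* The scenario machinery treats segments as atomic; nested rearrangements
  below segment resolution are invisible.
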