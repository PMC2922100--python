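# Methods

This note documents the models, parameter choices and numerical conventions
behind `crmscan`, and what the synthetic benchmarks do and do not establish.

## PWM scoring model

A motif is an `L×4` count matrix. Two frequency views are kept:

* **Raw frequencies** `f(i,b) = c(i,b) / Σ_b c(i,b)` feed the conservation
  (information) vector `Ci = (100/ln 4)·(ln 4 + Σ_b f·ln f)`. `Ci` is pinned
  to exactly 100 for single-base rows and strictly below 100 otherwise, so
  "fully conserved" is a crisp predicate.
* **Scoring frequencies** add a small pseudocount (`1e-4` of the row total
  per cell) so that no window can score exactly 0; scores therefore live in
  `(0, 1]`, with 1 attained precisely on argmax-base (consensus) windows.

The similarity of a window `s` is `Σ_i Ci·f(i,s_i) / Σ_i Ci·max_b f(i,b)` —
mismatches at conserved positions are expensive, mismatches at degenerate
positions are nearly free. The **core** is the 4 consecutive positions with
maximal summed `Ci` (ties: leftmost; matrices shorter than 4 use their whole
length). Core similarity is the same ratio restricted to core positions and
acts as a cheap first-pass filter at 0.75.

Windows containing any non-ACGT character are skipped rather than scored:
there is no defensible frequency for `N`, and partial scoring would break
the consensus-iff-1 property. Both strands are always scanned; a minus-strand
hit is reported at its forward-coordinate leftmost base, which makes
`scan(revcomp(seq))` an exact mirror of `scan(seq)` (a property test).

## Optimized thresholds

Published per-matrix cut-offs for this scoring family are tool-internal, so
the package defines them operationally: the smallest threshold on a 0.01
grid (0.50–1.00) at which a seeded i.i.d. background of 100 kb (GC 0.41)
yields at most `target_rate` retained matches per 10 kb (default 3), with
the core cut applied. The calibration is deterministic given its seed, and a
rate unreachable even at 1.00 is flagged rather than silently clamped.
Because motif scores on background are lumpy (they cluster by mismatch
count), the realized background rate at the chosen threshold is typically
well below the target — the target is a ceiling, not an expectation.

## Module discovery

Candidate families are those with at least one retained hit in every
species (family-level by default; a matrix-level strict mode exists).
Anchor sites are ranked lexicographically by matrix similarity, then core
similarity, then distance to the TSS (the ranking the anchor-selection rule
implies but does not fully specify); the top 3 (plus ties) seed windows.

The search enumerates hit-bounded intervals: every window that matters has a
member hit on each edge, so the `O(n²)` start/end pairs (deduplicated by
tight hull) cover all distinct member sets of span ≤ 1000 bp. Per interval
the covered family set is recorded; the reported module is the largest
family set `S` containing the anchor such that every species has an anchored
interval covering `S`, found by iterating subsets of a pre-filtered viable
family set in decreasing size (pairs `{anchor, f}` coverable in all species).
Ties between equal-sized sets resolve to the lexicographically smallest
family tuple; per-species windows then minimize span, then start coordinate.
These tie-breaks are arbitrary but fixed, making output files byte-stable.

`min_families` defaults to 2 (anchor + one partner): the method is a
detector, and the statistics module — not the window search — judges whether
a small module is surprising. The all-species conservation requirement is
strict by default; `min_species_fraction` can relax it, off by default.

## Clustering statistic

For each module family: `k` member sites summed over species are compared
with `Binomial(2·L_eff, p_bg)`, where `L_eff = Σ_species (span − L + 1)` is
the number of scorable positions in the windows, the factor 2 counts both
strands, and `p_bg` is the empirical retained-hit rate per strand-window on
100 kb of seeded background at the family's calibrated threshold. The tail
`P(X ≥ k)` uses `scipy.stats.binom.sf`; `k = 0` returns exactly 1. A null
calibration test (200 unplanted windows) checks the p-values are
conservative at the 0.05 level. This statistic is this package's own,
defined because commonly quoted module p-values come from unpublished
methods and cannot be reproduced; no multiple-testing correction is applied
by default (a Bonferroni flag exists — six families hardly need more).

## Synthetic benchmark: what it emulates

The generator's defaults are the benchmark conditions, chosen once:

* **Matrices**: one matrix per family (configurable), lengths 11–14 bp,
  dominant-base frequency 0.85 with one uninformative position — the shape
  of curated vertebrate matrix libraries, and long enough that a calibrated
  threshold separates one-substitution sites from background. Six true
  families (NEUR, HNF1, HNF6, BRNF, PDX1, LEFF) plus 4 decoy families.
* **Regions**: 5000 bp (4500 up / 500 down), i.i.d. background at GC 0.41
  (vertebrate-like). A first-order Markov background is deliberately not the
  default: i.i.d. keeps the analytic hit-rate calibration interpretable.
* **Planting**: one instance per true family per species, non-overlapping
  (rejection sampling, 10 000 attempts before a named error), random strand
  and order, inside one window of span ≤ 800 bp whose TSS-proximal edge sits
  1000–3000 bp upstream (drawn per species). One random substitution per
  site, applied to non-core positions first — mirroring that real sites pass
  the core filter while degenerating elsewhere.
* **Decoys**: planted per species with probability 0.6 and forced absent
  from at least one species, so the common-family filter is load-bearing;
  scattered uniformly outside the module window.
* **Controls**: `no_anchor` co-localizes the five non-anchor families but
  contains no anchor site anywhere; `scattered` plants all six families with
  the anchor > 1000 bp from every other family's site in every species.
  All-pairwise scattering of six sites at > 1000 bp is geometrically
  impossible in 4500 bp of upstream sequence; anchor isolation is the
  property that actually forbids an anchored module call.
* **Proteomes**: star phylogeny, 20 families of 150–450 aa, per-site
  substitution at the requested divergence; duplicated families carry an
  in-paralog at 3× that rate so the true ortholog is unambiguously closer.

What passing these benchmarks does **not** show: robustness to indels or
repeat/CpG structure in promoters (not simulated), to phylogenetically
correlated divergence (star phylogeny only), to alternative promoters or
TSS mis-annotation (the TSS is taken as given), or to matrix libraries whose
families overlap heavily. Results on real genomes depend on the matrix
library and TSS annotations supplied by the caller.

## Problem sizes and determinism

Benchmark suites use 20 positive sets and 50 control sets of 8 species,
100 kb calibration backgrounds, and 20-seed proteome batches — sizes at
which the full suite runs in well under a minute while estimating the
recovery and false-call rates to a few percent. Every stochastic component
takes one integer seed and flows through a single `numpy` generator per
call; pipeline stages derive disjoint seeds (+1000 calibration, +2000
statistics) from the run seed so stages can be re-run independently with
identical results. Scan outputs round similarities to 6 decimals in the TSV
interchange format, and the pipeline re-reads its own TSV before module
detection so that stage-wise and end-to-end runs agree bit for bit.

## Known limitations

* RBBH scoring is exact Smith–Waterman; at genome-proteome scale (tens of
  thousands of sequences) a seeded search tool should replace it. The gap
  model is declared (gap of length k costs `11 + k`), not inferred from any
  particular search tool's defaults.
* Anchor selection keeps the top 3 sites per species; a module whose only
  valid anchor ranks fourth would be missed (raise `top_k_anchors`).
* The subset search over common families is exponential in the worst case;
  the viability pre-filter keeps it trivial at realistic family counts, but
  pathological libraries with dozens of mutually common families would need
  a smarter search.
* Reported windows are tight hulls of member hits; a chance background hit
  of a member family near the planted cluster can shift a window edge while
  leaving the family set intact.
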