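# Methods

This note documents the models, parameter choices and numerical conventions
behind `pointcen`, and what the synthetic data do and do not establish.

## Coordinate conventions

All internal coordinates are 0-based half-open. Two boundaries convert:
GFF3 output is 1-based inclusive, and columns *within* a centromere window are
numbered 1-based inclusive, so that element positions read naturally as
"positions 20–26" and mutation names as `21-23a`.

## The centromere window model

A centromere window is generated column by column from a
`CentromereModel` (defaults in parentheses):

* `window_length` (110) with a conserved core `core_start..core_end` (20–89);
* two consensus elements, NaCDEI = `SGGKTAA` at columns 20–26 and NaCDEII =
  `ACGDDWWT` at 45–52. Each element column draws a *dominant* base — the
  alphabetically first base of its IUPAC set — with probability
  `element_dominance` (0.995), and spreads the rest uniformly over the
  remaining allowed bases. Every sampled element therefore matches its
  pattern by construction, while across a set of ten sequences each column is
  identical in ~10/10 or 9/10 of them, the conservation level the
  classification rules are designed to detect;
* designated strict-A/T columns (`at_only_columns`) and strict-G/C columns
  (`gc_rich_columns`) scattered through the core, emulating the A+T-only and
  GC-rich positions of the real consensus. Columns 87–89 are strict-A/T,
  anchoring the right edge of the core span;
* uniform-composition columns (`neutral_columns`, 19/27/44/53) immediately
  adjacent to the elements. Uniform composition minimises the probability
  that a non-element column reaches 80% conservation by chance
  (~0.17%/column at n=10), which would otherwise extend an element run;
* all remaining core columns are Bernoulli A/T-vs-G/C spacers
  (`spacer_at_fraction`, 0.7; uniform within each class), and flank columns
  likewise (`flank_at_fraction`, 0.7).

Why the flanks are 0.7 and not higher: with ten independent sequences, a
column drawn A/T with probability q is *all* A/T in q^10 of columns — 20% of
columns at q = 0.85 but 2.8% at q = 0.7. Since the A+T-only class is part of
the core definition, very AT-heavy flanks would routinely extend the
classified core past the planted boundary; 0.7 keeps the flanks AT-rich while
keeping chance-classified flank columns rare.

A `ConventionalCenModel` covers the conventional point-centromere arm of the
generator. Only the CDEII constraint is built in: spacer length uniform on
70–170 bp and AT content strictly greater than `cdeII_min_at` (0.79),
enforced constructively (bases drawn at 90% A/T; the rare draw at or below
the bound is rejected and resampled). CDEI/CDEIII consensus strings are
configuration-supplied, with no baked-in default.

## Genome, annotation and coverage simulation

Chromosomes (default 10 × 300 kb) alternate 500-bp intergenic intervals and
1.5-kb genes on alternating strands over a 60%-AT background. One centromere
window is planted in the intergenic interval nearest each chromosome
midpoint; per-factor secondary sites (defaults 0/1/2/6 for
Ndc80/Cse4/Ndc10/Cep3, the extra-peak counts the analysis must recover) go to
intergenic midpoints at least 50 kb from every centromere.

Coverage is binned (50 bp) negative-binomial counts, var = m + αm² with
dispersion α = 0.02 (overdispersed relative to Poisson, as ChIP input
typically is). The chip mean is `background_mean · (1 + (peak_fold−1) · a ·
G(d))` summed over planted sites, with a Gaussian kernel G of width
`peak_sd` = 150 bp, amplitude a = 1 at centromeres and a =
`secondary_rel_amplitude` = 0.15 at secondary sites. With `peak_fold` = 12
this puts centromeres at ~12-fold and secondary sites at ~2.7-fold
enrichment — two clearly separated tiers. Randomness flows from one root
seed through named child streams (per chromosome, per factor), so adding a
chromosome or factor leaves all other draws unchanged.

## Peak calling

Enrichment is the pseudocounted ratio (chip+1)/(input+1) smoothed by a 5-bin
centered moving average; no further library-size scaling is applied (a
documented limitation — depth differences cancel in the ratio, composition
biases do not). Candidate peaks are maximal runs of bins strictly above
`secondary_threshold` (1.8) × the genome-wide **median** enrichment — a robust
baseline when enriched bins are a tiny minority — merged across gaps of ≤2
bins and dropped below 3 bins wide. A peak is *primary* when its maximum
smoothed enrichment reaches `primary_threshold` (4.0) × median. The
thresholds bracket the simulated secondary tier (~2.7-fold) with ≥1-fold of
headroom on each side so that tier assignment is not decided by noise.
Summit ties break leftmost; intergenic status is decided by the summit alone
(the biology localises these centromeres to intergenic points, and summits
are far better determined than peak edges).

## Ungapped alignment and consensus annotation

Point-centromere elements sit at fixed spacing, so candidates are aligned
without gaps: one integer offset per sequence, maximising the
column-consensus score Σ_c max_b n_b(c). When the product of offset choices
is ≤10⁶ the optimum is found by exhaustive enumeration (lexicographically
smallest offsets win ties). Otherwise a deterministic multi-restart
refinement runs: one centered start plus one start anchored on each
sequence's centered window, each refined by align-to-profile coordinate
ascent *plus a global-shift move* — the score is invariant-shaped along the
"translate everything together" ridge, which single-sequence moves cannot
cross — keeping the best-scoring result. Note the de-novo alignment frame is
defined only up to translation; element geometry (widths and spacing), not
absolute column numbers, is the meaningful output when candidates are longer
than the window.

Columns of the PFM are classified with precedence
invariant > high > at_only > gc_rich:

* invariant: one base in 100% of sequences;
* high: one base in 80–90% (inclusive at both ends; with n=10 exactly 8 or 9);
* at_only: G and C counts both zero;
* gc_rich: (G+C)/n ≥ 0.8.

Elements are maximal invariant/high runs of ≥`element_min_len` (5) columns —
long enough to exclude isolated chance-conserved columns, short enough to
keep a 7-column element. The degenerate consensus per column is the IUPAC
code of the bases with frequency ≥`include_min` (0.15; with n=10 a base needs
two occurrences, suppressing singletons while recovering genuine two-fold
codes); an empty base set falls back to `N`. The core spans the first to the
last classified column, counting only classified columns in runs of
≥`core_min_run` (3): an isolated flank column that happens to be all-A/T in
ten sequences (a ~3% event per column) should not stretch the reported core.

## Motif scanning and mutations

Matching is set-aware: a window position is a mismatch when its base falls
outside the IUPAC code's set, so "one mismatch against `S`" is meaningful. A
sequence `N` matches only a pattern `N`. Long patterns (the 70-bp core) are
scanned by per-window set comparison, never by expansion. Reverse-strand
hits are found by scanning the reverse-complemented pattern on the forward
strand and are reported at the forward coordinate of the window start; all
overlapping hits are reported, and a palindromic locus yields one hit per
strand. Window mutations (`21-23a` style, hyphen or en-dash) replace an
inclusive 1-based column range by one base; they are idempotent and commute
when non-overlapping.

## Synteny classification

A centromere locus is its pair of immediately flanking genes. Against a
reference gene order and an ortholog map (≤2 partners per gene, the post-WGD
double mapping), the locus is *syntenic* when **some** ortholog of the left
flank and **some** ortholog of the right flank lie on one reference
chromosome with ≤`gap_tolerance` (5) intervening genes — existential
semantics over the ≤2×2 pairings, orientation-agnostic, since the underlying
argument is order-based, not strand-based. It is *breakpoint* when every
pairing violates this and *ambiguous* when a flank or its orthologs are
missing. The default tolerance of 5 lets small local rearrangements pass;
strict adjacency is `gap_tolerance=0`. The synthetic reference is built by
splitting all but one chromosome at the centromere-flanking adjacency and
reassembling the arms across chromosomes, so exactly one centromere pair
remains fully syntenic — the configuration the survey must report as
(1 syntenic-with-centromere, 9 breakpoint) on the ten-chromosome fixture.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure the analysis assumes*:
single dominant intergenic enrichment per chromosome, factor-specific weaker
extra sites, a conserved core with two near-invariant elements at fixed
spacing, AT-rich surroundings, and a rearrangement history with one conserved
centromere adjacency. It does **not** model read-level artifacts
(mappability, GC bias, duplicates, fragment-length effects), diploidy,
repeat structure, or any sequence evolution beyond per-column sampling.
Passing tests therefore demonstrate that the pipeline's inferences are
correct *given* these structural assumptions — they do not validate the
upstream wet-lab processing of real ChIP-seq data.

## Problem sizes and determinism

Default analyses run on 10 × 300 kb genomes (60 k bins/track), where the full
pipeline completes in a few seconds on one CPU. Property suites use 200–3000
randomized trials against brute-force oracles (exhaustive offset enumeration,
pattern-expansion scanning, explicit threshold scans, pairing enumeration),
all with fixed seeds; every simulation draws from `numpy.random.Generator`
streams derived from a single root seed, and identical configuration + seed
reproduces every artifact and report metric byte-for-byte (timestamps aside).

## Known limitations

* The enrichment ratio assumes chip and input share composition biases.
* The de-novo alignment frame is translation-free (see above); window-frame
  column numbers are only meaningful when candidates are the window itself.
* The uniqueness scan defaults to 0 mismatches; the match criterion for
  "found nowhere else" is configurable because the original claim's criterion
  is not stated.
* Ortholog inference and ancestral-genome reconstruction are out of scope;
  the synteny module consumes a given ortholog map and reference order.
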