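# Methods

## The problem

A ChIP-seq library is sequenced to a chosen depth, so the number of tags says
nothing about the absolute amount of immunoprecipitated chromatin. When a
treatment changes a histone modification *globally* — for example an EZH2
inhibitor depleting H3K27me3 across the genome — every locus loses signal by
roughly the same factor, library yields stay similar, and fixed-depth
sequencing followed by the conventional normalization (downsampling every
sample to the smallest library) reproduces near-identical tracks. The global
change is structurally invisible.

The remedy implemented here is an exogenous reference ("spike-in"): a constant
mass of reference-species chromatin (Drosophila, in the original design) is
added to every reaction together with an antibody against a reference-specific
histone variant (H2Av) that pulls down a constant amount of reference
chromatin regardless of the experimental antibody's target. After sequencing,
tags are partitioned by species. Because the reference pull-down is constant,
differences in reference-tag counts between samples measure exactly the
distortion introduced by fixed-depth sequencing, and the correction factor

    f_i = (reference-tag count of the designated reference sample)
          / (reference-tag count of sample i)

applied to sample i's experimental-species tags (by uniform random tag
removal) restores between-sample proportionality. Factors are rescaled so the
largest is 1, because scaling is realized by removal only.

### Reference-tag counting modes

`whole_genome` counts every reference-species tag. `restricted_regions`
counts only tags whose 5′ base lies inside the pre-defined reference
pull-down (H2Av-bound) intervals. The restricted mode matters when the
experimental antibody cross-reacts with reference chromatin: cross-reactive
pull-down grows as the experimental target is depleted (more free antibody),
inflating whole-genome reference counts in treated samples and corrupting the
factors. Tags pulled down cross-reactively land outside the H2Av intervals,
so restricted counting is insensitive to them. Membership by the 5′ base is a
deterministic proxy for aligning against a partial reference genome built
from those intervals only; it differs from true partial-reference alignment
at interval edges, which is negligible for kilobase-scale regions.

## Preprocessing

Applied identically to both species of every sample, in fixed order:

1. **MAPQ filter** — keep tags with mapping quality strictly greater than 25
   (a uniqueness proxy). Strictness matters: MAPQ 25 is excluded.
2. **Deduplication** — at most one tag per (chromosome, 5′ position, strand).
   PCR duplicates share the 5′ alignment coordinate, and single-end tags of
   one library have one length, so the 5′ position identifies the molecule.
   The filter order (MAPQ first) prevents a low-quality duplicate from
   shadowing a high-quality tag at the same key.
3. **Extension** — each tag is extended at its 3′ end to 200 bp, the average
   genomic fragment length, clipped at chromosome boundaries.
4. **Binning** — fragment coverage is accumulated into 32-bp bins as
   fractional overlap (fragment bp in bin ÷ bin bp), so total mass is
   conserved exactly: Σ(bin value × bin bp) = Σ fragment lengths. Midpoint
   assignment was deliberately not used; fractional overlap makes the
   conservation identity exact and testable to 1e-9.

At high local tag density, 5′-position deduplication saturates: the expected
number of distinct keys after n uniform draws over K = 2 × (region bp) keys is
K(1 − (1 − 1/K)^n) < n. At the desk scales used in the test suite this removes
several percent more tags from dense samples than sparse ones; the test
oracles account for it in closed form rather than pretending it away.

## Island calling

Broad-mark enrichment is detected SICER-style against a random background,
without a control library:

- The genome is tiled with non-overlapping windows of `window_width`
  (default 200 bp, the published default; the source protocol states only the
  gap and E-value). Each fragment is counted once, in the window holding its
  midpoint, giving a Poisson count model with background rate
  λ = n·w / (f_eff · G) (n tags, window w, effective genome fraction f_eff,
  genome length G).
- A window is *eligible* when its count k has Poisson upper-tail probability
  P(X ≥ k) < 0.2 (the conventional choice, configurable); its score is
  −ln P(k; λ).
- Runs of eligible windows separated by at most `gap` bp of ineligible
  windows form islands (gap must be a multiple of the window width; 600 bp
  for H3K27me3/H3K9me3, 200 bp for H3K4me3). Island score = Σ eligible-window
  scores.
- The score cutoff is set so that the expected number of islands reaching it
  on a pure random background equals the configured **E-value** (default 1).
  The expectation is estimated by seeded Monte Carlo: `null_mc_draws` null
  genomes are simulated by multinomial placement of n tags over the
  effective-genome windows, and the cutoff is the ⌈E·R⌉-th largest island
  score across the R null genomes. This replaces the original analytic
  recurrence with an estimator that is directly verifiable against
  brute-force simulation; bit-exact reproduction of the original tool is a
  non-goal.

Defaults: `null_mc_draws` = 10 000 for one-off calls. Pipeline configurations
in this repository use 500–2000 draws, which resolves the cutoff to well
under the margin by which genuine broad domains exceed it; the null
calibration test (mean called islands ≈ E-value over 50 background seeds)
passes at 2000 draws. `effective_genome_fraction` defaults to 0.74 (the
human-genome convention) and is set to 1.0 for synthetic genomes.

## Quantification

Peak regions are the union of island intervals across the conditions being
compared (merged, sorted, disjoint). Per region and sample, *average signal*
is fragment bp overlapping the region ÷ region bp — mean per-bp fragment
coverage, the same unit as the tracks. Fold-change summaries report the
median and quartiles of per-region ratios (control/treated orientation,
matching the correction-factor convention). Each side of the ratio receives a
pseudocount of 0.1 × that sample's genome-wide mean signal; scaling the prior
with the sample's depth (as count-based differential tools scale prior
counts by library size) leaves a uniform global fold change unshrunken,
whereas a shared pseudocount would bias it toward 1.

## The synthetic generator

`chipspike.simulate` draws complete two-species tag libraries with known
ground truth. Per sample, four compartments receive pull-down weights:

| compartment | control weight | treated weight |
|---|---|---|
| experimental domains | domain bp × enrichment | control / F |
| experimental background | background bp × 1 | control / F |
| reference pull-down (H2Av) regions | R (constant) | R |
| reference cross-reactive regions | 0 | κ · (1 − 1/F) · R |

R is set so the reference share of the control pull-down equals
`spike_fraction`. The treated experimental signal is the control's scaled by
1/F everywhere — a *uniform* global change, the regime the method targets.
Cross-reactive pull-down is linear in the depleted target fraction
(κ · (1 − 1/F)), the simplest monotone model of free-antibody excess; κ
expresses it as a multiple of the H2Av pull-down at full depletion.

Exactly N tags are then drawn multinomially over the compartments and placed
uniformly within each compartment (strand uniform, fixed MAPQ 60, 50-bp
tags). Drawing a *fixed* total is the point: it reproduces the masking
mechanism structurally, not incidentally. With fixed depth, cross-reactive
material dilutes H2Av and experimental tags by the same factor, so
restricted-count factors remain unbiased for the factor that recovers F — the
generator-side mirror of the whole-genome/restricted asymmetry.

Defaults (the desk-scale study conditions): experimental genome 4 × 1 Mb;
reference genome 2 × 100 kb; 60 domains with widths drawn from 2–20 kb and
rescaled to cover 25% of the experimental genome; 40 reference pull-down
regions and 20 cross-reactive regions of 1–3 kb, placed jointly so they are
disjoint; enrichment 10-fold over background (a typical broad-mark contrast);
F = 4; `spike_fraction` 0.05 (the original design targeted a reference yield
of roughly 2–4% of total tags); κ = 0; N = 200 000 tags per sample. Optional
flags inject PCR duplicates and low-MAPQ tags for filter tests; neither is on
by default.

What the generator does **not** emulate: sequence-level artifacts (no reads,
no aligner, no mappability structure), fragment-length variability (the 200-bp
extension is exact downstream, not modeled), locus-to-locus enrichment
heterogeneity (all domains share one enrichment), chromatin-preparation
batch effects, and partial (non-uniform) global changes. Passing tests
therefore demonstrate that the *analysis* behaves correctly under the model's
assumptions, not that any particular wet-lab experiment satisfies them.

## Experimental-design arithmetic

`chipspike.design` implements the planning arithmetic. With the reference
genome 27× smaller than the experimental one, copy-number equality needs a
27:1 mass ratio: 30 µg of experimental chromatin pairs with 30/27 ≈ 1.11 µg
of reference chromatin, and a 50 M-tag run is then expected to yield
50 M × 1.11/30 ≈ 1.85 M reference tags (the yield scales with the
spike-to-experimental mass ratio, assuming equal precipitation per unit
chromatin). The 27 is a stated design constant, not recomputed from assembly
lengths — total assembly sizes give a different ratio because the relevant
quantity is the euchromatic genome; it is configurable and never derived.
Practical designs use less (e.g. 0.75 µg per 30 µg, a ≈40:1 mass ratio)
targeting ≈1 M reference tags.

## Numerical and convention choices

- Coordinates are 0-based half-open everywhere; text formats are BED-family
  so readers/writers do no shifting. tagAlign is parsed with column 5 as
  MAPQ, same as BED6.
- Region sets are normalized on construction (sorted; overlapping and
  book-ended intervals merged), making normalization idempotent.
- Downsampling keeps round(f·n) tags (banker's rounding), sampled uniformly
  without replacement, input order preserved, bit-reproducible per seed. All
  seeds are explicit; per-sample generators are spawned from one seed via
  `numpy.random.SeedSequence`.
- bedGraph values are quantized to 4 significant digits (fixed-decimal);
  round-trips are exact at that precision, and coverage values (multiples of
  1/32) lose at most a fifth digit. Zero bins are omitted; equal-valued runs
  are merged.
- Degenerate inputs: empty tag files are valid (empty library); calling
  islands on zero fragments warns and returns nothing; a zero reference-tag
  count aborts factor computation with advice to increase spike-in material.

## Known limitations

- The Monte-Carlo E-value cutoff carries sampling error of order one
  rank among ~10³ null islands per draw set; with 500 draws this is far
  below the signal/background score separation but would matter for marginal
  islands near the cutoff.
- Restricted counting by 5′-base membership ignores edge-spanning alignments
  that a true partial-reference mapping would or would not recover.
- Only one reference species is supported, and no statistical test of
  differential occupancy is provided — the output is normalized signal and
  its per-region summaries, matching the method's scope.
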