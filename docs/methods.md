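# Methods

This note documents the statistical models, the synthetic study design,
and the numerical and design choices behind `sagetf`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential tag statistics

**Model.** A LongSAGE library is treated as a multinomial sample of tags;
for a single tag the count is effectively Poisson. Conditional on
observing `x` counts in a library of `N1` useful tags, the count `Y` in a
second library of `N2` useful tags follows the Audic–Claverie conditional
distribution

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

which is a negative binomial with `x + 1` successes and success
probability `N1/(N1+N2)`; tails are evaluated through that identity in log
space (scipy), so counts up to 1e5 pose no overflow problem. A brute-force
term-by-term series summation serves as the independent oracle in the
tests and is required to agree to a relative tolerance of 1e-10 for all
counts ≤ 50 at three library-size ratios.

**Tail convention.** The plain conditional tails are not symmetric under
`(x, N1) ↔ (y, N2)` (e.g. `x=4, y=0`, equal sizes: `P(Y≤0|x=4) = 1/32`
while the swapped minimum tail is 1/16). Because a two-library comparison
should not depend on which library is called first, the package
symmetrises: the one-sided p-value is `min(P(Y≤y|x), P(X≤x|y))` and the
two-sided p-value (the default for the `P < 0.05` screen) doubles it,
capped at 1. At `x = y`, `N1 = N2` the two-sided p is exactly 1. The pure
lower tail remains available (`conditional_lower_tail`) and is monotone
non-decreasing in `y` up to `x`.

**Fold changes.** Counts are normalised to tags per 100,000 useful tags.
Zero counts are raised to 1 *before* normalisation — for the fold change
only, never for the significance test. The magnitude is max/min of the two
normalised values; the sign is positive when the mutant library is higher,
so a gene silenced in the mutant reports a negative fold. The most
significant tag per gene carries the gene's fold into the stage matrix.

**Calibration.** The exact test is discrete: a tag with `x + y = 4` and
equal library sizes can never reach two-sided `p < 0.05` (the smallest
attainable value is 1/16). Type-I calibration is therefore checked on a
null simulation with Poisson counts at moderate-to-high expression
(lognormal σ = 0.5 around a mean of ~40 counts) and without noise
singletons, which are never significant at depth 1 and would only dilute
the rate; under those conditions the rejection rate at α = 0.05 must fall
within three binomial standard deviations of 0.05 over ≥ 1000 expressed
tags. Recovery of spiked four-fold genes at expected counts ≥ 20 is
likewise measured under Poisson sampling — the model under which the test
is exact; under the default overdispersed counts the same spike is still
recovered, but with a seed-dependent rate around 0.9.

## Cross-stage overlap and clustering

The seven-region Venn partition is computed exactly from the three stage
gene sets. Percentages follow the conventions used throughout the
analysis: stage specificity = exclusive/stage-total; pairwise overlap =
|A∩B| / |A∪B| (Jaccard, the intersection including the triple region);
triple overlap over the full union.

Clustering uses distance `1 − Spearman ρ` over pairwise-complete cells
(NaN marks "no expressed tags") and complete linkage via scipy. Items are
sorted lexicographically before clustering so the dendrogram does not
depend on input order; pairs with fewer than two shared valid cells, or a
constant vector, get the maximal distance 2. Stage correlations restrict
to genes valid in both stages (matching analyses that report a different
`n` per stage pair), use average ranks for ties and the t-approximation
for the p-value, and are flagged undefined below 3 valid genes.

## Binding profiles, scanning and footprinting

A PFM tallies base counts over ≥ 2 equal-length site sequences. The PWM is

    w(b, i) = log2( (c(b,i) + p·q_b) / ((n + p)·q_b) )

with pseudocount `p = 0.8` distributed by the background `q` (a common PWM
convention; the upstream tooling this emulates does not publish its
value). Sites are reported where the relative score
`(s − s_min)/(s_max − s_min)` reaches the threshold (default 0.80) on
either strand; minus-strand windows are scored against the
reverse-complemented matrix with coordinates reported on the forward
strand, 0-based half-open. Windows containing N are skipped rather than
scored worst-case.

Footprint filtering keeps conserved regions with identity ≥ 0.70, ranks
them by identity (ties by start), and retains them until the cumulative
length reaches `top_fraction` (default 0.10) of the promoter length,
including the region that crosses the budget; only sites fully inside a
retained region survive. This "top fraction by identity rank until the
length budget is covered" reading makes the filter monotone: raising the
identity floor or shrinking the fraction can only remove sites. A
pairwise-alignment path (`conservation_from_alignment`) computes
sliding-window percent identity with gaps as mismatches and maps merged
above-threshold runs to ungapped first-sequence coordinates, for when a
conservation track is not supplied directly.

Motif discovery is a deliberately simple stand-in for full motif-discovery
suites: one-occurrence-per-sequence EM over ungapped windows with seeded
random restarts, followed by a phase-polishing step that tries ±2-column
global shifts of the final alignment (EM reliably converges to
one-column-shifted local optima on repetitive motifs). It is deterministic
given its seed.

## Term enrichment

The EASE score is the hypergeometric upper tail with the observed overlap
reduced by one: `P(X ≥ k−1)`, so `k ≤ 1` is never significant, and the
score is conservative relative to the plain one-tailed Fisher test for
every table (verified exhaustively against an enumeration oracle).
Bonferroni multiplies by the number of terms actually tested, i.e. terms
with at least `min_genes = 3` submitted genes — the upstream service's
exact accounting is not published, so the package states its own. Genes
outside the annotation universe are dropped with a warning rather than
failing, since identifier conversion is out of scope.

## Anchored co-factor over-representation

For each gene, other-TF sites are kept when their interval lies within
100 bp of an anchor-site interval (gap ≤ window) and shares no base with
any anchor. The searchable length is the union of ± window flanks around
the anchors minus the anchor bases themselves; it is the denominator of
the site-density rate. Two statistics are computed per TF against a fixed
background gene set:

* **Fisher score** — one-tailed hypergeometric probability of at least the
  observed number of target genes carrying a proximal site, given the
  pooled target + background gene-hit table. Verified against exhaustive
  tail enumeration, and against printed contingency tables whose inputs
  are fully known (40/64 vs 172/500 → 1.58e-05; 41/64 vs 190/500 →
  6.53e-05; 47/64 vs 248/500 → 2.13e-04).
* **Z-score** — the rate model `z = (x − u − 0.5)/sqrt(L·p(1−p))` with
  `p = bg_sites/bg_nt` and `u = p·L` for target searchable length `L`. The
  source analysis prints Z values but no formula, so the package adopts
  this binomial continuity-corrected form from the methodology it is
  modelled on; published Z values are not reproducible without the
  original per-gene site counts. A background with zero sites is floored
  at half a site so the null variance stays defined.

Empirical p-values re-run both scores on `N` random target-size gene sets
drawn without replacement (within a set) from the candidate pool, with the
same fixed background; `p = n/N` where `n` counts trials *strictly* more
significant (greater Z, smaller Fisher), and `n = 0` is reported as the
bound `< 1/N`. Enrichment requires Z > 10 and Fisher < 0.01. By default
the background sample excludes the target genes while the trial pool
includes them, matching a design where random sets are drawn from the full
candidate list.

## Synthetic study design

`synthetic.simulate_transcriptome` / `simulate_libraries` generate every
pipeline input with known ground truth:

* **Libraries.** 2 genotypes × 3 stages. Per-gene expected counts are
  `depth · w` with lognormal weights (σ = 1.25). The default pairs 2,000
  genes with 8,000 useful tags per library: the real libraries average
  ~3.3 counts per tag type (~83,000 useful tags over ~25,000 types), and
  preserving that singleton-heavy spectrum at a tractable gene count
  matters more for the statistics than the absolute depth. Counts are
  negative binomial with dispersion 0.1 (SAGE counts are overdispersed);
  Poisson is available for exactness tests. Spiked genes (5 % by default)
  change four-fold in the mutant, direction random, constant across
  stages. Singleton noise tags are added so ~18 % of useful tags are
  singletons, plus small contaminant classes (N-base, linker, low-quality
  records) that the filter must remove.
* **Promoters.** 10,001 bp with a central TSS, uniform ACGT background.
  Each anchored promoter (70 % of genes) carries 1–3 exact anchor-consensus
  sites with random spacing inside a high-identity (0.90) footprint block;
  filler conserved blocks (0.72–0.82) and sub-threshold decoy blocks (0.4–
  0.6) complete the track, which is emitted directly as intervals so
  footprinting is testable without an aligner. Planted sites are exact
  consensus copies (or reverse complements) and never overlap. The
  variable anchor count and spacing give promoters genuinely different
  searchable lengths — mirroring the wide per-gene site-count range seen
  in real promoter scans — which keeps the co-factor Z statistic
  effectively continuous; a fixed layout would lattice the empirical null.
* **Ground-truth targets.** One annotation term is enriched for the
  spiked + anchored genes, drawing its "pure" members from the
  best-expressed ones (the real target list consisted of genes the screen
  had detected, so detectability is part of the design, not a
  confounder). A planted co-factor consensus sits within 10–80 bp of an
  anchor on 80 % of the target genes, and on 5 % of non-target anchored
  promoters as nonspecific background; with the planted fraction set to 0
  no co-factor site is planted anywhere. Six decoy TFs get
  Poisson-distributed site counts (mean 0.5/promoter) at random conserved
  positions.

**What the generator does not emulate:** ditag assembly and sequencing
error beyond a per-tag quality scalar; tag-to-gene ambiguity from shared
3' ends (each gene has a unique canonical tag, so mapping ambiguity is
exercised only in unit fixtures); real conservation structure (tracks are
planted intervals, not alignments of orthologues); correlated expression
between genes; and stage-specific regulation (spikes persist across
stages). Passing recovery tests therefore demonstrate correctness of the
statistics and plumbing under the stated model, not performance on real
libraries.

## Problem sizes

The test suite and acceptance script use scaled-down configurations chosen
to keep the full run in minutes on one CPU: 250–600 genes with 1.5–2.4 kb
promoters for integration and co-factor experiments (10 planted seeds, 20
null seeds, 200–500 permutation trials), 1,500 genes for the calibration
null, and one full default-scale run (2,000 genes, 10 kb promoters, 1,000
trials, 500 background genes) in the acceptance script. The statistics are
size-free; only their Monte-Carlo error depends on these choices.

## Known limitations

* The symmetrised Audic–Claverie tail is a design choice; software that
  conditions on one fixed library can differ near the significance
  boundary for asymmetric library sizes.
* The Z-score formula is adopted, not reverse-engineered; printed Z values
  from the original analysis are not expected to reproduce.
* Empirical p-values inherit the discreteness of site counts; with few
  variable sites per gene set the n/N distribution under the null is
  uniform only approximately (ties count as "not more significant").
* The EASE/Bonferroni accounting and the "top fraction of conserved
  regions" rule are reasonable readings of under-specified upstream tools,
  stated explicitly above and implemented deterministically.
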