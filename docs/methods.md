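# Methods

## Panels and scored columns

A panel is an ordered list of loci; the unit of counting is the *scored
column*. Yfiler has 16 loci scored as 17 columns (DYS385 contributes the
order-free pair DYS385a/DYS385b). The RM set is scored as 14 columns
(RM13), with DYS526A+B as one combined column and DYF403S1a/DYF403S1b as
two distinct single-copy loci — they are separate amplicons with separate
rates, which is also what makes RM11 (RM13 minus DYF399S1 and DYF403S1a,
12 columns) a strict column subset of RM13. Markers that are biologically
multi-copy (DYS385, DYF399S1, DYF387S1, DYF404S1, DYF403S1a/b) are
flagged as such independently of their column structure: within a
pedigree, copy identity can be tracked through inheritance, but between
unrelated men it cannot, so these markers are excluded from the DAPC
feature sets.

Multi-copy allele tuples are sorted at ingest (copy assignment is not
observable from an electropherogram) and compared copy-wise in sorted
order, which for equal-length sorted tuples is the minimal-total-
difference matching. Allele values may carry one decimal digit
(microvariants); the simulator emits integers only, since counting
operates in whole repeat units.

## Stepwise mutation model

Per meiosis, each scored copy of each locus mutates independently with
probability μ. On mutation the step size is 1 repeat unit with
probability 1 − p_multistep, otherwise 1 + Geometric(step_tail) units;
the sign is ±1 equiprobably; an allele pushed below zero is reflected to
a positive step (logged — it never occurs at realistic founder alleles).
Defaults: per-column μ from the published direct counts (events/470
meioses; DYF399S1 ≈ 0.064, typical Yfiler columns ≈ 0.002–0.013),
p_multistep = 0.04 and step_tail = 0.5 — the step-size distribution is
not constrained by the direct-count data, so a small multi-step fraction
in line with the wider STR literature is used and both parameters are
configurable. One pseudo-random stream is consumed in deterministic
node/column order, so a seed fixes every output byte.

Back mutation falls out of the model naturally: two consecutive hits at
one locus cancel in half of the cases, which is the mechanism behind both
homoplasy and the saturation bias discussed below.

## Study designs emulated by the generator

* **Deep pedigrees** (rate estimation): 26 star-shaped paternal
  pedigrees connecting 66 sampled men (twelve with two branches,
  fourteen with three), branch depths uniform on 1–13 generations. This
  reproduces the published scale — ≈470 subtree meioses, pairwise
  separations up to 26 — which is what the estimators' behaviour depends
  on. The meiosis denominator of a pedigree is the edge count of the
  minimal (Steiner) subtree connecting its sampled men: mutations are
  only observable on lineages leading to sampled descendants.
* **Close relatives** (saturation control): 27 couples spanning 45
  meioses — 15 father–son, 8 brothers, 2 uncle–nephew, 2 cousins, the
  unique mixture consistent with those published totals given all four
  relationship classes.
* **Clustered lineages** (phylogenetic signal): a star-of-stars
  genealogy — nine group founders diverging from a common root, samples
  diverging from their founder. Defaults (divergence 22, within-group 35
  meioses) were chosen so that simulated same-group and cross-group
  couples sit at the observed order of 10–25 independent-event
  differences on the RM panels; the design is an emulation of a young,
  homoplasy-prone haplogroup's structure, not a reconstruction of any
  real lineage history.
* **Non-paternity** (outlier screening): a false paternal link is
  emulated by replacing one sampled man's haplotype with one evolved
  independently for 150 meioses. Note the detectability gradient this
  produces: in a 4-meiosis pedigree the contamination yields a
  mutations/meioses ratio of ≈4 and is flagged at once, while the same
  event diluted over 17 meioses approaches the upper tail of clean
  ratios and can survive the screen (with the default seed the Grubbs
  procedure recovers the two shallow injections and leaves the deepest
  marginal at p ≈ 0.10). Ratio-based screening is intrinsically weak
  against deep-pedigree non-paternity.

What the generator does **not** emulate: population structure beyond the
star topologies, mutation-rate heterogeneity across lineages, allele
dropout/typing error, microvariant alleles, and realistic allele
frequency spectra. Passing tests therefore certify the estimators and
counters under the stated model, not the full messiness of real data.

## Mutation counting

Within pedigrees the count at a column is the minimum number of subtree
edges on which the allele changes, over all assignments of alleles to
unsampled ancestors — unordered-state parsimony (any-size change costs
one event), because a single multi-step event is far more likely than
multiple independent hits at one locus within a pedigree's time frame.
It is computed by Sankoff dynamic programming over the distinct observed
alleles (an optimal unit-cost solution never needs other states), with
observed men fixed wherever they sit in the tree. Individuals with a
missing call at a column are pruned for that column; fewer than two
informative men yields count 0 with a logged notice; the meiosis
denominator is *not* down-weighted for missing calls (rates are reported
per scored column, and the handful of missing calls expected in practice
is logged for audit instead).

Between unrelated men the same 36-vs-34 difference counts as |Δ| = 2
independent single-step events: with no recent shared ancestor there is
no reason to favour one multi-step event.

## Rate estimation

μ̂ = NMUT/(NGEN × L). The 95% CI takes q(0.025) and q(0.975) of
Binomial(n = NGEN, p = NMUT/NGEN) — q(u) being the smallest k with
CDF(k) ≥ u — each divided by NGEN × L. The binomial size is the meiosis
count, *not* NGEN × L; this is the construction that reproduces the
published tables' endpoints exactly, and its endpoints are always
achieved event counts. NMUT = 0 gives the degenerate interval (0, 0).
One published pooled row (the deep-pedigree RM11 interval) is internally
inconsistent — its printed endpoints match neither this construction nor
the same value quoted elsewhere in the source study's text — and is
excluded from exactness checks; its point estimate reproduces.

**Saturation.** At RM-scale rates the direct count is a biased-down
estimate of the underlying per-meiosis rate: with ≈0.19 expected hits
per column on a 13-meiosis branch, multi-hit collapse and cancellation
hide ≈10–15% of true events. The package's own diachronic binning shows
the effect — RM13 binned rates fall by ≈15% from the 1–10 to the 21–26
meiosis bin while Yfiler rates stay flat (loss ≈3% at Yfiler rates) —
and the parameter-recovery tests measure it directly: at a uniform true
μ = 0.00325 the pooled estimate recovers within ≈3.5% with ≈94% CI
coverage, while at μ = 0.0146 the estimate sits ≈14% low and coverage
collapses, exactly as the within-pedigree physics dictates. Direct-count
RM rates should therefore be read as rates *as observable in pedigrees
of this depth profile*, not as germline rates.

**Grubbs screening.** Candidate non-paternity pedigrees are removed by
iterating the two-sided single-outlier Grubbs test on per-pedigree
mutations/meioses ratios: compute G = max|xᵢ − x̄|/s, its p-value
2N·P(T_{N−2} > t) with t² = N(N−2)G²/((N−1)² − NG²), drop the extreme
ratio while p ≤ α (default 0.05), stop otherwise. Identical ratios give
p = 1 and no exclusions; the scan order is sorted for input-order
invariance. Masking applies as to any single-outlier iteration: several
comparable outliers inflate the variance and can shield one another.

**Diachronic bins.** Within-pedigree pairwise comparisons (each couple's
meioses = path length through the common ancestor) are pooled into
disjoint separation bins — default 1–10, 11–20, 21–26 — and each bin is
estimated like a pooled dataset. Couples outside every bin are logged
and skipped.

## Discrimination summaries

Discriminatory power is the fraction of couples with ≥1 differing scored
column. Percentages are printed by rounding half-up to three decimals
and then to two — a double-rounding convention adopted deliberately so
that 4/27 prints as 14.82 (the source tables' formatting), alongside
7.41 for 2/27 and 33.33 for 9/27. The mean per-couple mutation count
gets a percentile-bootstrap 95% CI by resampling couples (their counts)
with replacement, B = 1000 by default, seeded; no bias correction —
the empirical-percentile method matches the scale of the quantities
involved and is exactly reproducible.

## DAPC

Features are the single-copy loci's allele values, imputed by column
mean where missing, centered (not variance-scaled — repeat units share a
scale; scaling is a flag) and reduced by PCA; linear discriminant
analysis with **equal group priors** is fitted on the retained scores,
and membership probabilities are the Gaussian posteriors in discriminant
space. Equal priors keep group sizes from leaking into membership.
Defaults: retained PCs = smallest count explaining ≥90% of variance,
capped at n/3; discriminant axes = groups − 1. Constant columns are
dropped with a warning before PCA; requesting more PCs than the matrix
rank clips with a warning; with full-rank PCs the posteriors equal
direct LDA on the raw features (PCA is then a rotation).

Reported memberships are training-set values (matching the analysis
style the package reproduces); a stratified k-fold cross-validated mode
exists for honest out-of-sample assignment. Training-set amp is inflated
by overfitting as the retained-PC count grows: on structureless data
with permuted labels (9 groups, n = 90) amp sits at the 1/9 chance level
for few PCs but reaches ≈0.30 at 14 PCs. The null-calibration test
therefore uses a deliberately modest 5-PC model; for real inference at
default dimensionality, prefer the cross-validated mode.

## Numerical conventions and problem sizes

Rates are reported to 5 decimals (round-half-up), percentages as above.
Seeds: every stochastic routine takes a seed or Generator; a single
stream is consumed in deterministic order. Test problem sizes were
chosen to keep the full suite under half a minute while leaving the
statistical assertions well-powered: 500 random trees (≤8 free ancestral
nodes, 5 allele states) for the exhaustive parsimony oracle, 300
replicate simulations of the 26-pedigree study for recovery/coverage,
10⁴ single-meiosis replicates for the event-frequency check, 100 label
permutations for the DAPC null, B = 10⁵ for the bootstrap-vs-enumeration
comparison.

## Known limitations

Parsimony counting is a minimum, hence the saturation bias above;
no likelihood-based or Bayesian rate model is provided. The Grubbs
screen is a univariate ratio test and misses deep-pedigree non-paternity.
The lineage generator's star-of-stars topology has no within-group
genealogical structure. DYF399S1 is scored as a single column even
though the marker is tri-allelic in practice, following the convention
of the reference rate table; its internal copy structure is not
modelled.
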