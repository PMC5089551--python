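# rmystr

Pedigree-based mutation-rate estimation and discrimination analysis for
Y-chromosomal STR panels, with a focus on the rapidly-mutating (RM) Y-STR
set used in forensic genetics and molecular anthropology.

## The problem

Y-STR haplotypes are the standard tool for telling paternal lineages
apart, but two men can share a haplotype either through recent common
ancestry or through homoplasy (independent mutations converging under the
stepwise mutation model). Rapidly-mutating Y-STRs — a 13-marker set with
per-locus mutation rates roughly ten times those of the classic 17-column
Yfiler panel — were proposed to separate even close relatives. Assessing
what they actually deliver requires (i) mutation rates estimated by
direct count in deep-rooted paternal pedigrees, (ii) the fraction of
related couples a panel can distinguish, and (iii) how much sub-lineage
("phylogenetic") signal survives the markers' high mutability.

This package implements that entire analysis as a tested library:

- **Panels** — `YFILER` (17 scored columns), `RM13` (14), `RM11` (12;
  RM13 minus its two most mutable markers, DYF399S1 and DYF403S1a).
- **Simulation** — haplotypes evolved down paternal pedigrees under a
  symmetric stepwise mutation model (per-column rate μ, occasional
  multi-step events), with truth logs for parameter-recovery tests.
- **Counting** — mutation events by maximum parsimony within pedigrees
  (a multi-step change like 36→34 is **one** event between relatives)
  and by direct comparison between unrelated men (36 vs 34 counts as
  **two** independent events).
- **Rates** — the direct-count estimator μ̂ = NMUT / (NGEN × L) with a
  binomial-quantile 95% CI: the 2.5% and 97.5% quantiles of
  Binomial(n = NGEN, p = NMUT/NGEN), divided by NGEN × L; iterated
  two-sided Grubbs tests screen out pedigrees whose mutations/meioses
  ratio betrays non-paternity; diachronic rates by meiosis-separation
  bins (1–10, 11–20, 21–26).
- **Discrimination** — fraction of differing couples per panel, mean
  mutations per couple, percentile-bootstrap CIs.
- **DAPC** — PCA followed by linear discriminant analysis on single-copy
  loci, yielding posterior sub-lineage membership probabilities and
  per-group average membership probabilities (amp).

## Worked example

```python
>>> from rmystr import estimate_rate
>>> est = estimate_rate(NMUT=26, NGEN=470, L=17, panel="YFILER")
>>> est.rounded()
(0.00325, 0.00213, 0.00451)
```

26 mutation events over 470 meioses across 17 scored columns give the
Yfiler average rate 3.25 × 10⁻³ per locus per generation, with 95%
binomial-quantile CI (2.13 × 10⁻³, 4.51 × 10⁻³): the quantile counts are
17 and 36 events. The same estimator applied per column (L = 1) gives,
e.g., 30 events at DYF399S1 → 0.06383 (CI 0.04255–0.08723), an order of
magnitude above typical Yfiler loci.

The full analysis is a sequence of thin drivers over the library:

```sh
python analysis/01_simulate_datasets.py --seed 1   # pedigrees, couples, lineages
python analysis/02_count_mutations.py              # parsimony NGEN/NMUT tables
python analysis/03_estimate_rates.py               # Grubbs screen + rate tables
python analysis/04_discrimination.py               # couple discrimination
python analysis/05_classify_lineages.py            # DAPC membership / amp
```

With the default seed this prints, among other things, a deep-pedigree
set of 26 pedigrees spanning 449 meioses plus three injected
non-paternity pedigrees of which the Grubbs screen recovers the two
shallow ones (`excluded ['G27', 'G28']`), close-relative discriminating
powers of 7.41% / 14.82% / 25.93% for Yfiler / RM11 / RM13, a clear
relatedness gradient in mean pairwise mutation counts (close relatives
0.41 ≪ same-lineage 9.47 < cross-lineage 13.03 for RM13, non-overlapping
bootstrap CIs), and mean DAPC amp rising from 0.64 (Yfiler) and 0.57
(RM11) to 0.86 when the feature sets are combined. Tables land under
`results/`. The same pipeline is exposed as a CLI
(`rmystr simulate|count|rates|discriminate|dapc`).

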