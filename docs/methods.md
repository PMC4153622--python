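# Methods

This note documents the models, conventions and numerical choices behind
`senotf`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Study design being modeled

Cultures of primary human fibroblasts passaged toward replicative senescence
are profiled at three population-doubling (PD) levels with three biological
replicates each; the lowest PD level is the reference (calibrator) condition
for both the expression contrasts and the qPCR normalization.  Downstream,
the promoters (1,000 bp upstream of each gene's transcription start) of
differentially expressed genes are screened for binding sites of the
differentially expressed transcription factors.

## Synthetic data

`SimulationConfig` fixes the study conditions; its defaults are the design
points used throughout the test suite.

| parameter | default | units / meaning |
| --- | --- | --- |
| `n_genes`, `n_promoters` | 5,000 | genes on the array; one promoter per gene |
| `promoter_length` | 1,000 | bp of upstream sequence |
| `groups` | PD38, PD47, PD54 | ordered PD levels; first = reference |
| `replicates_per_group` | 3 | biological replicates |
| `de_fraction` | 0.10 | proportion of truly DE genes |
| `effect_size` | 1.0 | log₂-units; magnitude of the planted shift |
| `noise_sd` | 0.25 | log₂-units; i.i.d. Gaussian replicate noise |
| `gc_content` | 0.45 | promoter G+C proportion |
| `plant_rate_target` / `plant_rate_background` | 2.0 / 0.2 | Poisson mean planted sites per targeted / other promoter |

Choices and rationale:

* **Baseline expression** is Gaussian on the log₂ scale, mean 8, SD 2 — the
  typical dynamic range of summarized bead-array log intensities.  Truly DE
  genes (a round-half-to-even fraction `de_fraction` of `n_genes`) receive a
  single random sign and a ±`effect_size` shift applied to every
  non-reference group, modeling a monotone senescence trajectory; the truth
  table records the per-group true log₂ fold change.
* **Promoters** are i.i.d. bases with P(G) = P(C) = `gc_content`/2.
  Planted motif sites are Poisson in number, non-overlapping, forward strand,
  each a uniformly drawn concrete variant of the motif; sites that cannot be
  placed without overlap are dropped and the actual count recorded, so truth
  stays exactly countable.  Chance background matches are accepted — scans of
  planted promoters are therefore tested with ≥, not equality, except in
  constructions where chance matches are impossible.
* **Ct tables** realise quantity = E^(−Ct) with a per-sample log-normal
  loading factor shared by all genes of the sample (it cancels under
  reference normalization), Gaussian Ct noise, and reference genes at fold 1
  by construction.
* **Determinism**: every generator draws from a `numpy` Generator seeded by
  `(seed, fixed-substream-key)`, so identical configurations give
  byte-identical FASTA/TSV outputs and adding one stage never reshuffles
  another.

What the generator does **not** emulate: probe-level bead chemistry,
normalization artifacts, correlated noise between genes, variance–intensity
dependence, nucleotide composition structure of real promoters (CpG islands,
repeats), or linkage between a TF's expression and its targets' expression
(correlations must be planted explicitly or arise by chance).  Passing tests
therefore demonstrate correctness of the *computations* under a clean,
homoscedastic model — not performance on real arrays.

## Differential expression

Per gene and contrast: log₂ fold change is the difference of group means on
the log₂ scale; significance is a two-sided two-sample *t*-test.  The default
is the **pooled-variance Student** test: under the generator's equal-variance
Gaussian noise it is exact, and at n = 3 per group this matters — the Welch
variant (available via `method="welch"`) is measurably conservative there
(type-I rate ≈ 0.032 at nominal 0.05 in the 5,000-gene null simulation,
versus ≈ 0.050 for the pooled test).  Degenerate genes (zero variance on both
sides) get p = 1 for equal means, p = 0 otherwise.

Multiple testing uses Benjamini–Hochberg within each contrast.  A gene is
called DE iff **both** strict inequalities hold: |log₂FC| > 0.4 and q < 0.05
(`use_raw_p=True` substitutes the raw p-value — both readings of a
"fold change + significance" filter are common in array studies and the
choice is exposed rather than asserted).

A caveat the truth-recovery tests make explicit: with 3 replicates per side
the *t* statistic has 4 degrees of freedom, so even a 4.9-standard-error
effect yields p-values around 10⁻² – 10⁻³.  BH at 0.05 across 5,000 genes is
then extremely stringent (near-zero sensitivity with near-zero false
discoveries), while the raw p < 0.05 filter is sensitive (≈ 0.95) but does
not control the FDR (≈ 0.18 empirically at these settings).  This trade-off
is a property of tiny-n per-gene testing itself; moderated-variance models
that would soften it are out of scope.

## Motif scanning

IUPAC codes map to base sets; the variant count of a pattern is the product
of per-position set sizes, and only motifs with **fewer than 1,000** variants
(strict) are eligible — beyond that a pattern matches so promiscuously that
occurrence counts carry no signal.  Matching is exact: a position matches iff
every sequence base is in the corresponding set; an `N` in the *sequence* is
a masked base and matches nothing (conservative; masked stretches never
inflate counts).  Default scanning searches both strands — a binding site is
a double-stranded feature — by also matching the reverse complement of the
pattern on the forward sequence; identical intervals from palindromic
patterns are reported once (strand recorded as `+`).  Overlapping matches are
counted by default; the non-overlap policy keeps a greedy left-to-right
subset (deterministic tie-break).  Coordinates are 0-based half-open.  The
scanner is regex-based with lookahead and is property-tested against a
position-by-position brute-force checker.

## Target calling, correlation, enrichment

Background statistics per motif are the sample mean and sample SD (n−1
denominator) of occurrence counts over all promoters; candidates lie
*strictly* outside mean ± SD (both tails: unusually site-rich and unusually
site-poor promoters are both informative).  Correlation between a TF and a
candidate uses Pearson *r* across replicate-level samples (9 points in the
default design; a group-mean mode with 3 points is selectable); |r| ≥ 0.8
counts, anti-correlation included, and with so few points this is explicitly
a screening heuristic.  TFs are ranked by descending correlated-target count,
ties broken by smaller enrichment p, then lexicographic TF id — a total,
input-order-independent order.

Enrichment per motif is a two-sided Fisher exact test on promoter membership
(DE × target), with the sample odds ratio a·d/(b·c) (∞ when b·c = 0 and
a·d > 0, 0 when a·d = 0), BH across motifs, and `enriched ⇔ q < 0.05 ∧ OR > 1`.
The p-value is computed directly from the hypergeometric pmf over the table's
support (sum of outcomes no more likely than observed, with the customary
1 + 10⁻⁷ tie tolerance); this is numerically identical to
`scipy.stats.fisher_exact` — asserted in the suite — and fast enough for the
exhaustive small-table verification against an integer-arithmetic oracle.
An alternative permutation method (statistic: total site count in DE
promoters; DE labels shuffled, default 10,000 rounds, seeded) probes
occurrence *rates* rather than promoter membership.  The pipeline's DE set
for enrichment is the union over contrasts.  Empty DE set ⇒ p = 1 everywhere
by convention.

## Quantification utilities

* **Population doublings**: ΔPD = log₂(n_f/n_i) per subculture, summed from
  the initial PD; the final level depends only on total expansion
  (log₂(a·b) = log₂a + log₂b), which the tests assert as split-invariance.
* **qPCR NRQ** (multi-reference model): technical replicates are averaged on
  the Ct scale *before* any exponentiation (order matters; the exponential
  of a mean is not the mean of exponentials); RQ = E^(ΔCt) anchored at the
  calibrator-group mean Ct; the per-sample normalization factor is the
  geometric mean of the reference-gene RQs (their geometric mean is exactly 1
  afterward — an asserted invariant); NRQs are rescaled so the calibrator
  group's mean is 1 per target.  The reference-gene set is a required
  explicit argument — studies vary in which housekeeping genes they use per
  figure, so nothing is defaulted silently.  Relative SDs propagate in
  quadrature (product/quotient rule): combined = √Σ(rel SD²), with the
  reference contribution scaled by 1/n_refs through the geometric mean.
* **ChIP-qPCR**: fold over control = E^(Ct_control − Ct_IP); percent input
  corrects the input aliquot's Ct by −log_E(dilution factor), so an IP whose
  Ct equals that of a 1/100 input aliquot recovers 1% of input.
* **Band densitometry**: target/loading-control ratio, rescaled to the
  reference-group mean ratio.
* **Group comparisons** use the classical pooled-variance two-tailed Student
  *t*-test with the same degenerate-variance conventions as the DE module.

## Problem sizes and numerical conventions

The test suite and the acceptance script use 2,000–5,000 genes/promoters,
1,000-bp promoters, 100 seeded runs for the enrichment power check and 25 for
the script's scaled-down variant, 200 motifs for null calibration, and 2,000
random tables (script) or the full ≤ 50-margin sweep (suite) for the Fisher
cross-check — sizes at which every statistical property under test is
well-resolved.  Probabilistic assertions use 3-SD bands around their expected
values; exact recoveries (noiseless limits, round trips) are asserted at
1e−9 relative error or tighter; all randomness flows from explicit seeds and
all outputs carry the configuration hash.
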