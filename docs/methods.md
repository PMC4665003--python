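# Methods

This note documents the models, conventions and design choices behind
`ltrcage`, in the order the pipeline runs them.

## Coordinates and formats

All internal coordinates are 0-based half-open; RepeatMasker `.out` and GTF
(1-based inclusive) are converted on read and back on write. A CTSS record's
position is the 5′ base of the tag on either strand, with no shifting.
Duplicate CTSS records at one (chromosome, position, strand) are summed on
read — counts are additive tag tallies. Repeat subfamilies ending in `-int`
(internal proviral segments) are flagged and, by default, excluded from
LTR-family overlap analyses.

## TSS clustering

Clustering follows the density ("Paraclu-style") scheme with parameters
10 tags / 2-fold density rise / 500 bp maximum span. For a run of tag sites,
density is total tags divided by the site span (`last − first + 1`, so a
single site has a well-defined density equal to its count). Each maximal run
per (chromosome, strand) is recursively split at its minimum-density proper
prefix or suffix; ties between the prefix and suffix minimum are broken
toward the prefix, and within prefixes/suffixes the leftmost minimum wins.
A cluster appears between `d_form` (the running maximum of the break
densities of its ancestors; 0 at the root) and `d_break` (its own minimum
prefix/suffix density; +∞ for single sites).

The normative semantics is the threshold sweep: for each achievable density
`d` (the density of some site run), the clusters at `d` are the runs left
after repeatedly splitting at minimum-density prefixes/suffixes below `d`.
A consequence worth noting: a candidate produced by the recursion whose
interval `(d_form, d_break]` contains **no** achievable density appears at
no threshold and is not reported. For finite `d_break` the break density is
itself achievable, so only single-site candidates are affected: a leaf is
reported only if some single-site count on its strand exceeds its formation
density. `tests/_oracles.sweep_clusters` implements the sweep directly and
the suite verifies exact agreement (boundaries, tag totals, `d_form`,
`d_break`) on randomized instances.

After the three filters, reported clusters strictly contained in another
reported cluster on the same strand are dropped (the outermost wins). Peaks
are quantified per sample by counting tags with 5′ position inside
`[start, end)` on the peak strand; tpm = count / library size × 10⁶, where
the library size is the supplied total of uniquely mapped tags (not the
column sum of the peak matrix). The working set keeps peaks with tpm > 1 in
at least one tumor sample and ≥ 1 tag in at least two tumor samples;
"expressed" is deliberately the one-tag criterion, consistent with the atlas
breadth criterion.

## Peak taxonomy

The classification cascade is: coding (peak interval intersects a
protein-coding TSS ± 100 bp window, inclusive, same strand), else proximal
(peak summit within 5 kb — summit-to-summit — of any coding peak, any
strand, or interval overlap with a protein-coding exon on either strand),
else distal. Distances are computed within a chromosome; ties go to the
smaller coordinate; distal peaks on chromosomes without coding peaks are
excluded from distance histograms with a tally. The 5-kb rule is
summit-to-summit because the summit is the single defined TSS point; the
window is configurable.

## Differential expression

The count model is negative binomial with variance μ + φμ². The procedure
is a deliberately simplified conditional-likelihood pipeline, not a
re-implementation of any particular package's internals:

1. *Library equalization*: counts are rescaled to the geometric-mean library
   size and rounded half-to-even (unbiased, deterministic).
2. *Common dispersion*: φ maximizes the summed log conditional likelihood of
   within-group counts given group totals (for m i.i.d. NB(μ, φ) samples the
   conditional law given the total depends only on φ). Optimization is a
   40-point log-grid scan on φ ∈ [10⁻⁶, 5] followed by bounded scalar
   refinement at tolerance 10⁻⁶; Poisson-like data hits the lower boundary
   and reports φ ≈ 10⁻⁶ rather than failing.
3. *Exact test*: group sums are NB with means proportional to group size and
   aggregated dispersion (sum of m i.i.d. NB(μ, φ) is NB(mμ, φ/m)).
   Conditional on the total, the two-sided p-value is the sum of the
   conditional probabilities of all outcomes at most as likely as the
   observed one (with a 10⁻¹⁰ relative tolerance for float ties). At φ = 0
   the conditional law is exactly binomial, which the tests exploit as a
   closed-form oracle.
4. *Calling*: BH FDR across all tested peaks; "up" means FDR < 0.05 and
   case-group mean above control. Fold changes are ratios of group-mean tpm
   with a 0.001 pseudocount (0.005 in the log-display convention).

The method is validated by calibration (null type-I error within
[0.03, 0.07] at α = 0.05) and parameter recovery (φ within ±25%) rather than
by matching another implementation bit for bit. Tagwise (per-peak)
dispersion is an explicit non-goal; common dispersion is sufficient for the
recovery and calibration targets and is noted as the extension point.

## Repeat enrichment

Overlap requires ≥ 1 bp intersection; a peak hitting several elements takes
the element covering its summit, then the largest intersection, ties to the
smaller element start. The relative position of a summit along an element is
`(summit − start)/length` on plus-strand elements and
`(end − summit)/length` on minus-strand elements (5′→3′ on the element
strand). Enrichment contingencies use the working-set distal peaks
partitioned into up and non-up; Fisher tests are one-sided for enrichment
among up peaks, with Woolf confidence intervals (Haldane–Anscombe +0.5 when
a cell is zero). Subfamily activation counts distinct elements (not peaks)
against genomic copy number with a hypergeometric test and BH correction —
elements are the sampling unit so multi-peak elements are not double
counted. The randomization control relocates each distal peak to a uniform
random genome position (chromosome drawn proportional to length, so
placement is uniform per bp; strand redrawn by default), preserving peak
length; with uniformly placed repeats covering fraction q, the expected
sense-overlap fraction is q/2, which the tests check against the empirical
null at 3 standard errors.

## Signature and stratification

Signature peaks are distal peaks with FDR < 10⁻¹⁰, linear fold change
strictly above 8, and ≥ 1 tag in at least 30 tumor samples, named
`PREFIX-001…` in ascending FDR (peak-id tiebreak, so the output is
independent of input order). In the simulated default cohort of 20 tumors
the 30-sample criterion is unattainable by construction, so the end-to-end
driver scales it to ⌈0.6 · n_tumor⌉ — the same 60% of the cohort that 30/50
represents; an explicitly configured value is always used verbatim.

Stratification clusters sample vectors of log₁₀(tpm + 0.005) over the
signature with average linkage (UPGMA) and Euclidean distance; the tree is
cut into exactly k = 3 groups (lowest cut producing k clusters, via the
hierarchy's `cut_tree`), and strata are labeled high/intermediate/low by
descending mean signature expression. PCA uses the centered log matrix and
an SVD with a deterministic sign convention (largest-magnitude loading
positive). Clinical association compares the high and low strata
(intermediate excluded): per binary covariate a 2×2 Fisher two-sided test,
Woolf 95% CI, BH across covariates, and Cochran's Q over the covariate
log odds ratios as the heterogeneity test — Q is this package's concrete
reading of an otherwise unnamed "test for heterogeneity".

## Regulatory integration

A peak is active in the reference cell line iff it contains ≥ 1 cell CAGE
tag and the nearest open-chromatin interval (all replicates concatenated) is
within 1 kb (gap distance; overlap = 0). Chromatin-state labels collapse to
Promoter / Enhancer / Repressive / Others with the priority
Promoter > Enhancer > Repressive across overlapping segments. TF binding is
a ChIP peak midpoint inside the strand-oriented window [−600, +400] bp
around the peak summit (both bounds inclusive; "peak center" = summit);
association is a one-sided Fisher test per TF, Bonferroni-corrected by the
number of TFs tested. A TF's target set is its bound, active, up-regulated
peaks; cobinding edges require Jaccard strictly above 0.5, and maximal
cliques come from the graph library, checked in the tests against a plain
recursive enumeration.

## Synthetic cohorts

The generator emulates the shape of a CAGE liver-tumor study on a small
genome (default two 5-Mb chromosomes). Placement scatters 200 three-exon
genes, a repeat catalog of eight subfamilies, and reserved intergenic slots
with ≥ 6 kb spacing (so planted intergenic promoters classify as distal and
divergent partners as proximal). Planted structure:

* 60 strongly activated promoters at 70% of element length (strand-aware)
  inside a designated LTR subfamily, baseline mean 50–200 tags, fold 16 in
  tumors — modulated by each tumor's latent tier (high ×1, intermediate
  ×0.3, low ×0; tier fractions 0.32/0.40/0.28, echoing the 16/20/14 split of
  a 50-tumor cohort);
* 40 weakly activated intergenic promoters (fold 3 in every tumor) and 150
  background distal promoters (6% placed in non-activated LTR copies in
  sense orientation), so the enrichment denominator is realistic;
* housekeeping promoters at every gene TSS, 40 of them with a divergent
  antisense partner 250 bp upstream sharing a per-sample lognormal latent
  factor (σ = 0.4) — the substrate for the bidirectionality and
  neighbor-correlation analyses;
* weak antisense promoters near the 5′ end of long LINE copies for the
  metaelement profile.

Counts are NB(mean, φ = 0.1) totals per locus and sample (mean scaled by
relative library size), spread multinomially over a 5-bp window with weights
(0.1, 0.15, 0.5, 0.15, 0.1) — enough to give every peak a summit; background
tags fall uniformly at 50 per Mb per sample. Clinical covariates are
Bernoulli draws conditional on the latent tier; the recurrence defaults give
10/16 recurrent high-tier and 2/14 low-tier patients in expectation.
Regulatory tracks plant a 6-TF clique binding each activated locus with
probability 0.9, midpoints within −100..0 bp of the summit, plus 13
background TFs at 5% binding; open chromatin covers every active locus and
chromatin states label active loci promoter-like and unused repeat copies
heterochromatic.

What the generator does *not* emulate: sequence content (no motifs, no GC
structure), multimapping tags, repeat copy-number change, paired-sample
correlation beyond the shared latent factors, and mapping artifacts.
Passing tests therefore demonstrate algorithmic correctness and statistical
calibration under the stated count model — not robustness to alignment or
sequence-level confounders of real CAGE data.

## Numerical choices and degenerate inputs

Half-to-even rounding in library equalization; log-space conditional
probabilities with `logsumexp`; a 10⁻¹⁰ relative tie tolerance in the exact
test; equal-density clustering ties split at the prefix boundary; nearest
neighbours tie toward the smaller coordinate; sign-fixed SVD; empty
signatures, empty TF sets, constant expression vectors and one-level
covariates are tolerated with logged tallies rather than errors. Simulation
problem sizes in the test and acceptance studies (e.g. 5 000 null peaks at
20 vs 20 for calibration, 200 random instances for the clustering oracle,
1 000 replicate cohorts for clinical calibration, the 2 × 5 Mb default
cohort) were chosen so each study runs in seconds while the Monte-Carlo
error stays well inside the asserted bands.

## Known limitations

Common (not tagwise) dispersion; no paired-sample or covariate-adjusted
models; randomized-peak controls preserve length but not GC or gene
density; `run_all` orchestrates simulated cohorts only, with the stage
subcommands serving external inputs; clustering at extremely deep single
sites inherits the threshold-sweep semantics described above, which differs
from a naive "report every leaf" reading.
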