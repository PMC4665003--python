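# ltrcage

Promoter-centric analysis of CAGE (Cap Analysis of Gene Expression) data for
tumor cohorts, with a focus on transcription from retroviral long terminal
repeats (LTRs). Hepatocellular carcinoma tumors aberrantly reactivate
LTR-embedded promoters that are silent in normal liver; `ltrcage`
re-implements the full promoter workflow that detects and characterises this
signal, from single-nucleotide transcription start site (CTSS) tags to a
clinical stratification of patients — and ships a synthetic-cohort generator
with planted ground truth so that every stage is testable end to end.

The pipeline stages:

1. **TSS clustering** — Paraclu-style density clustering of pooled CTSS
   counts. For a run of tag sites, density = tags / span; each run is
   recursively split at its minimum-density proper prefix or suffix, and a
   cluster is characterised by the density at which it becomes maximal
   (`d_form`) and the density at which it splits (`d_break`). Reported peaks
   need ≥ 10 tags, span ≤ 500 bp and `d_break / d_form ≥ 2`, then are
   quantified per sample in tpm (tags per million uniquely mapped tags) and
   filtered to a working set (> 1 tpm in ≥ 1 tumor, ≥ 1 tag in ≥ 2 tumors).
2. **Peak taxonomy** — *coding* (sense overlap with a protein-coding TSS
   ± 100 bp), *proximal* (summit within 5 kb of a coding peak, or coding-exon
   overlap), *distal* (the ncRNA candidates), plus distance spectra,
   bidirectionality profiles, neighbor correlations and atlas breadth.
3. **Differential expression** — a negative-binomial conditional exact test
   (variance μ + φμ²) for tumor vs nontumor: library sizes equalized to the
   geometric mean, one common dispersion by conditional maximum likelihood,
   per-peak two-sided exact p ("sum of smaller likelihoods"), BH FDR and an
   up-regulated call at FDR < 0.05.
4. **Repeat enrichment** — strand-aware overlap of distal peaks with a
   RepeatMasker-style catalog; sense/antisense × up/non-up contingencies with
   one-sided Fisher tests; randomized-peak controls; per-subfamily activation
   vs genomic copy number (hypergeometric); relative-position histograms
   along elements and metaelement tag profiles on long LINEs.
5. **Signature & stratification** — stringent signature selection
   (FDR < 10⁻¹⁰, fold > 8, expressed in ≥ 30 tumors), UPGMA clustering of
   log₁₀(tpm + 0.005) signature profiles into LTR-high / intermediate / low
   strata, PCA, and a forest-plot style odds-ratio analysis of clinical
   covariates (Fisher tests, Woolf CIs, BH FDR, Cochran's Q heterogeneity).
6. **Regulatory integration** — activity calls in a reference cell line
   (≥ 1 CAGE tag + open chromatin within 1 kb), chromatin-state summaries,
   TF-binding association in a −600..+400 bp window (one-sided Fisher,
   Bonferroni) and the TF cobinding network (edges at Jaccard > 0.5, maximal
   cliques).

## Worked example

Run the whole pipeline on a simulated cohort (two 5-Mb chromosomes, 200
genes, eight repeat subfamilies with 60 activated LTR copies, 20 tumor /
20 nontumor / 5 normal samples):

```bash
ltrcage run --simulate --seed 7 --outdir out/
# completed 9 stages; manifest at out/manifest.json
```

Inspect the LTR-sense enrichment among up-regulated distal peaks:

```bash
python - <<'PY'
import pandas as pd
t = pd.read_csv("out/repeat_enrichment.tsv", sep="\t")
print(t[t.family == "LTR"][["orientation", "frac_up", "frac_nonup",
                            "odds_ratio", "p_fisher"]].to_string(index=False))
PY
```

```
orientation  frac_up  frac_nonup  odds_ratio     p_fisher
      sense      0.5    0.059072   15.928571 1.337494e-21
  antisense      0.0    0.000000    1.938776 1.000000e+00
```

Half of the up-regulated distal peaks sit inside LTR elements in sense
orientation versus ~6% of the non-up peaks — the planted retroviral promoter
activation, recovered with an odds ratio of 16. `out/signature.tsv` lists the
signature peaks (named `LTR-001`, `LTR-002`, … in ascending FDR),
`out/strata.tsv` assigns every sample to the high/intermediate/low stratum,
and `out/clinical.tsv` holds the covariate odds-ratio table behind
`out/forest.png`.

Each stage is also exposed separately (`ltrcage simulate`, `cluster`,
`classify`, `diff`, `repeats`) for running on externally supplied CTSS
tracks, annotations and repeat catalogs, and as plain library functions
(`ltrcage.clustering.paraclu_cluster`, `ltrcage.diffexp.nb_exact_test`, …).

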