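# moderseq

Desk-scale reimplementation of the computational analyses behind a mouse
genetics study of SEC24A, the COPII inner-coat cargo adaptor whose loss
lowers plasma cholesterol by blocking PCSK9 secretion.  The package covers
the study's full statistical tool chain and ships seeded synthetic-data
generators so every stage can be exercised and validated without the
original (undeposited) sequencing data:

- **Two-pass RPKM quantification** — unique and splice reads are tallied on
  gene-model exon unions, multireads are apportioned across candidate genes
  in proportion to first-pass RPKM, and read clusters within 20 kb of a gene
  are absorbed into its model before the final RPKM
  (RPKM = reads x 10^9 / (exonic length x mapped reads)).
- **Intensity-moderated variance DE test** — per-gene log2-expression
  variance is modeled as a smooth function of average intensity A via
  tricube-weighted local regression; on the Fisher's-Z scale the trend acts
  as an empirical-Bayes prior with degrees of freedom d0 recovered from the
  trigamma moment equation, giving the shrunk variance
  `s~²_g = (d0·s0²(A_g) + d_g·s²_g) / (d0 + d_g)`,
  z-scores, normal or t(d0+d_g) p-values, Benjamini–Hochberg FDR, and
  fold-change / FDR / RPKM-floor calls.
- **Exon-level splicing screen** — per exon, Fisher's exact test on the
  (exon vs rest-of-gene) x (condition 1 vs 2) table, BH-adjusted genome-wide.
- **Genetics statistics** — Pearson chi-square goodness-of-fit of genotype
  counts to Mendelian ratios, and pooled/Welch two-sample t-tests computed
  directly from published group summaries (mean ± sd or sem, n).

## Worked example

```python
>>> from moderseq.datasets import INTERCROSS_COUNTS, EPISTASIS_COMPARISONS
>>> from moderseq.genetics_stats import chi_square_gof, t_from_summary
>>> r = chi_square_gof(INTERCROSS_COUNTS["sec24a_gt_intercross"])
>>> round(r.statistic, 4), round(r.p, 3)
(0.1667, 0.92)
```

The heterozygote intercross (36 / 70 / 38 offspring against 1:2:1) gives
chi² = 1/6 on 2 df, p = 0.92 — segregation is Mendelian, so SEC24A loss does
not impair viability.  The cholesterol epistasis test on the Apoe-null
background:

```python
>>> res = t_from_summary(*EPISTASIS_COMPARISONS["apoe_null"], variant="welch")
>>> round(res.statistic, 3), round(res.p, 2)
(-0.262, 0.8)
```

272 ± 13 (n=8) vs 277 ± 14 mg/dl (n=7, sem) are indistinguishable (p ≈ 0.8):
Apoe is epistatic to Sec24a, placing SEC24A upstream of receptor-mediated
lipoprotein clearance.

For the sequencing side, an end-to-end run on simulated data:

```sh
moderseq run --seed 7 --outdir run7        # simulate -> de -> splicing -> report
moderseq cross --counts crosses.tsv --out mendelian.tsv
moderseq ttest --groups groups.tsv --variant pooled --out ttests.tsv
```

The numbered scripts under `analysis/` reproduce each piece with a short
narrative (`python analysis/01_mendelian_segregation.py`, ...), writing
their tables under `results/`.

## Layout

- `src/moderseq/` — the library: `io_formats`, `synthetic_data`, `quantify`,
  `de_moderated`, `exon_splicing`, `genetics_stats`, `calibration`,
  `pipeline`, `cli`, plus `datasets` (the published study tables).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite with brute-force oracles (exact Fisher
  enumeration, literal BH step-up, trigamma bisection, multinomial Monte
  Carlo).
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
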