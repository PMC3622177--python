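# Methods

## Scope and coordinates

The package reimplements, as a tested pipeline, the statistics of a mouse
study of the COPII adaptor SEC24A: RNA-seq quantification and differential
expression of wild-type vs Sec24a-null liver, an exon-level splicing
screen, Mendelian segregation tests, and phenotype t-tests from group
summaries.  All genomic coordinates are 0-based half-open internally; the
GTF-lite reader converts from 1-based inclusive on ingest.  Strand is
carried on gene models but read–gene overlap is coordinate-only (the
counting protocol predates reliable strand-aware handling; a stranded mode
is deliberately not offered).

## Two-pass RPKM quantification

Pass 1 records unique and splice reads on each gene's exon union;
RPKM = reads x 10^9 / (exonic length in bp x total mapped reads).  A read
overlapping several models is assigned to the gene with the largest exon
overlap (ties to the smaller gene_id): the alternative — crediting every
overlapped gene — would break the invariant that each read contributes
total weight exactly 1, which the pipeline maintains to 1e-9 relative
tolerance.  Reads on no model are clustered into candidate regions (merge
gap 500 bp, configurable); regions within 20 kb of a gene's span (distance
between closest interval ends, ties broken lexicographically for
determinism) are absorbed into the nearest gene, extending its effective
length and read tally.  Pass 2 splits each multiread across its candidate
genes in proportion to first-pass RPKM — the simplest faithful reading of
"weights computed during the first pass" — with a uniform split when all
candidates are at zero.  The default is exactly two passes; `--iterations`
repeats the reweighting with the previous final RPKM, which converges
toward winner-take-more apportionment.  With no multireads and no candidate
regions the two-pass output equals the single pass bit-exactly.

## Intensity-moderated variance test

Expression is tested on x = log2(RPKM + c), c = 0.25 RPKM by default
(config-exposed; the value only matters below ~1 RPKM).  Let A_g be the
per-gene mean of x.  Two variance modes are provided because the
unreplicated case needs one:

- **trend_only** (works at 1 vs 1): all unordered between-sample
  differences d feed a tricube-weighted local linear regression of |d| on
  A (span 0.4, 2 robustness iterations; statsmodels lowess).  Fitted E|d|
  converts to a difference-scale sd via sigma = E|d|·sqrt(pi/2), exact for
  centered normal d, floored at 1e-4; the per-observation variance is
  sigma²/2 since a difference of two observations carries twice the
  per-observation variance.  Using cross-condition pairs is justified by
  the working assumption that few genes are truly differentially
  expressed; a within-only flag exists for replicated designs.
- **moderated** (default with replicates): the pooled within-condition
  sample variance s²_g with d_g = n1+n2−2 residual df is mapped to the
  Fisher's-Z scale, e_g = log s²_g − psi(d_g/2) + log(d_g/2), an unbiased
  estimate of log sigma²_g under normality.  A lowess trend of e_g on A_g
  gives the intensity-dependent prior location; the prior df solve the
  moment equation mean[(e − ê)²] − psi'(d_g/2) = psi'(d0/2) via Newton on
  the trigamma inverse (d0 = +inf when the residual spread does not exceed
  the sampling variance, i.e. a pure trend).  Zero-variance genes are
  excluded from fitting and reinstated at shrinkage.  The posterior
  variance is s~² = (d0·s0²(A) + d_g·s²)/(d0+d_g).

z = (x̄₂ − x̄₁)/sqrt(s~²(1/n1+1/n2)).  The default reference is the
standard normal, matching the method's "z-scores"; a t reference with
d0+d_g df is provided and is the calibrated choice — on null simulations
its type-I error is near-nominal (~0.035 at alpha 0.05) while the normal
reference is measurably anti-conservative (~0.04–0.07 here; documented,
bounded below 0.12 in testing).  BH adjustment is the step-up rule
implemented directly (and checked against a brute-force double-loop oracle
and statsmodels).  Multiple testing is filter-then-test: only genes whose
larger condition-mean RPKM exceeds the floor (default 0.1; the source
material prints both 0.1 and 0.2 — the discrepancy is documented, not
resolved, and the value is configurable) enter the adjustment.  Calls are
strict inequalities: up/down requires q < 0.05, |log2 fold change| >
log2(2), and floor passage; fold changes are reported in both directions
(cond2/cond1 and its negation) to keep signs unambiguous.

### Depth dependence of the prior df

d0 estimation assumes s²_g·d_g/sigma²_g is chi-square.  At very low counts
that assumption fails (counts are discrete, and at fixed A genes with
different lengths carry different counts), inflating the residual spread
and driving d̂0 down, which fattens the t tails and costs power.  At the
library sizes the generator emulates (see below) the effect is confined to
a small low-count tail and d̂0 is large; at severely shallow depth (tens of
reads per gene) d̂0 drops to ~5 and sensitivity degrades.  This is a
property of the method on count data, not of the implementation, and is
the reason count-based precision-weight methods were later developed.

## Exon-level splicing screen

Per-exon read counts are summed per condition; for each exon of each
multi-exon gene a 2x2 table (this exon vs rest of gene) x (condition 1 vs
2) is tested with Fisher's exact test (conditional hypergeometric,
probability-mass two-sided rule — scipy's implementation, checked against
an exact-rational enumeration oracle over every table with total <= 30).
The exon-vs-rest construction is the minimal reading of "changes in
expression ratios across exons"; a whole-gene exon x condition chi-square
screen is available behind a flag.  Tables with total below 10 (config)
are skipped; BH runs genome-wide over all tested exons.  Fisher p-values
on discrete tables are conservative (no mid-p), so the null p distribution
sits below uniform — tests check one-sided non-anticonservatism.
Reads spanning an exon junction credit the exon with the larger overlap
(ties to the lower index).

## Genetics statistics

Chi-square goodness-of-fit is plain Pearson (no continuity correction),
df = classes − 1, upper-tail p; expected cells below 1 warn.  t-tests from
summaries: `±` values declared sd feed the pooled test (the reading that
reproduces the published blood-count p-values of 0.85 / 0.02 / 0.001 /
0.38); `±` values declared sem (as in the cholesterol figures, whose error
bars are sem) are converted via sd = sem·sqrt(n) and feed Welch by
default.  Two published rows (hemoglobin and hematocrit) do not reproduce
exactly under any single consistent variant and are excluded from the
validated set, as is the litter-size comparison whose sd/sem reading is
indeterminate.

## Synthetic data

One integer seed drives everything; sub-streams are keyed by a CRC-32 hash
of (seed, purpose) so adding a generator never perturbs existing draws.

- **Counts**: gene mean expression is log-normal on the log2 scale,
  location 8, scale 2 — median ~256, mean ~670 expected counts per gene,
  i.e. ~13M mapped reads at 20,000 genes, a typical single-lane liver
  mRNA-seq library of the emulated platform.  Counts are negative binomial
  with var = mu + phi(mu)·mu², phi(mu) = a0 + a1/mu (defaults 0.05 and 2),
  so log-scale variance falls with expression as the method assumes;
  a0 = a1 = 0 recovers Poisson.  A fraction pi_de of genes (default
  0.0015, ~30 of 20,000) receives a log2 fold change of magnitude
  ~N(2, 0.5), sign ±.  Gene lengths are log-normal (median 2 kb); RPKM is
  computed from counts, lengths and per-sample totals.  Default design 2
  vs 2; 1 vs 1 supported.
- **Exon reads**: per-gene exon proportions are Dirichlet; null genes use
  identical proportions in both conditions, differential genes shift one
  exon's proportion upward (siblings rescaled on the simplex — so sibling
  exons of a shifted gene are genuinely differential too).
- **Multireads**: homologous gene pairs emit a configurable shared
  fraction of reads as two-candidate multi records; totals are conserved
  read-by-read.
- **Crosses / groups**: multinomial genotype draws and normal phenotype
  draws matching target summaries.

What the generators do not emulate: positional/GC bias, isoform structure
within genes, correlated genes, batch effects, and library-composition
effects that make RPKM comparisons biased in real data.  Passing tests
therefore demonstrate correctness of the statistical machinery under its
own model, not robustness to those artefacts.

## Numerical choices

Local regression: statsmodels lowess, tricube weights, local linear, span
0.4, 2 robustness iterations, interpolation speed-up delta = 1% of the
x-range above 200 points, constant extrapolation beyond the fitted range.
Trigamma inverse: Newton from x = 0.5 + 1/y with asymptotic shortcuts for
y outside [1e-6, 1e7], tolerance 1e-10, max 50 iterations (checked against
geometric bisection).  BH uses a stable sort so ties share treatment.
Degenerate zero-variance genes: p = 0 if the condition means differ, 1
otherwise, flagged.  -log10(p) is capped at 320 in volcano tables.
Multiread weights are renormalized to sum to 1 exactly.

## Pipeline and determinism

`run_pipeline` executes simulate/ingest -> quantify -> de -> splicing ->
report; unknown config keys are rejected before any computation; partial
outputs are quarantined until every stage succeeds; the manifest records
version, resolved parameters, seed, and SHA-256 checksums of inputs and
outputs.  No timestamps are written, so identical config + inputs produce
byte-identical outputs.  Multi-sample alignment TSVs carry sample identity
as a `<sample>:<read>` read_id prefix.

## Problem sizes

The calibration battery (used by the tests and the acceptance script)
runs 20-seed replicates of 5,000-gene experiments for type-I error, FDP
and sensitivity, and a 10,000-gene hierarchical simulation for prior-df
recovery — sizes at which the binomial error of the measured rates is
well inside the tested bands and the battery completes in seconds.
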