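"""Seeded generators for every input the pipeline consumes.

Each generator emulates one facet of a two-condition liver RNA-seq
experiment: negative-binomial gene counts with an expression-dependent
variance trend and a small fraction of true DE genes, per-exon read tables
with optional differential usage, multiread groups between homologous gene
pairs, multinomial genotype draws from intercrosses, and normal phenotype
groups.  All generators are pure functions of (config, seed); sub-streams
are derived by stable hashing of (seed, purpose) so adding a generator never
perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, CrossCounts, ExpressionMatrix, GeneModel, GroupSummary


def substream(seed: int, purpose: str) -> np.random.Generator:
    """Independent RNG stream keyed by a stable hash of (seed, purpose)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(purpose.encode())])


@dataclass
class CountSimConfig:
    """Study conditions for the gene-count simulator.

    Defaults mirror the modeled experiment: ~20,000 transcripts, 2 vs 2
    design, NB variance trend var = mu + phi(mu) mu^2 with
    phi(mu) = a0 + a1/mu, and a small fraction of true DE genes
    (~30 of 20,000) with |log2 fold change| around 2.
    """

    n_genes: int = 20_000
    design: tuple[int, int] = (2, 2)
    mean_log_expr_dist: tuple[float, float] = (8.0, 2.0)
    dispersion_trend: tuple[float, float] = (0.05, 2.0)
    pi_de: float = 0.0015
    lfc_dist: tuple[float, float] = (2.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        a0, a1 = self.dispersion_trend
        if not 0.0 <= self.pi_de <= 1.0:
            raise ValueError("pi_de must lie in [0, 1]")
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion trend coefficients must be non-negative")
        if min(self.design) < 1:
            raise ValueError("each condition needs at least one sample")
        if self.pi_de > 0 and self.lfc_dist[0] == 0 and self.lfc_dist[1] == 0:
            raise ValueError("pi_de > 0 requires a non-degenerate lfc_dist")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """NB draw with var = mu + phi(mu) mu^2, phi = a0 + a1/mu (Poisson if phi=0)."""
    mu = np.asarray(mu, dtype=float)
    phi = a0 + np.divide(a1, mu, out=np.zeros_like(mu), where=mu > 0)
    out = np.empty_like(mu)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(cfg: CountSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a gene x sample count/RPKM matrix plus its ground truth.

    Returns ``(ExpressionMatrix, truth)`` where truth has columns gene_id,
    is_de, true_lfc, true_mean (mean expected count across conditions).
    Gene lengths are log-normal with median 2 kb; RPKM is computed from the
    simulated counts and per-sample totals.
    """
    rng = substream(cfg.seed, "counts")
    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    loc, scale = cfg.mean_log_expr_dist
    mu_base = np.exp2(rng.normal(loc, scale, size=n))
    is_de = rng.random(n) < cfg.pi_de
    mag = np.abs(rng.normal(cfg.lfc_dist[0], cfg.lfc_dist[1], size=n))
    sign = rng.choice([-1.0, 1.0], size=n)
    true_lfc = np.where(is_de, sign * mag, 0.0)
    # degenerate draws of magnitude exactly 0 would break is_de <=> lfc != 0
    true_lfc[is_de & (true_lfc == 0.0)] = 1e-6

    n1, n2 = cfg.design
    samples = [f"wt_{i + 1}" for i in range(n1)] + [f"mut_{i + 1}" for i in range(n2)]
    design = pd.Series(["cond1"] * n1 + ["cond2"] * n2, index=samples, name="condition")
    a0, a1 = cfg.dispersion_trend
    counts = np.empty((n, n1 + n2))
    for j in range(n1 + n2):
        mu = mu_base if j < n1 else mu_base * np.exp2(true_lfc)
        counts[:, j] = _nb_draw(rng, mu, a0, a1)

    lengths = rng.lognormal(mean=np.log(2000.0), sigma=0.6, size=n)
    totals = counts.sum(axis=0)
    rpkm = counts * 1e9 / (lengths[:, None] * totals[None, :])

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    rpkm_df = pd.DataFrame(rpkm, index=gene_ids, columns=samples)
    totals_s = pd.Series(totals.astype(np.int64), index=samples, name="total_mapped_reads")
    expr = ExpressionMatrix(rpkm_df, counts_df, design, totals_s)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_de": is_de,
        "true_lfc": true_lfc,
        "true_mean": mu_base * (1.0 + np.exp2(true_lfc)) / 2.0,
        "length": lengths,
    })
    return expr, truth


def simulate_exon_reads(
    n_genes: int,
    exons_per_gene: int,
    depth: float,
    differential_exon_fraction: float,
    usage_shift: float,
    seed: int,
    design: tuple[int, int] = (2, 2),
    exon_length: int = 200,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Per-exon count tables under null or shifted exon usage.

    Null genes draw exon counts multinomially with the same exon-proportion
    vector in both conditions; a ``differential_exon_fraction`` of genes
    shifts one exon's proportion upward by ``usage_shift`` in condition 2
    (the other exons rescaled to keep the vector on the simplex).

    Returns (gene models, exon x sample counts indexed by (gene_id,
    exon_index), truth with columns gene_id, is_differential, shifted_exon).
    """
    if exons_per_gene < 2:
        raise ValueError("exons_per_gene must be >= 2")
    if not 0.0 <= differential_exon_fraction <= 1.0:
        raise ValueError("differential_exon_fraction must lie in [0, 1]")
    rng = substream(seed, "exon-reads")
    n1, n2 = design
    samples = [f"wt_{i + 1}" for i in range(n1)] + [f"mut_{i + 1}" for i in range(n2)]
    models: list[GeneModel] = []
    rows = []
    truth_rows = []
    counts = np.zeros((n_genes * exons_per_gene, n1 + n2), dtype=np.int64)
    offset = 0
    for g in range(n_genes):
        gid = f"g{g:05d}"
        start = offset
        exons = tuple((start + i * (exon_length + 100), start + i * (exon_length + 100) + exon_length)
                      for i in range(exons_per_gene))
        offset = exons[-1][1] + 5000
        models.append(GeneModel(gid, "chrS", "+", exons))
        props = rng.dirichlet(np.full(exons_per_gene, 5.0))
        is_diff = rng.random() < differential_exon_fraction
        shifted = -1
        props2 = props
        if is_diff and usage_shift > 0:
            shifted = int(rng.integers(exons_per_gene))
            target = min(props[shifted] + usage_shift, 0.95)
            props2 = props * (1.0 - target) / (1.0 - props[shifted])
            props2[shifted] = target
        for j in range(n1 + n2):
            p = props if j < n1 else props2
            total = rng.poisson(depth)
            counts[g * exons_per_gene:(g + 1) * exons_per_gene, j] = rng.multinomial(total, p)
        for i in range(exons_per_gene):
            rows.append((gid, i))
        truth_rows.append((gid, bool(is_diff and usage_shift > 0), shifted))
    table = pd.DataFrame(counts, columns=samples,
                         index=pd.MultiIndex.from_tuples(rows, names=["gene_id", "exon_index"]))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "is_differential", "shifted_exon"])
    return models, table, truth


def simulate_multireads(
    gene_pairs: int | Sequence[tuple[str, str]],
    shared_fraction: float,
    depth: int,
    seed: int,
    gene_length: int = 1000,
    expression_ratio: float = 1.0,
) -> tuple[list[GeneModel], list[AlignmentRecord]]:
    """Alignment tables for homologous gene pairs sharing multireads.

    Each pair emits ``depth`` reads from gene A and ``round(depth *
    expression_ratio)`` from gene B; each read independently becomes a multi
    record listing both genes with probability ``shared_fraction``, otherwise
    a unique record.  Every simulated read appears exactly once.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = substream(seed, "multireads")
    if isinstance(gene_pairs, int):
        pair_ids = [(f"pair{i}_a", f"pair{i}_b") for i in range(gene_pairs)]
    else:
        pair_ids = list(gene_pairs)
    models: list[GeneModel] = []
    records: list[AlignmentRecord] = []
    offset = 0
    read_no = 0
    for ga, gb in pair_ids:
        a = GeneModel(ga, "chrM", "+", ((offset, offset + gene_length),))
        b = GeneModel(gb, "chrM", "+", ((offset + gene_length + 50_000,
                                         offset + 2 * gene_length + 50_000),))
        offset += 2 * gene_length + 100_000
        models.extend([a, b])
        for gene, other, n_reads in ((a, b, depth), (b, a, int(round(depth * expression_ratio)))):
            gs, ge = gene.span
            starts = rng.integers(gs, ge - 50, size=n_reads)
            shared = rng.random(n_reads) < shared_fraction
            for s, is_multi in zip(starts, shared):
                read_no += 1
                if is_multi:
                    hits = tuple(sorted((gene.gene_id, other.gene_id)))
                    records.append(AlignmentRecord(f"r{read_no}", "chrM", int(s), int(s) + 50,
                                                   "multi", hits))
                else:
                    records.append(AlignmentRecord(f"r{read_no}", "chrM", int(s), int(s) + 50,
                                                   "unique", (gene.gene_id,)))
    return models, records


def simulate_cross(n_offspring: int, expected_ratio: Sequence, seed: int,
                   labels: Sequence[str] | None = None) -> CrossCounts:
    """Multinomial genotype draw from an intercross; observed sums to n."""
    rng = substream(seed, "cross")
    ratio = [Fraction(r) for r in expected_ratio]
    total = sum(ratio, Fraction(0))
    probs = np.array([float(r / total) for r in ratio])
    observed = rng.multinomial(n_offspring, probs)
    if labels is None:
        labels = [f"geno{i + 1}" for i in range(len(ratio))]
    return CrossCounts(tuple(labels), tuple(int(o) for o in observed), tuple(ratio))


def simulate_groups(specs: Sequence[GroupSummary], seed: int) -> dict[str, np.ndarray]:
    """Normal draws matching each GroupSummary target (mean, sd, n)."""
    rng = substream(seed, "groups")
    out: dict[str, np.ndarray] = {}
    for spec in specs:
        out[spec.label] = rng.normal(spec.mean, spec.sd, size=spec.n)
    return out
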