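"""Exon-level differential-splicing screen.

For each exon of each gene, a 2x2 table of (this exon vs rest of gene) by
(condition 1 vs condition 2) read counts is tested with Fisher's exact
test; p-values are Benjamini-Hochberg adjusted genome-wide across all
tested exons.  An alternative whole-gene exon x condition chi-square screen
is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .de_moderated import bh_adjust
from .io_formats import AlignmentRecord, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 10


def build_exon_tables(
    alignments: Iterable[AlignmentRecord],
    gene_models: Sequence[GeneModel],
    design: pd.Series,
) -> pd.DataFrame:
    """Exon x sample read counts, indexed by (gene_id, exon_index).

    A read increments the exon it overlaps by >= 1 bp; a read spanning two
    exons is credited to the exon with the larger overlap (ties to the
    lower exon index, then the smaller gene_id).  Genes whose counts are
    all zero are excluded (logged).  Sample columns follow ``design``.
    """
    trees: dict[str, IntervalTree] = {}
    for m in gene_models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for i, (s, e) in enumerate(m.exons):
            tree.addi(s, e, (m.gene_id, i))
    samples = list(design.index)
    sample_pos = {s: j for j, s in enumerate(samples)}
    index = pd.MultiIndex.from_tuples(
        [(m.gene_id, i) for m in gene_models for i in range(len(m.exons))],
        names=["gene_id", "exon_index"])
    row_pos = {key: r for r, key in enumerate(index)}
    counts = np.zeros((len(index), len(samples)), dtype=np.int64)
    for rec in alignments:
        if rec.read_class == "multi":
            continue
        sample = rec.read_id.rsplit(":", 1)[0] if ":" in rec.read_id else None
        # sample identity is carried as a 'sample:read' read_id prefix when
        # present; otherwise all reads fall in the first sample
        j = sample_pos.get(sample, 0)
        tree = trees.get(rec.chrom)
        hits = tree.overlap(rec.start, rec.end) if tree is not None else ()
        if not hits:
            continue
        best = min(hits, key=lambda iv: (-(min(iv.end, rec.end) - max(iv.begin, rec.start)),
                                         iv.data[1], iv.data[0]))
        counts[row_pos[best.data], j] += 1
    df = pd.DataFrame(counts, index=index, columns=samples)
    zero = df.groupby(level="gene_id", sort=False).sum().sum(axis=1) == 0
    if zero.any():
        logger.info("%d genes with all-zero exon counts excluded from testing",
                    int(zero.sum()))
        df = df[~df.index.get_level_values("gene_id").isin(zero[zero].index)]
    return df


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    p is the conditional hypergeometric probability-mass rule: the sum of
    probabilities of all tables with the same margins whose probability does
    not exceed the observed table's (to 1e-7 relative tolerance).  The odds
    ratio is the sample value ad/bc (+inf when bc = 0 and ad > 0; 1 when
    both products are 0).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = 1.0 if ad == 0 else np.inf
    else:
        odds = ad / bc
    return float(odds), float(p)


@dataclass
class SplicingResult:
    gene_id: str
    exon_index: int
    exon_cond1: int
    rest_cond1: int
    exon_cond2: int
    rest_cond2: int
    odds_ratio: float
    p: float
    q: float = np.nan


def test_exon_usage(
    tables: pd.DataFrame,
    design: pd.Series,
    min_total: int = DEFAULT_MIN_TOTAL,
    method: str = "exon_vs_rest",
) -> pd.DataFrame:
    """Differential exon usage across two conditions.

    ``exon_vs_rest`` (default): per exon, Fisher's exact test on
    [[exon_c1, rest_c1], [exon_c2, rest_c2]]; exons with grand total below
    ``min_total`` are skipped; BH adjustment is genome-wide over all tested
    exons.  ``gene_chi2``: per gene, a chi-square test of the full
    exon x condition table (one row per gene in the output, exon_index -1).
    """
    conds: list[str] = []
    for c in design:
        if c not in conds:
            conds.append(c)
    if len(conds) != 2:
        raise ValueError("exon usage testing expects exactly two conditions")
    s1 = [s for s in tables.columns if design[s] == conds[0]]
    s2 = [s for s in tables.columns if design[s] == conds[1]]
    cond_counts = pd.DataFrame({
        "c1": tables[s1].sum(axis=1),
        "c2": tables[s2].sum(axis=1),
    })
    rows: list[SplicingResult] = []
    if method == "exon_vs_rest":
        for gid, sub in cond_counts.groupby(level="gene_id", sort=False):
            if len(sub) < 2:
                raise RuntimeError(f"single-exon gene {gid!r} reached exon testing")
            tot1, tot2 = int(sub["c1"].sum()), int(sub["c2"].sum())
            for (gene, exon_i), row in sub.iterrows():
                a, c = int(row["c1"]), int(row["c2"])
                b, d = tot1 - a, tot2 - c
                if a + b + c + d < min_total:
                    continue
                odds, p = fisher_exact_2x2(a, b, c, d)
                rows.append(SplicingResult(gene, int(exon_i), a, b, c, d, odds, p))
    elif method == "gene_chi2":
        for gid, sub in cond_counts.groupby(level="gene_id", sort=False):
            if len(sub) < 2:
                raise RuntimeError(f"single-exon gene {gid!r} reached exon testing")
            table = sub.to_numpy()
            if table.sum() < min_total or (table.sum(axis=0) == 0).any():
                continue
            keep = table.sum(axis=1) > 0
            res = stats.chi2_contingency(table[keep])
            rows.append(SplicingResult(gid, -1, int(sub["c1"].sum()), 0,
                                       int(sub["c2"].sum()), 0, np.nan,
                                       float(res.pvalue)))
    else:
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame([r.__dict__ for r in rows],
                      columns=list(SplicingResult.__dataclass_fields__))
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df
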