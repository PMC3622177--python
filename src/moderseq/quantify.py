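"""Two-pass RPKM quantification with multiread apportionment.

Pass 1 records unique and splice reads on the gene-model exon unions and
computes a first-pass RPKM.  Multireads are then apportioned across their
candidate genes in proportion to those first-pass values, candidate regions
(read clusters outside any model) within 20 kb of a gene are absorbed into
it, and a final RPKM is computed over the expanded models.

Read conservation holds throughout: each unique/splice read contributes
weight exactly 1 to one gene (largest exon overlap; ties to the smaller
gene_id) or to one candidate region, and each multiread's weights sum to 1
over its candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AlignmentRecord, CandidateRegion, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_REGION_RADIUS_BP = 20_000
DEFAULT_CLUSTER_GAP_BP = 500


@dataclass
class GeneReadTally:
    """Per-gene read bookkeeping across the two passes."""

    gene_id: str
    unique_reads: int = 0
    splice_reads: int = 0
    multiread_weight: float = 0.0
    region_reads: int = 0
    exonic_length: int = 0
    effective_length: int = 0

    @property
    def total_reads(self) -> float:
        return self.unique_reads + self.splice_reads + self.multiread_weight + self.region_reads


@dataclass
class MultireadGroup:
    """One multiread with its candidate genes and (second-pass) weights."""

    read_id: str
    candidate_genes: tuple[str, ...]
    weights: tuple[float, ...] | None = None


def _exon_trees(models: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for s, e in m.exons:
            tree.addi(s, e, m.gene_id)
    return trees


def _cluster_regions(unassigned: dict[str, list[tuple[int, int]]],
                     gap_bp: int) -> list[CandidateRegion]:
    regions: list[CandidateRegion] = []
    for chrom in sorted(unassigned):
        ivs = sorted(unassigned[chrom])
        cur_s, cur_e, cur_n = ivs[0][0], ivs[0][1], 1
        for s, e in ivs[1:]:
            if s - cur_e <= gap_bp:
                cur_e = max(cur_e, e)
                cur_n += 1
            else:
                regions.append(CandidateRegion(chrom, cur_s, cur_e, cur_n))
                cur_s, cur_e, cur_n = s, e, 1
        regions.append(CandidateRegion(chrom, cur_s, cur_e, cur_n))
    return regions


def tally_reads(
    alignments: Iterable[AlignmentRecord],
    gene_models: Sequence[GeneModel],
    cluster_gap_bp: int = DEFAULT_CLUSTER_GAP_BP,
) -> tuple[dict[str, GeneReadTally], list[CandidateRegion], list[MultireadGroup]]:
    """First pass: count unique/splice reads on exon unions.

    A unique/splice read is credited to the overlapping gene (>= 1 bp of
    exon-union overlap; among several, the gene with the largest overlap,
    ties to the smaller gene_id).  Reads overlapping no model are clustered
    into CandidateRegions (reads within ``cluster_gap_bp`` merge).  Multi
    records become MultireadGroups over their listed candidates present in
    the model set; weights are left unset.
    """
    model_ids = {m.gene_id for m in gene_models}
    trees = _exon_trees(gene_models)
    tallies = {m.gene_id: GeneReadTally(m.gene_id, exonic_length=m.exonic_length,
                                        effective_length=m.exonic_length)
               for m in gene_models}
    unassigned: dict[str, list[tuple[int, int]]] = {}
    groups: list[MultireadGroup] = []
    n_orphans = 0
    for rec in alignments:
        if rec.read_class == "multi":
            candidates = tuple(sorted({h for h in rec.hits if h in model_ids}))
            if not candidates:
                n_orphans += 1
                unassigned.setdefault(rec.chrom, []).append((rec.start, rec.end))
                continue
            groups.append(MultireadGroup(rec.read_id, candidates))
            continue
        tree = trees.get(rec.chrom)
        hits = tree.overlap(rec.start, rec.end) if tree is not None else ()
        if not hits:
            unassigned.setdefault(rec.chrom, []).append((rec.start, rec.end))
            continue
        overlap_by_gene: dict[str, int] = {}
        for iv in hits:
            ov = min(iv.end, rec.end) - max(iv.begin, rec.start)
            overlap_by_gene[iv.data] = overlap_by_gene.get(iv.data, 0) + ov
        gene = min(overlap_by_gene, key=lambda g: (-overlap_by_gene[g], g))
        if rec.read_class == "splice":
            tallies[gene].splice_reads += 1
        else:
            tallies[gene].unique_reads += 1
    if n_orphans:
        logger.warning("%d multireads listed no candidate present in the model set; "
                       "treated as unassigned", n_orphans)
    regions = _cluster_regions(unassigned, cluster_gap_bp) if unassigned else []
    return tallies, regions, groups


def first_pass_rpkm(tallies: dict[str, GeneReadTally],
                    total_mapped_reads: float) -> dict[str, float]:
    """RPKM = (unique + splice) * 1e9 / (effective_length * total_mapped_reads)."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    out = {}
    for gid, t in tallies.items():
        if t.effective_length <= 0:
            raise ValueError(f"{gid}: non-positive effective length")
        out[gid] = (t.unique_reads + t.splice_reads) * 1e9 / (t.effective_length * total_mapped_reads)
    return out


def apportion_multireads(
    groups: Sequence[MultireadGroup],
    first_pass: dict[str, float],
    tallies: dict[str, GeneReadTally] | None = None,
) -> list[MultireadGroup]:
    """Second pass: weight each multiread across candidates by first-pass RPKM.

    weight(g) = RPKM_g / sum over candidates; all-zero candidates share the
    read uniformly.  Weights are renormalized to sum to 1 exactly.  If
    ``tallies`` is given, per-gene multiread_weight totals are accumulated.
    """
    weighted: list[MultireadGroup] = []
    for grp in groups:
        if not grp.candidate_genes:
            logger.warning("multiread %s has no candidates; dropped", grp.read_id)
            continue
        vals = np.array([first_pass[g] for g in grp.candidate_genes], dtype=float)
        if (vals < 0).any():
            raise ValueError("negative first-pass RPKM")
        total = vals.sum()
        w = vals / total if total > 0 else np.full(len(vals), 1.0 / len(vals))
        w = w / w.sum()  # exact renormalization
        weighted.append(replace(grp, weights=tuple(w)))
        if tallies is not None:
            for g, wi in zip(grp.candidate_genes, w):
                tallies[g].multiread_weight += wi
    return weighted


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between closest ends of two half-open intervals (0 if they touch)."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return b[0] - a[1] if b[0] >= a[1] else a[0] - b[1]


def expand_gene_regions(
    gene_models: Sequence[GeneModel],
    candidate_regions: Sequence[CandidateRegion],
    tallies: dict[str, GeneReadTally],
    radius_bp: int = DEFAULT_REGION_RADIUS_BP,
) -> tuple[list[GeneModel], list[CandidateRegion]]:
    """Absorb candidate regions lying within ``radius_bp`` of a gene span.

    Each region goes to the nearest gene (ties to the smaller gene_id); its
    interval extends the gene's effective length and its reads join the
    gene's tally.  Regions beyond the radius of every gene are returned
    unassigned.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in gene_models:
        by_chrom.setdefault(m.chrom, []).append(m)
    absorbed: dict[str, list[tuple[int, int]]] = {}
    leftovers: list[CandidateRegion] = []
    for reg in candidate_regions:
        best: tuple[int, str] | None = None
        for m in by_chrom.get(reg.chrom, ()):
            d = _interval_distance(m.span, (reg.start, reg.end))
            if d < radius_bp and (best is None or (d, m.gene_id) < best):
                best = (d, m.gene_id)
        if best is None:
            leftovers.append(reg)
            continue
        gid = best[1]
        absorbed.setdefault(gid, []).append((reg.start, reg.end))
        tallies[gid].region_reads += reg.read_count
    expanded: list[GeneModel] = []
    for m in gene_models:
        if m.gene_id in absorbed:
            m2 = m.with_extra_intervals(absorbed[m.gene_id])
            tallies[m.gene_id].effective_length = m2.exonic_length
            expanded.append(m2)
        else:
            expanded.append(m)
    return expanded, leftovers


def final_rpkm(tallies: dict[str, GeneReadTally],
               total_mapped_reads: float) -> dict[str, float]:
    """Final RPKM over expanded models and apportioned multireads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return {gid: t.total_reads * 1e9 / (t.effective_length * total_mapped_reads)
            for gid, t in tallies.items()}


def quantify_sample(
    alignments: Sequence[AlignmentRecord],
    gene_models: Sequence[GeneModel],
    total_mapped_reads: float | None = None,
    radius_bp: int = DEFAULT_REGION_RADIUS_BP,
    cluster_gap_bp: int = DEFAULT_CLUSTER_GAP_BP,
    iterations: int = 1,
) -> pd.DataFrame:
    """Run the full two-pass quantification for one sample.

    ``total_mapped_reads`` defaults to the number of alignment records.
    ``iterations`` repeats the multiread reweighting using the previous
    final RPKM as weights (the default single reweighting reproduces the
    two-pass protocol).  Returns a per-gene DataFrame with the tally
    components, first-pass and final RPKM.
    """
    alignments = list(alignments)
    if total_mapped_reads is None:
        total_mapped_reads = len(alignments)
    tallies, regions, groups = tally_reads(alignments, gene_models, cluster_gap_bp)
    fp = first_pass_rpkm(tallies, total_mapped_reads)
    apportion_multireads(groups, fp, tallies)
    expanded, leftovers = expand_gene_regions(gene_models, regions, tallies, radius_bp)
    for _ in range(max(0, iterations - 1)):
        current = final_rpkm(tallies, total_mapped_reads)
        for t in tallies.values():
            t.multiread_weight = 0.0
        apportion_multireads(groups, current, tallies)
    final = final_rpkm(tallies, total_mapped_reads)
    rows = []
    for gid in sorted(tallies):
        t = tallies[gid]
        rows.append({
            "gene_id": gid,
            "unique_reads": t.unique_reads,
            "splice_reads": t.splice_reads,
            "multiread_weight": t.multiread_weight,
            "region_reads": t.region_reads,
            "exonic_length": t.exonic_length,
            "effective_length": t.effective_length,
            "first_pass_rpkm": fp[gid],
            "final_rpkm": final[gid],
        })
    df = pd.DataFrame(rows).set_index("gene_id")
    df.attrs["unassigned_regions"] = leftovers
    df.attrs["total_mapped_reads"] = total_mapped_reads
    return df
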