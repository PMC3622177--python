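"""Readers, writers and validated domain types for every external format.

All genomic coordinates are 0-based half-open internally (BED convention).
GTF-lite input, which is 1-based inclusive, is converted on ingest by
``start - 1``.  Strand is carried on gene models but read-gene overlap is
coordinate-only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

READ_CLASSES = ("unique", "splice", "multi")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals: sorted, overlap/abutment merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon structure; the unit of RPKM quantification.

    ``exons`` is stored as the union of the input exons (sorted,
    non-overlapping); ``exonic_length`` is the summed length of that union
    and is the denominator of the RPKM formula.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: strand must be one of + - . (got {self.strand!r})")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs at least one exon")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: malformed exon interval ({s}, {e})")
        object.__setattr__(self, "exons", merge_intervals(self.exons))

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def with_extra_intervals(self, intervals: Iterable[tuple[int, int]]) -> "GeneModel":
        return GeneModel(self.gene_id, self.chrom, self.strand,
                         tuple(self.exons) + tuple(intervals))


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read hit; ``hits`` lists candidate gene placements."""

    read_id: str
    chrom: str
    start: int
    end: int
    read_class: str
    hits: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: start >= end ({self.start}, {self.end})")
        if self.read_class not in READ_CLASSES:
            raise ValueError(f"{self.read_id}: unknown read_class {self.read_class!r}")
        if not self.hits:
            raise ValueError(f"{self.read_id}: empty hits list")
        if self.read_class in ("unique", "splice") and len(self.hits) != 1:
            raise ValueError(f"{self.read_id}: {self.read_class} read must have exactly one hit")


@dataclass(frozen=True)
class CandidateRegion:
    """A cluster of reads outside annotated models; may be absorbed by a gene."""

    chrom: str
    start: int
    end: int
    read_count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"candidate region start >= end ({self.start}, {self.end})")
        if self.read_count < 0:
            raise ValueError("candidate region read_count must be non-negative")


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM and (weighted) counts plus the sample design.

    ``design`` maps sample id -> condition label; ``total_mapped_reads`` is
    the per-sample library size used as the RPKM denominator.
    """

    rpkm: pd.DataFrame
    counts: pd.DataFrame
    design: pd.Series
    total_mapped_reads: pd.Series

    def __post_init__(self) -> None:
        if not self.rpkm.index.equals(self.counts.index) or not self.rpkm.columns.equals(self.counts.columns):
            raise ValueError("rpkm and counts matrices must share genes and samples")
        samples = list(self.rpkm.columns)
        if list(self.design.index) != samples or list(self.total_mapped_reads.index) != samples:
            raise ValueError("design and total_mapped_reads must cover exactly the matrix samples, in order")
        if (self.rpkm.to_numpy() < 0).any() or (self.counts.to_numpy() < 0).any():
            raise ValueError("negative entries in expression matrix")
        if (self.total_mapped_reads <= 0).any():
            raise ValueError("total_mapped_reads must be positive")
        excess = self.counts.sum(axis=0) - self.total_mapped_reads
        if (excess > 1e-6 * self.total_mapped_reads).any():
            raise ValueError("per-sample counts exceed total_mapped_reads")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.design.items() if c == condition]


@dataclass(frozen=True)
class CrossCounts:
    """Observed genotype counts from a cross plus the expected Mendelian ratio."""

    genotype_labels: tuple[str, ...]
    observed: tuple[int, ...]
    expected_ratio: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        k = len(self.genotype_labels)
        if k < 2 or len(self.observed) != k or len(self.expected_ratio) != k:
            raise ValueError("labels, observed and expected_ratio must align with >= 2 classes")
        if any(o < 0 for o in self.observed) or sum(self.observed) < 1:
            raise ValueError("observed counts must be non-negative and sum to >= 1")
        if any(r <= 0 for r in self.expected_ratio):
            raise ValueError("expected ratios must be positive")
        total = sum(self.expected_ratio, Fraction(0))
        object.__setattr__(self, "expected_ratio",
                           tuple(Fraction(r) / total for r in self.expected_ratio))


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one experimental group (mean +/- sd or sem, n)."""

    label: str
    mean: float
    dispersion: float
    dispersion_kind: str
    n: int

    def __post_init__(self) -> None:
        if self.dispersion_kind not in ("sd", "sem"):
            raise ValueError("dispersion_kind must be 'sd' or 'sem'")
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @property
    def sd(self) -> float:
        return self.dispersion * np.sqrt(self.n) if self.dispersion_kind == "sem" else self.dispersion


# ---------------------------------------------------------------------------
# gene models

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def _parse_gtf_lite(path: Path) -> dict[str, list]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            m = _GENE_ID_RE.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            s, e = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
            if s >= e:
                raise FormatError(f"{path}:{lineno}: malformed coordinates start >= end")
            g = genes.setdefault(gid, {"chrom": chrom, "strand": strand, "exons": []})
            if g["chrom"] != chrom:
                raise FormatError(f"{path}:{lineno}: gene {gid} spans multiple chromosomes")
            g["exons"].append((s, e))
    return genes


def _parse_bed12(path: Path) -> dict[str, dict]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED12 fields")
            chrom, chrom_start, chrom_end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if fields[5] in ("+", "-") else "."
            if chrom_start >= chrom_end:
                raise FormatError(f"{path}:{lineno}: malformed coordinates start >= end")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != len(starts) or len(sizes) != int(fields[9]):
                raise FormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
            exons = [(chrom_start + bs, chrom_start + bs + sz) for bs, sz in zip(starts, sizes)]
            if name in genes:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            genes[name] = {"chrom": chrom, "strand": strand, "exons": exons}
    return genes


def read_gene_models(path: str | Path, dialect: str = "gtf_lite") -> list[GeneModel]:
    """Load gene models from a GTF-lite or BED12 file.

    Returns models ordered deterministically by (chrom, start, gene_id);
    exon unions and exonic lengths are computed on load.
    """
    path = Path(path)
    if dialect == "gtf_lite":
        raw = _parse_gtf_lite(path)
    elif dialect == "bed12":
        raw = _parse_bed12(path)
    else:
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    models = [GeneModel(gid, g["chrom"], g["strand"], tuple(g["exons"])) for gid, g in raw.items()]
    ids = [m.gene_id for m in models]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate gene_id")
    models.sort(key=lambda m: (m.chrom, m.span[0], m.gene_id))
    return models


def write_gene_models_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                fh.write(f'{m.chrom}\tmoderseq\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tgene_id "{m.gene_id}"\n')


# ---------------------------------------------------------------------------
# alignment tables

ALIGNMENT_COLUMNS = ("read_id", "chrom", "start", "end", "read_class", "hits")


def read_alignment_table(path: str | Path) -> list[AlignmentRecord]:
    """Read the simplified BED-like alignment TSV (one row per read)."""
    path = Path(path)
    records: list[AlignmentRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            logger.warning("%s: empty alignment table", path)
            return records
        cols = header.split("\t")
        if tuple(cols) != ALIGNMENT_COLUMNS:
            raise FormatError(f"{path}: header must be {' '.join(ALIGNMENT_COLUMNS)}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            read_id, chrom, start, end, read_class, hits = fields
            if read_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate read_id {read_id!r}")
            seen.add(read_id)
            try:
                rec = AlignmentRecord(read_id, chrom, int(start), int(end), read_class,
                                      tuple(h for h in hits.split(",") if h))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if not records:
        logger.warning("%s: alignment table has no records", path)
    return records


def write_alignment_table(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.read_class}\t{','.join(r.hits)}\n")


def read_sam_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Optional SAM importer: maps aligned lines to AlignmentRecords.

    A line becomes class ``multi`` if MAPQ == 0 or an NH tag > 1 is present;
    ``splice`` if the CIGAR contains an N operation; ``unique`` otherwise.
    Candidate gene assignment is deferred to quantification (hits carry a
    placeholder '*').
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qname, flag, rname, pos, mapq, cigar = f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[5]
            if flag & 0x4 or rname == "*":
                continue
            length = sum(int(n) for n, op in re.findall(r"(\d+)([MDN=X])", cigar)) or 1
            nh = 1
            for tag in f[11:]:
                if tag.startswith("NH:i:"):
                    nh = int(tag.split(":")[2])
            if mapq == 0 or nh > 1:
                cls = "multi"
            elif "N" in cigar:
                cls = "splice"
            else:
                cls = "unique"
            records.append(AlignmentRecord(qname, rname, pos - 1, pos - 1 + length, cls, ("*",)))
    return records


# ---------------------------------------------------------------------------
# matrices and design

def read_matrix(path: str | Path) -> pd.DataFrame:
    """TSV matrix: first column gene_id, remaining columns sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_design(path: str | Path) -> tuple[pd.Series, pd.Series | None]:
    """Design TSV: columns sample_id, condition[, total_mapped_reads]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    if "sample_id" not in df.columns or "condition" not in df.columns:
        raise FormatError(f"{path}: design needs sample_id and condition columns")
    design = pd.Series(df["condition"].to_numpy(), index=df["sample_id"], name="condition")
    totals = None
    if "total_mapped_reads" in df.columns:
        totals = pd.Series(df["total_mapped_reads"].to_numpy(), index=df["sample_id"],
                           name="total_mapped_reads")
    return design, totals


def write_design(design: pd.Series, totals: pd.Series | None, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": design.index, "condition": design.to_numpy()})
    if totals is not None:
        df["total_mapped_reads"] = totals.to_numpy()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype-count and group-summary tables

def read_crosses_table(path: str | Path) -> dict[str, CrossCounts]:
    """Crosses TSV: cross_id, genotype_labels, observed, expected_ratio.

    List fields are comma-separated; expected_ratio accepts integers or
    fractions ("1,2,1") and is normalized to sum 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"cross_id", "genotype_labels", "observed", "expected_ratio"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: crosses table needs columns {sorted(needed)}")
    out: dict[str, CrossCounts] = {}
    for _, row in df.iterrows():
        out[row["cross_id"]] = CrossCounts(
            tuple(row["genotype_labels"].split(",")),
            tuple(int(x) for x in row["observed"].split(",")),
            tuple(Fraction(x) for x in row["expected_ratio"].split(",")),
        )
    return out


def read_groups_table(path: str | Path) -> dict[str, tuple[GroupSummary, GroupSummary]]:
    """Group-summary TSV with columns comparison, label, mean, dispersion,
    dispersion_kind, n; exactly two rows per comparison."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[GroupSummary, GroupSummary]] = {}
    for cid, sub in df.groupby("comparison", sort=False):
        if len(sub) != 2:
            raise FormatError(f"{path}: comparison {cid!r} must have exactly 2 rows")
        groups = [GroupSummary(str(r["label"]), float(r["mean"]), float(r["dispersion"]),
                               str(r["dispersion_kind"]), int(r["n"]))
                  for _, r in sub.iterrows()]
        out[str(cid)] = (groups[0], groups[1])
    return out


# ---------------------------------------------------------------------------
# result tables

def write_results_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a homogeneous result list (or DataFrame) as a TSV.

    Floats are serialized with 6 significant digits so the table round-trips
    bit-identically through :func:`read_results_table` at that precision.
    An empty record list produces a header-only file (``columns`` names the
    header in that case).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and not all(type(r) is type(records[0]) for r in records):
            raise ValueError("result records must be homogeneous")
        df = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else r for r in records],
                          columns=columns if not records else None)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
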