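"""Genomic containers and readers for segmented copy-number data.

Segmented CNV profiles (SEG-style), gene annotation (BED-style), cytoband
tables (UCSC ``cytoBand.txt`` layout) and healthy-population structural
variant records (DGV-style) are parsed into lightweight dataclasses, and
segments are intersected with gene models to produce a genes x samples
matrix of continuous log2 copy-number ratios.

Coordinates are held internally as 0-based half-open intervals (BED
semantics). Public SEG exports are frequently 1-based closed, so the segment
reader takes an explicit ``dialect`` argument and normalizes on the way in.
Chromosome names are normalized by stripping a leading ``chr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SEG_DIALECTS = ("zero_based_half_open", "one_based_closed")


class FormatError(ValueError):
    """A file (or one of its rows) violates the expected tabular layout."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class Segment:
    """One sample's contiguous interval with a continuous log2 ratio."""

    sample_id: str
    interval: GenomicInterval
    log2_ratio: float
    n_probes: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_ratio):
            raise ValueError("log2_ratio must be finite")


@dataclass
class GeneModel:
    """Gene symbol with its genomic footprint and (optionally) a cytoband."""

    symbol: str
    interval: Optional[GenomicInterval]
    band: Optional[str] = None


@dataclass(frozen=True)
class CytobandRecord:
    """One band of a chromosome; ``name`` carries no chromosome prefix."""

    interval: GenomicInterval
    name: str


@dataclass(frozen=True)
class HealthyVariantRecord:
    """A gain/loss call in one healthy individual."""

    individual_id: str
    interval: GenomicInterval
    variant_class: str

    def __post_init__(self) -> None:
        if self.variant_class not in ("gain", "loss"):
            raise ValueError("variant_class must be 'gain' or 'loss'")


@dataclass
class GeneCNVMatrix:
    """Genes x samples continuous CNV values (possibly missing entries).

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns; ``genes`` keeps the full gene models in row order.
    """

    genes: list[GeneModel]
    values: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != self.values.shape[0]:
            raise ValueError("gene list does not match value matrix rows")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        symbols = [g.symbol for g in self.genes]
        if list(self.values.index) != symbols:
            raise ValueError("matrix index does not match gene symbols")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def band_of(self, symbol: str) -> Optional[str]:
        for g in self.genes:
            if g.symbol == symbol:
                return g.band
        raise KeyError(symbol)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_SEG_REQUIRED = ("sample", "chrom", "start", "end", "seg_mean")


def read_segments(path: str | Path, dialect: str = "one_based_closed") -> list[Segment]:
    """Read a SEG-style tab-delimited file into :class:`Segment` records.

    The file must have a header with columns ``sample``, ``chrom``,
    ``start``, ``end``, ``seg_mean`` and optionally ``n_probes``. ``dialect``
    declares the coordinate convention of the file; intervals are normalized
    to 0-based half-open.
    """
    if dialect not in SEG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {SEG_DIALECTS}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _SEG_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"segment file {path} is missing required column {col!r}")
    has_probes = "n_probes" in df.columns
    segments: list[Segment] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header occupies line 1
        try:
            start = int(getattr(row, "start"))
            end = int(getattr(row, "end"))
            value = float(getattr(row, "seg_mean"))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"malformed row at line {line_no} of {path}: {exc}") from exc
        if dialect == "one_based_closed":
            start -= 1
        if start >= end:
            raise FormatError(
                f"row at line {line_no} of {path}: start >= end after normalization"
            )
        n_probes = None
        if has_probes:
            raw = getattr(row, "n_probes")
            if raw is not None and not pd.isna(raw) and str(raw) != "":
                n_probes = int(raw)
        try:
            seg = Segment(
                sample_id=str(getattr(row, "sample")),
                interval=GenomicInterval(normalize_chrom(getattr(row, "chrom")), start, end),
                log2_ratio=value,
                n_probes=n_probes,
            )
        except ValueError as exc:
            raise FormatError(f"row at line {line_no} of {path}: {exc}") from exc
        segments.append(seg)
    return segments


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    """Write segments as 0-based half-open SEG-style TSV."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tseg_mean\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.interval.chrom}\t{s.interval.start}"
                f"\t{s.interval.end}\t{s.log2_ratio!r}\n"
            )


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read a 4-column BED-style gene annotation (chrom, start, end, symbol).

    Duplicate symbols keep the longest interval (identical duplicates are
    silently collapsed); drops are logged.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "symbol"], dtype=str,
    )
    if df.empty:
        raise FormatError(f"gene annotation {path} contains no rows")
    by_symbol: dict[str, GeneModel] = {}
    dropped = 0
    for row in df.itertuples(index=False):
        iv = GenomicInterval(normalize_chrom(row.chrom), int(row.start), int(row.end))
        sym = str(row.symbol)
        prev = by_symbol.get(sym)
        if prev is None:
            by_symbol[sym] = GeneModel(sym, iv)
        elif prev.interval == iv:
            continue  # identical duplicate
        else:
            dropped += 1
            if iv.length > prev.interval.length:
                by_symbol[sym] = GeneModel(sym, iv)
    if dropped:
        logger.info("read_gene_annotation: dropped %d duplicate gene rows", dropped)
    return list(by_symbol.values())


def read_cytobands(path: str | Path) -> list[CytobandRecord]:
    """Read a UCSC ``cytoBand.txt``-style table (gieStain column ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"cytoband file {path} needs >= 4 columns")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CytobandRecord(
                interval=GenomicInterval(normalize_chrom(row[0]), int(row[1]), int(row[2])),
                name=str(row[3]),
            )
        )
    return records


_HEALTHY_CLASS_MAP = {
    "duplication": "gain",
    "tandem duplication": "gain",
    "tandem_duplication": "gain",
    "gain": "gain",
    "insertion": "gain",
    "deletion": "loss",
    "loss": "loss",
}


def read_healthy_variants(path: str | Path) -> list[HealthyVariantRecord]:
    """Read DGV-style healthy variant records.

    Required header columns: ``individual``, ``chrom``, ``start``, ``end``,
    ``variant_class``. Classes are collapsed to gain/loss; records of other
    classes (e.g. inversions) are dropped and counted in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("individual", "chrom", "start", "end", "variant_class"):
        if col not in df.columns:
            raise FormatError(f"healthy variant file {path} is missing column {col!r}")
    records: list[HealthyVariantRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        mapped = _HEALTHY_CLASS_MAP.get(str(row.variant_class).strip().lower())
        if mapped is None:
            dropped += 1
            continue
        records.append(
            HealthyVariantRecord(
                individual_id=str(row.individual),
                interval=GenomicInterval(normalize_chrom(row.chrom), int(row.start), int(row.end)),
                variant_class=mapped,
            )
        )
    if dropped:
        logger.info("read_healthy_variants: dropped %d records of unmapped classes", dropped)
    return records


# ---------------------------------------------------------------------------
# Band assignment and segment -> gene aggregation
# ---------------------------------------------------------------------------

def _trees_by_chrom(items: Sequence, get_interval) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for item in items:
        iv = get_interval(item)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, item)
    return trees


def assign_cytobands(genes: Sequence[GeneModel], bands: Sequence[CytobandRecord]) -> list[GeneModel]:
    """Label each gene with the cytoband containing its midpoint.

    A gene straddling two bands gets the band of its midpoint; genes with no
    covering band keep ``band=None`` (logged as a warning).
    """
    trees = _trees_by_chrom(bands, lambda b: b.interval)
    out: list[GeneModel] = []
    unassigned = 0
    for gene in genes:
        iv = gene.interval
        hits = sorted(trees.get(iv.chrom, IntervalTree())[iv.midpoint],
                      key=lambda h: h.begin) if iv is not None else []
        if hits:
            band = f"{iv.chrom}{hits[0].data.name}"
            out.append(replace(gene, band=band))
        else:
            unassigned += 1
            out.append(replace(gene, band=None))
    if unassigned:
        logger.warning("assign_cytobands: %d genes had no covering band", unassigned)
    return out


def segments_to_gene_matrix(
    segments: Sequence[Segment],
    genes: Sequence[GeneModel],
    cohort_label: str = "",
) -> GeneCNVMatrix:
    """Aggregate per-sample segments to gene-level values.

    Each (gene, sample) entry is the overlap-length-weighted mean of the log2
    ratios of all of that sample's segments overlapping the gene; genes with
    no overlapping segment in a sample are left missing. Samples are ordered
    by first appearance, genes in annotation order.
    """
    samples: list[str] = []
    sample_idx: dict[str, int] = {}
    for seg in segments:
        if seg.sample_id not in sample_idx:
            sample_idx[seg.sample_id] = len(samples)
            samples.append(seg.sample_id)
    if not samples:
        raise ValueError("empty matrix: no segments supplied")

    trees = _trees_by_chrom(
        [(i, g) for i, g in enumerate(genes)], lambda pair: pair[1].interval
    )
    n_genes, n_samples = len(genes), len(samples)
    wsum = np.zeros((n_genes, n_samples))
    weight = np.zeros((n_genes, n_samples))
    for seg in segments:
        j = sample_idx[seg.sample_id]
        tree = trees.get(seg.interval.chrom)
        if tree is None:
            continue
        for hit in tree[seg.interval.start: seg.interval.end]:
            gi, gene = hit.data
            ov = gene.interval.overlap_length(seg.interval)
            if ov > 0:
                wsum[gi, j] += ov * seg.log2_ratio
                weight[gi, j] += ov
    with np.errstate(invalid="ignore"):
        values = np.where(weight > 0, wsum / np.where(weight > 0, weight, 1.0), np.nan)
    if not np.isfinite(values).any():
        raise ValueError("empty matrix: no segment overlaps any gene")
    df = pd.DataFrame(values, index=[g.symbol for g in genes], columns=samples)
    return GeneCNVMatrix(genes=list(genes), values=df, cohort_label=cohort_label)


# ---------------------------------------------------------------------------
# Matrix TSV round-trip
# ---------------------------------------------------------------------------

def write_matrix(matrix, path: str | Path) -> None:
    """Write a gene-level matrix as TSV: symbol, band, then one column per
    sample; missing entries are empty cells. Works for continuous values and
    integer codes alike (floats are serialized with full round-trip precision).
    """
    values = matrix.values
    with open(path, "w") as fh:
        fh.write("symbol\tband\t" + "\t".join(map(str, values.columns)) + "\n")
        bands = [g.band if g.band is not None else "" for g in matrix.genes]
        arr = values.to_numpy()
        for i, gene in enumerate(matrix.genes):
            cells = ["" if not np.isfinite(v) else repr(float(v)) for v in arr[i]]
            fh.write(f"{gene.symbol}\t{bands[i]}\t" + "\t".join(cells) + "\n")


def read_matrix(path: str | Path, cohort_label: str = "") -> GeneCNVMatrix:
    """Read a matrix written by :func:`write_matrix`.

    Gene intervals are not stored in the TSV, so the returned gene models
    carry ``interval=None`` (bands are preserved).
    """
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "band": str},
                     float_precision="round_trip")
    if "symbol" not in df.columns or "band" not in df.columns:
        raise FormatError(f"matrix file {path} must start with symbol and band columns")
    genes = [
        GeneModel(str(row.symbol), None, band=None if pd.isna(row.band) else str(row.band))
        for row in df.itertuples(index=False)
    ]
    values = df.drop(columns=["symbol", "band"]).astype(float)
    values.index = pd.Index([g.symbol for g in genes])
    return GeneCNVMatrix(genes=genes, values=values, cohort_label=cohort_label)
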