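"""Genome architecture metrics from validated gene models.

A genome is partitioned exhaustively into coding, intronic, and intergenic
base classes with priority coding > intronic > intergenic: a base is coding
when it falls inside the strand-blind union of representative CDS segments,
intronic when it falls inside some gene's CDS extent but not in the coding
union (this covers nested genes: the host's intron keeps its intronic
label except where the nested gene's CDS sits), and intergenic otherwise,
including scaffold-terminal stretches.

Intron statistics cover only the gaps between consecutive CDS segments of
each gene's representative isoform (CDS introns); UTR introns are ignored.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation_io import (
    AnnotationError,
    GenomeAnnotation,
    Scaffold,
    TranscriptModel,
)

__all__ = [
    "GenomePartition",
    "IntronRecord",
    "ArchitectureSummary",
    "IntronPositionProfile",
    "merge_cds_union",
    "partition_genome",
    "extract_cds_introns",
    "iter_cds_introns",
    "intergenic_gaps",
    "architecture_summary",
    "relative_intron_positions",
]


@dataclass(frozen=True)
class GenomePartition:
    coding_bp: int
    intronic_bp: int
    intergenic_bp: int
    total_bp: int

    def __post_init__(self) -> None:
        if self.coding_bp + self.intronic_bp + self.intergenic_bp != self.total_bp:
            raise ValueError("partition classes do not sum to the assembly length")

    @property
    def coding_pct(self) -> float:
        return 100.0 * self.coding_bp / self.total_bp

    @property
    def intronic_pct(self) -> float:
        return 100.0 * self.intronic_bp / self.total_bp

    @property
    def intergenic_pct(self) -> float:
        return 100.0 * self.intergenic_bp / self.total_bp


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    ordinal: int          # 1-based index in transcription direction
    c_upstream: int       # coding nt 5' of the intron, transcription direction
    total_coding: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def phase(self) -> int:
        return self.c_upstream % 3

    @property
    def relative_position(self) -> float:
        """Fraction of the coding length lying 5' of this intron."""
        return self.c_upstream / self.total_coding


@dataclass(frozen=True)
class ArchitectureSummary:
    n_genes: int
    pct_intronless: float
    partition: GenomePartition
    median_intergenic_gap: float
    median_intron_length: float
    n_cds_introns: int


@dataclass(frozen=True)
class IntronPositionProfile:
    positions: tuple[float, ...]
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]

    @property
    def fraction_5prime_half(self) -> float:
        return sum(1 for r in self.positions if r < 0.5) / len(self.positions)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; book-ended intervals coalesce."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            prev_start, prev_end = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


def merge_cds_union(annotation: GenomeAnnotation) -> dict[str, list[tuple[int, int]]]:
    """Disjoint per-scaffold union of all representative CDS segments.

    Strand is ignored: a base covered by CDS on either strand is coding.
    """
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes:
        for seg in gene.representative.segments:
            by_scaffold.setdefault(seg.scaffold_id, []).append((seg.start, seg.end))
    return {sid: _merge_intervals(ivs) for sid, ivs in sorted(by_scaffold.items())}


def _interval_total(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(end - start + 1 for start, end in intervals)


def partition_genome(
    annotation: GenomeAnnotation, scaffolds: Sequence[Scaffold] | None = None
) -> GenomePartition:
    """Exact base counts of coding / intronic / intergenic sequence."""
    if scaffolds is None:
        scaffolds = annotation.scaffolds
    if not scaffolds:
        raise AnnotationError("partition_genome: scaffold lengths are required")
    lengths = {sc.id: sc.length for sc in scaffolds}
    for gene in annotation.genes:
        if gene.scaffold_id not in lengths:
            raise AnnotationError(
                f"partition_genome: no length for scaffold {gene.scaffold_id!r} "
                f"(gene {gene.id!r})"
            )

    coding_union = merge_cds_union(annotation)
    spans_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes:
        spans_by_scaffold.setdefault(gene.scaffold_id, []).append(gene.span)

    total_bp = sum(lengths.values())
    coding_bp = sum(_interval_total(ivs) for ivs in coding_union.values())
    # CDS segments lie inside their gene's span, so genic = coding + intronic
    genic_bp = sum(
        _interval_total(_merge_intervals(spans))
        for spans in spans_by_scaffold.values()
    )
    intronic_bp = genic_bp - coding_bp
    return GenomePartition(coding_bp, intronic_bp, total_bp - genic_bp, total_bp)


def extract_cds_introns(transcript: TranscriptModel) -> list[IntronRecord]:
    """One record per gap between consecutive CDS segments.

    Ordinal, ``c_upstream`` and hence phase are computed in transcription
    direction: a minus-strand transcript is traversed from its genomically
    rightmost segment leftwards.
    """
    segments = transcript.segments  # ascending genomic start
    total = transcript.coding_length
    records: list[IntronRecord] = []
    n = len(segments)
    if transcript.strand == "+":
        upstream = 0
        for i in range(n - 1):
            upstream += segments[i].length
            records.append(
                IntronRecord(
                    transcript.gene_id,
                    transcript.scaffold_id,
                    segments[i].end + 1,
                    segments[i + 1].start - 1,
                    ordinal=i + 1,
                    c_upstream=upstream,
                    total_coding=total,
                )
            )
    else:
        upstream = 0
        for i in range(n - 1, 0, -1):
            upstream += segments[i].length
            records.append(
                IntronRecord(
                    transcript.gene_id,
                    transcript.scaffold_id,
                    segments[i - 1].end + 1,
                    segments[i].start - 1,
                    ordinal=n - i,
                    c_upstream=upstream,
                    total_coding=total,
                )
            )
    return records


def iter_cds_introns(annotation: GenomeAnnotation) -> list[IntronRecord]:
    records: list[IntronRecord] = []
    for gene in annotation.genes:
        records.extend(extract_cds_introns(gene.representative))
    return records


def intergenic_gaps(annotation: GenomeAnnotation, clamp: bool = True) -> list[int]:
    """Gaps between CDS extents of adjacent genes per scaffold.

    Overlapping neighbours contribute 0 when ``clamp`` is set and are
    excluded otherwise.  Scaffold-terminal stretches never contribute.
    """
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes:
        by_scaffold.setdefault(gene.scaffold_id, []).append(gene.span)
    gaps: list[int] = []
    for spans in by_scaffold.values():
        spans.sort()
        for (_, prev_end), (next_start, _) in zip(spans, spans[1:]):
            gap = next_start - prev_end - 1
            if gap < 0:
                if clamp:
                    gaps.append(0)
            else:
                gaps.append(gap)
    return gaps


def architecture_summary(
    annotation: GenomeAnnotation, scaffolds: Sequence[Scaffold] | None = None
) -> ArchitectureSummary:
    """Table-style summary: gene count, %intronless, partition, medians."""
    if not annotation.genes:
        raise AnnotationError("architecture_summary: annotation has no genes")
    n_genes = len(annotation.genes)
    n_intronless = sum(
        1 for g in annotation.genes if len(g.representative.segments) == 1
    )
    introns = iter_cds_introns(annotation)
    gaps = intergenic_gaps(annotation)
    return ArchitectureSummary(
        n_genes=n_genes,
        pct_intronless=100.0 * n_intronless / n_genes,
        partition=partition_genome(annotation, scaffolds),
        median_intergenic_gap=statistics.median(gaps) if gaps else 0.0,
        median_intron_length=(
            statistics.median(r.length for r in introns) if introns else 0.0
        ),
        n_cds_introns=len(introns),
    )


def relative_intron_positions(
    annotation: GenomeAnnotation, n_bins: int = 10
) -> IntronPositionProfile:
    """Per-intron relative position along the spliced CDS, 5' to 3'."""
    introns = iter_cds_introns(annotation)
    if not introns:
        raise AnnotationError("relative_intron_positions: no CDS introns")
    positions = tuple(r.relative_position for r in introns)
    edges = tuple(i / n_bins for i in range(n_bins + 1))
    counts = [0] * n_bins
    for r in positions:
        counts[min(int(r * n_bins), n_bins - 1)] += 1
    return IntronPositionProfile(positions, edges, tuple(counts))
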