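"""Reading and normalizing genome annotations.

GFF3 gene annotations are reduced to a simple validated model: one
representative (longest-CDS) transcript per protein-coding gene, with its
ordered CDS segments.  All coordinates are GFF3-style 1-based inclusive;
every length is computed as ``end - start + 1``.

The GFF3 phase column is deliberately ignored; intron phase is recomputed
downstream from CDS segment lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Scaffold",
    "CdsSegment",
    "TranscriptModel",
    "GeneModel",
    "GenomeAnnotation",
    "AnnotationError",
    "read_gff3",
    "write_gff3",
    "select_longest_isoform",
    "read_scaffold_lengths",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Scaffold:
    id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError(f"scaffold {self.id!r}: length must be positive")


@dataclass(frozen=True)
class CdsSegment:
    scaffold_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"CDS segment on {self.scaffold_id!r}: "
                f"need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"CDS segment on {self.scaffold_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    id: str
    gene_id: str
    segments: tuple[CdsSegment, ...]
    strand: str

    def __post_init__(self) -> None:
        if not self.segments:
            raise AnnotationError(f"transcript {self.id!r}: no CDS segments")
        scaffolds = {s.scaffold_id for s in self.segments}
        if len(scaffolds) != 1:
            raise AnnotationError(
                f"transcript {self.id!r}: CDS segments span scaffolds {sorted(scaffolds)}"
            )
        if any(s.strand != self.strand for s in self.segments):
            raise AnnotationError(f"transcript {self.id!r}: mixed strands")
        ordered = sorted(self.segments, key=lambda s: s.start)
        object.__setattr__(self, "segments", tuple(ordered))
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.id!r}: overlapping CDS segments "
                    f"{a.start}..{a.end} and {b.start}..{b.end}"
                )

    @property
    def scaffold_id(self) -> str:
        return self.segments[0].scaffold_id

    @property
    def coding_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.segments[0].start, self.segments[-1].end


@dataclass(frozen=True)
class GeneModel:
    id: str
    representative: TranscriptModel

    @property
    def scaffold_id(self) -> str:
        return self.representative.scaffold_id

    @property
    def strand(self) -> str:
        return self.representative.strand

    @property
    def span(self) -> tuple[int, int]:
        return self.representative.span


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel]
    scaffolds: list[Scaffold] | None = None
    _scaffold_index: dict[str, Scaffold] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise AnnotationError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
        if self.scaffolds is not None:
            index: dict[str, Scaffold] = {}
            for sc in self.scaffolds:
                if sc.id in index:
                    raise AnnotationError(f"duplicate scaffold id {sc.id!r}")
                index[sc.id] = sc
            self._scaffold_index = index
            for g in self.genes:
                sc = index.get(g.scaffold_id)
                if sc is None:
                    raise AnnotationError(
                        f"gene {g.id!r} sits on unknown scaffold {g.scaffold_id!r}"
                    )
                if g.span[1] > sc.length:
                    raise AnnotationError(
                        f"gene {g.id!r} extends to {g.span[1]} beyond scaffold "
                        f"{sc.id!r} length {sc.length}"
                    )

    def scaffold_length(self, scaffold_id: str) -> int:
        try:
            return self._scaffold_index[scaffold_id].length
        except KeyError:
            raise AnnotationError(f"no length known for scaffold {scaffold_id!r}")


def select_longest_isoform(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick the transcript with the largest summed CDS length.

    Ties are broken by the lexicographically smallest transcript id so the
    choice is independent of input order.
    """
    if not transcripts:
        raise AnnotationError("select_longest_isoform: empty transcript list")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise AnnotationError(
            f"select_longest_isoform: transcripts belong to genes {sorted(gene_ids)}"
        )
    return min(transcripts, key=lambda t: (-t.coding_length, t.id))


def _segments_from_cds_rows(
    rows: Iterable[gffutils.Feature], transcript_id: str
) -> list[CdsSegment]:
    segments = []
    for f in rows:
        if f.strand not in ("+", "-"):
            raise AnnotationError(
                f"CDS of {transcript_id!r} at {f.seqid}:{f.start}-{f.end}: "
                f"strand {f.strand!r} is not allowed (must be '+' or '-')"
            )
        segments.append(CdsSegment(f.seqid, f.start, f.end, f.strand))
    return segments


def read_gff3(
    path: str | Path, scaffolds: Sequence[Scaffold] | None = None
) -> GenomeAnnotation:
    """Parse a GFF3 file into one representative gene model per gene.

    CDS features must name their transcript via ``Parent``; a CDS whose
    parent is a gene directly is accepted as a single implicit transcript.
    Genes with no CDS-bearing transcript are dropped with a warning.
    ``##sequence-region`` pragmas populate scaffold lengths when no explicit
    scaffold list is supplied.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            checklines=0,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"{path}: failed to parse GFF3: {exc}") from exc

    if scaffolds is None:
        regions = _read_sequence_regions(path)
        if regions:
            scaffolds = regions

    # transcript -> gene and transcript -> CDS rows
    gene_ids: set[str] = set()
    parent_of: dict[str, str] = {}
    for f in db.all_features():
        if f.featuretype == "gene":
            gene_ids.add(f.id)
    for f in db.all_features():
        if f.featuretype in ("gene", "CDS"):
            continue
        gene_parents = [p for p in f.attributes.get("Parent", []) if p in gene_ids]
        # transcripts without a gene feature act as their own gene
        parent_of[f.id] = gene_parents[0] if gene_parents else f.id

    cds_by_transcript: dict[str, list[gffutils.Feature]] = {}
    implicit: dict[str, list[gffutils.Feature]] = {}  # CDS directly under a gene
    for f in db.features_of_type("CDS"):
        if f.start > f.end:
            raise AnnotationError(
                f"{path}: CDS at {f.seqid}:{f.start}-{f.end}: start > end"
            )
        parents = f.attributes.get("Parent", [])
        if not parents:
            raise AnnotationError(
                f"{path}: CDS at {f.seqid}:{f.start}-{f.end} has no Parent attribute"
            )
        for parent in parents:
            if parent in gene_ids:
                implicit.setdefault(parent, []).append(f)
            elif parent in parent_of:
                cds_by_transcript.setdefault(parent, []).append(f)
            else:
                raise AnnotationError(
                    f"{path}: CDS at {f.seqid}:{f.start}-{f.end} references "
                    f"unknown Parent {parent!r}"
                )

    transcripts_by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, rows in cds_by_transcript.items():
        segs = _segments_from_cds_rows(rows, tid)
        gid = parent_of[tid]
        transcripts_by_gene.setdefault(gid, []).append(
            TranscriptModel(tid, gid, tuple(segs), segs[0].strand)
        )
    for gid, rows in implicit.items():
        segs = _segments_from_cds_rows(rows, gid)
        tid = f"{gid}.cds"
        transcripts_by_gene.setdefault(gid, []).append(
            TranscriptModel(tid, gid, tuple(segs), segs[0].strand)
        )

    genes: list[GeneModel] = []
    for gid in sorted(gene_ids | set(transcripts_by_gene)):
        transcripts = transcripts_by_gene.get(gid)
        if not transcripts:
            logger.warning("gene %r has no CDS-bearing transcript; dropped", gid)
            continue
        genes.append(GeneModel(gid, select_longest_isoform(transcripts)))
    return GenomeAnnotation(genes, list(scaffolds) if scaffolds else None)


def _read_sequence_regions(path: Path) -> list[Scaffold]:
    regions: list[Scaffold] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise AnnotationError(f"{path}: malformed pragma: {line.strip()!r}")
                try:
                    start, end = int(parts[2]), int(parts[3])
                except ValueError:
                    raise AnnotationError(
                        f"{path}: non-integer coordinate in pragma: {line.strip()!r}"
                    )
                regions.append(Scaffold(parts[1], end - start + 1))
            elif not line.startswith("#") and line.strip():
                # pragmas only appear in the header block
                break
    return regions


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Serialize gene models back to GFF3 (gene -> mRNA -> CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if annotation.scaffolds:
            for sc in annotation.scaffolds:
                fh.write(f"##sequence-region {sc.id} 1 {sc.length}\n")
        for gene in annotation.genes:
            t = gene.representative
            start, end = gene.span
            fh.write(
                f"{gene.scaffold_id}\tgenarch\tgene\t{start}\t{end}\t.\t"
                f"{gene.strand}\t.\tID={gene.id}\n"
            )
            fh.write(
                f"{gene.scaffold_id}\tgenarch\tmRNA\t{start}\t{end}\t.\t"
                f"{gene.strand}\t.\tID={t.id};Parent={gene.id}\n"
            )
            for seg in t.segments:
                fh.write(
                    f"{seg.scaffold_id}\tgenarch\tCDS\t{seg.start}\t{seg.end}\t.\t"
                    f"{seg.strand}\t.\tParent={t.id}\n"
                )


def read_scaffold_lengths(path: str | Path) -> list[Scaffold]:
    """One Scaffold per FASTA record, with length = residue count."""
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise AnnotationError(f"{path}: duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        scaffolds.append(Scaffold(record.id, len(record.seq)))
    if not scaffolds:
        raise AnnotationError(f"{path}: no FASTA records found")
    return scaffolds
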