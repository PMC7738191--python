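"""Synthetic inputs with machine-readable truth ledgers.

Every generator takes an explicit seed, uses a single ``numpy`` Generator
for all randomness, and emits plain-text files in the same formats the
pipeline consumes (FASTA, GFF3, cluster FASTA, BLAST tabular, RepeatMasker
``.out``) together with a ledger recording the planted truth.  Ledgers are
exactly consistent with the emitted files, so every pipeline stage can be
oracle-tested without tolerances.  Sequence content is arbitrary (uniform
nucleotides / residues): no pipeline stage inspects composition.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .annotation_io import (
    CdsSegment,
    GeneModel,
    GenomeAnnotation,
    Scaffold,
    TranscriptModel,
    write_gff3,
)
from .intron_evolution import (
    AlignedOrthogroup,
    AlignedSequence,
    IntronSiteTable,
    ProteinIntronAnnotation,
    _leafsets,
)

__all__ = [
    "GenomeSimConfig",
    "GenomeTruth",
    "IntronHistoryTruth",
    "HgtTruth",
    "RepeatTruth",
    "generate_genome",
    "generate_intron_history",
    "generate_hgt_table",
    "generate_repeat_landscape",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class GenomeSimConfig:
    seed: int
    n_scaffolds: int = 2
    scaffold_length: int = 50_000
    n_genes: int = 40
    intronless_fraction: float = 0.8
    introns_per_gene_p: float = 0.5      # geometric success prob (support 1,2,...)
    intron_length_median: float = 170.0  # log-normal
    intron_length_sigma: float = 0.6
    exon_length_min: int = 60
    exon_length_max: int = 400
    intergenic_gap_median: float = 500.0  # log-normal
    intergenic_gap_sigma: float = 0.8
    nested_gene_probability: float = 0.0
    minus_strand_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("intronless_fraction", "nested_gene_probability",
                     "minus_strand_fraction", "introns_per_gene_p"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_scaffolds <= 0 or self.scaffold_length <= 0:
            raise ValueError("scaffold dimensions must be positive")
        if self.exon_length_min < 3 or self.exon_length_max < self.exon_length_min:
            raise ValueError("bad exon length bounds")


@dataclass
class GenomeTruth:
    """Planted structure and exact expected metrics for a synthetic genome."""

    n_genes: int
    n_intronless: int
    n_nested: int
    coding_bp: int
    intronic_bp: int
    intergenic_bp: int
    total_bp: int
    n_cds_introns: int
    intron_lengths: list[int]
    intergenic_gap_lengths: list[int]

    @property
    def pct_intronless(self) -> float:
        return 100.0 * self.n_intronless / self.n_genes if self.n_genes else 0.0

    @property
    def median_intron_length(self) -> float:
        return statistics.median(self.intron_lengths) if self.intron_lengths else 0.0

    @property
    def median_intergenic_gap(self) -> float:
        return (
            statistics.median(self.intergenic_gap_lengths)
            if self.intergenic_gap_lengths
            else 0.0
        )


def _sample_lognormal_int(rng: np.random.Generator, median: float, sigma: float,
                          minimum: int) -> int:
    return max(minimum, int(round(rng.lognormal(np.log(median), sigma))))


def _sample_gene_structure(
    rng: np.random.Generator, config: GenomeSimConfig
) -> tuple[list[int], list[int]]:
    """(exon_lengths, intron_lengths) for one gene; coding length % 3 == 0."""
    if rng.random() < config.intronless_fraction:
        n_introns = 0
    else:
        n_introns = int(rng.geometric(config.introns_per_gene_p))
    exons = [
        int(rng.integers(config.exon_length_min, config.exon_length_max + 1))
        for _ in range(n_introns + 1)
    ]
    remainder = sum(exons) % 3
    exons[-1] += (3 - remainder) % 3
    introns = [
        _sample_lognormal_int(rng, config.intron_length_median,
                              config.intron_length_sigma, 4)
        for _ in range(n_introns)
    ]
    return exons, introns


def _segments_from_structure(
    scaffold_id: str, start: int, strand: str, exons: list[int], introns: list[int]
) -> list[CdsSegment]:
    segments = []
    pos = start
    for i, exon_len in enumerate(exons):
        segments.append(CdsSegment(scaffold_id, pos, pos + exon_len - 1, strand))
        pos += exon_len
        if i < len(introns):
            pos += introns[i]
    return segments


def generate_genome(
    config: GenomeSimConfig, out_dir: str | Path
) -> tuple[Path, Path, GenomeTruth]:
    """Emit a synthetic assembly (FASTA) and annotation (GFF3) plus truth.

    Genes are placed left to right with sampled intergenic gaps; nested
    genes are single-exon genes dropped into a host gene's intron.  The
    ledger partition is computed by an independent per-base labeler over
    the planted intervals.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    scaffolds = [
        Scaffold(f"scaf{i + 1}", config.scaffold_length)
        for i in range(config.n_scaffolds)
    ]

    genes: list[GeneModel] = []
    n_nested = 0
    cursors = {sc.id: 1 for sc in scaffolds}
    scaffold_order = [sc.id for sc in scaffolds]
    host_candidates: list[tuple[str, list[tuple[int, int]]]] = []  # (gene, free introns)

    gene_index = 0
    while gene_index < config.n_genes:
        gid = f"gene{gene_index + 1:05d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"

        # occasionally nest a single-exon gene inside a previous gene's intron
        if host_candidates and rng.random() < config.nested_gene_probability:
            host_id, free_introns = host_candidates[-1]
            istart, iend = free_introns[int(rng.integers(len(free_introns)))]
            room = iend - istart + 1 - 2  # keep >=1 intronic bp each side
            if room >= 6:
                nested_len = min(room - room % 3, 3 * ((room // 3)))
                nested_len = max(3, min(nested_len, 3 * (int(rng.integers(1, room // 3 + 1)))))
                nstart = istart + 1
                seg = CdsSegment(
                    genes[-1].scaffold_id, nstart, nstart + nested_len - 1, strand
                )
                transcript = TranscriptModel(f"{gid}.t1", gid, (seg,), strand)
                genes.append(GeneModel(gid, transcript))
                host_candidates.pop()
                n_nested += 1
                gene_index += 1
                continue

        placed = False
        for _ in range(50):
            gap = _sample_lognormal_int(
                rng, config.intergenic_gap_median, config.intergenic_gap_sigma, 1
            )
            exons, introns = _sample_gene_structure(rng, config)
            footprint = sum(exons) + sum(introns)
            for sid in scaffold_order:
                start = cursors[sid] + gap
                if start + footprint - 1 <= config.scaffold_length:
                    segments = _segments_from_structure(sid, start, strand, exons, introns)
                    transcript = TranscriptModel(
                        f"{gid}.t1", gid, tuple(segments), strand
                    )
                    genes.append(GeneModel(gid, transcript))
                    cursors[sid] = start + footprint
                    if introns:
                        intron_spans = [
                            (a.end + 1, b.start - 1)
                            for a, b in zip(segments, segments[1:])
                        ]
                        host_candidates.append((gid, intron_spans))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise RuntimeError(
                f"generate_genome: could not place {gid} — expected gene "
                "footprint exceeds remaining scaffold capacity"
            )
        gene_index += 1

    annotation = GenomeAnnotation(genes, scaffolds)
    gff_path = out_dir / "annotation.gff3"
    write_gff3(annotation, gff_path)

    fasta_path = out_dir / "assembly.fasta"
    with open(fasta_path, "w") as fh:
        for sc in scaffolds:
            bases = rng.choice(list("ACGT"), size=sc.length)
            fh.write(f">{sc.id}\n")
            seq = "".join(bases)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    truth = _genome_truth(genes, scaffolds)
    return fasta_path, gff_path, truth


def _genome_truth(genes: list[GeneModel], scaffolds: list[Scaffold]) -> GenomeTruth:
    """Brute-force per-base labeling of the planted structure."""
    coding = {sc.id: np.zeros(sc.length, dtype=bool) for sc in scaffolds}
    genic = {sc.id: np.zeros(sc.length, dtype=bool) for sc in scaffolds}
    intron_lengths: list[int] = []
    spans: dict[str, list[tuple[int, int]]] = {}
    n_intronless = 0
    n_nested = 0
    for gene in genes:
        t = gene.representative
        if len(t.segments) == 1:
            n_intronless += 1
        for seg in t.segments:
            coding[seg.scaffold_id][seg.start - 1 : seg.end] = True
        start, end = gene.span
        genic[gene.scaffold_id][start - 1 : end] = True
        spans.setdefault(gene.scaffold_id, []).append((start, end))
        for a, b in zip(t.segments, t.segments[1:]):
            intron_lengths.append(b.start - a.end - 1)
    # nested = fully contained in another gene's span
    for gene in genes:
        start, end = gene.span
        for other in genes:
            if other is gene or other.scaffold_id != gene.scaffold_id:
                continue
            o_start, o_end = other.span
            if o_start < start and end < o_end:
                n_nested += 1
                break
    gaps: list[int] = []
    for scaffold_spans in spans.values():
        scaffold_spans.sort()
        for (_, prev_end), (next_start, _) in zip(scaffold_spans, scaffold_spans[1:]):
            gaps.append(max(0, next_start - prev_end - 1))
    coding_bp = int(sum(m.sum() for m in coding.values()))
    genic_bp = int(sum(m.sum() for m in genic.values()))
    total_bp = sum(sc.length for sc in scaffolds)
    return GenomeTruth(
        n_genes=len(genes),
        n_intronless=n_intronless,
        n_nested=n_nested,
        coding_bp=coding_bp,
        intronic_bp=genic_bp - coding_bp,
        intergenic_bp=total_bp - genic_bp,
        total_bp=total_bp,
        n_cds_introns=len(intron_lengths),
        intron_lengths=intron_lengths,
        intergenic_gap_lengths=gaps,
    )


# ---------------------------------------------------------------------------
# intron histories on trees


@dataclass
class IntronHistoryTruth:
    """Planted single-origin events per site, plus per-branch tallies."""

    gains: dict[frozenset, int] = field(default_factory=dict)
    losses: dict[frozenset, int] = field(default_factory=dict)
    site_patterns: list[frozenset] = field(default_factory=list)  # present species
    indel_plants: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (cluster_id, column, phase, n_residues)

    def presence_histogram(self) -> dict[int, int]:
        histogram: dict[int, int] = {}
        for pattern in self.site_patterns:
            histogram[len(pattern)] = histogram.get(len(pattern), 0) + 1
        return histogram


def _simulate_site(
    rng: np.random.Generator,
    nodes: list[dendropy.Node],
    leafset: dict,
    loss_prob: float,
) -> tuple[frozenset, frozenset, list[frozenset]]:
    """One canonical single-origin history: (gain clade, present, loss clades).

    Histories are rejection-sampled until the raw events are identifiable
    from the leaf pattern: the origin is the MRCA of the surviving leaves
    and every loss subtree has a surviving sibling lineage.  The checks are
    structural and do not use the inference code.
    """
    for _ in range(10_000):
        origin = nodes[int(rng.integers(len(nodes)))]
        present_leaves: set[str] = set()
        loss_nodes: list[dendropy.Node] = []

        def descend(node: dendropy.Node) -> None:
            if node.is_leaf():
                present_leaves.add(node.taxon.label)
                return
            for child in node.child_nodes():
                if loss_prob > 0 and rng.random() < loss_prob:
                    loss_nodes.append(child)
                else:
                    descend(child)

        descend(origin)
        if not present_leaves:
            continue
        # origin must be the MRCA of the survivors
        if origin.is_leaf():
            ok = True
        else:
            ok = all(
                leafset[child] & present_leaves for child in origin.child_nodes()
            )
        # each loss must leave a surviving lineage on its parent
        for lost in loss_nodes:
            if not ok:
                break
            parent = lost.parent_node
            ok = any(
                leafset[sib] & present_leaves
                for sib in parent.child_nodes()
                if sib is not lost
            )
        if not ok:
            continue
        return (
            leafset[origin],
            frozenset(present_leaves),
            [leafset[n] for n in loss_nodes],
        )
    raise RuntimeError("could not sample a canonical site history")


def generate_intron_history(
    tree: dendropy.Tree,
    n_sites: int,
    per_branch_loss_prob: float,
    seed: int,
    out_dir: str | Path,
    sites_per_cluster: int = 5,
    plant_indel_for: str | None = None,
    indel_residues: int = 2,
) -> tuple[list[Path], IntronHistoryTruth]:
    """Evolve intron sites under single-origin dynamics and emit clusters.

    Each site originates once on a uniformly sampled tree node and is lost
    independently on each descendant branch with ``per_branch_loss_prob``.
    Emitted cluster alignments are gap-free unless ``plant_indel_for``
    names a species: then, in each cluster where that species lacks the
    first site, an ``indel_residues``-long insertion is planted there.
    """
    if not 0.0 <= per_branch_loss_prob <= 1.0:
        raise ValueError("per_branch_loss_prob must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    leafset = _leafsets(tree)
    nodes = list(tree.preorder_node_iter())
    roster = sorted(leafset[tree.seed_node])

    truth = IntronHistoryTruth()
    paths: list[Path] = []
    site_queue: list[tuple[frozenset, frozenset, list[frozenset]]] = []
    for _ in range(n_sites):
        gain, present, losses = _simulate_site(rng, nodes, leafset, per_branch_loss_prob)
        truth.gains[gain] = truth.gains.get(gain, 0) + 1
        for clade in losses:
            truth.losses[clade] = truth.losses.get(clade, 0) + 1
        truth.site_patterns.append(present)
        site_queue.append((gain, present, losses))

    flank = 8  # residues around each site, enough for default filters
    cluster_index = 0
    for chunk_start in range(0, len(site_queue), sites_per_cluster):
        chunk = site_queue[chunk_start : chunk_start + sites_per_cluster]
        cluster_index += 1
        cluster_id = f"cluster{cluster_index:04d}"
        length = flank + len(chunk) * (flank + 1)
        site_positions = [flank + i * (flank + 1) for i in range(len(chunk))]
        phases = [int(rng.integers(0, 3)) for _ in chunk]
        sequences: dict[str, AlignedSequence] = {}
        for species in roster:
            residues = "".join(
                AMINO_ACIDS[int(i)]
                for i in rng.integers(0, len(AMINO_ACIDS), size=length)
            )
            sites = tuple(
                (3 * s + p, p, s)
                for s, p, (_, present, _) in zip(site_positions, phases, chunk)
                if species in present
            )
            annotation = ProteinIntronAnnotation(
                f"{cluster_id}_{species}", species, length, sites
            )
            sequences[species] = AlignedSequence(species, residues, annotation)
        cluster = AlignedOrthogroup(cluster_id, sequences)
        if plant_indel_for is not None:
            cluster = _maybe_plant_indel(
                cluster, chunk, site_positions, phases,
                plant_indel_for, indel_residues, truth,
            )
        path = out_dir / f"{cluster_id}.fasta"
        from .intron_evolution import write_cluster_fasta

        write_cluster_fasta(cluster, path)
        paths.append(path)
    return paths, truth


def _maybe_plant_indel(
    cluster: AlignedOrthogroup,
    chunk: list,
    site_positions: list[int],
    phases: list[int],
    focal: str,
    n_residues: int,
    truth: IntronHistoryTruth,
) -> AlignedOrthogroup:
    """Insert residues into the focal sequence at its first lost site."""
    target = None
    for s, p, (_, present, _) in zip(site_positions, phases, chunk):
        if focal not in present:
            target = (s, p)
            break
    if target is None:
        return cluster
    column, phase = target
    new_sequences: dict[str, AlignedSequence] = {}
    for species, seq in cluster.sequences.items():
        if species == focal:
            inserted = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(n_residues))
            aligned = seq.aligned[:column] + inserted + seq.aligned[column:]
            sites = tuple(
                (c + 3 * n_residues, p, s + n_residues) if s >= column else (c, p, s)
                for c, p, s in seq.annotation.sites
            )
            annotation = ProteinIntronAnnotation(
                seq.annotation.sequence_id,
                species,
                seq.annotation.protein_length + n_residues,
                sites,
            )
        else:
            aligned = seq.aligned[:column] + "-" * n_residues + seq.aligned[column:]
            annotation = seq.annotation
        new_sequences[species] = AlignedSequence(species, aligned, annotation)
    # after insertion the bearers' residues shift, so the site projects to
    # column + n_residues in the padded alignment
    truth.indel_plants.append(
        (cluster.cluster_id, column + n_residues, phase, n_residues)
    )
    return AlignedOrthogroup(cluster.cluster_id, new_sequences)


# ---------------------------------------------------------------------------
# HGT hit tables


@dataclass
class HgtTruth:
    planted: set[str]
    expected: dict[str, tuple[float | None, float | None]]  # query -> (met, nonmet)


METAZOAN_DBS = ("metdb1", "metdb2")
NONMETAZOAN_DBS = ("bacdb", "fundb", "plantdb")


def generate_hgt_table(
    n_queries: int,
    n_planted: int,
    margin: float,
    seed: int,
    out_dir: str | Path,
    min_score: float = 75.0,
    min_h: float = 30.0,
) -> tuple[Path, Path, HgtTruth]:
    """BLAST tabular best-hit table with planted HGT candidates.

    Planted queries clear both thresholds by at least ``margin`` bits;
    background queries violate at least one threshold by at least
    ``margin``.
    """
    if n_planted > n_queries:
        raise ValueError("n_planted exceeds n_queries")
    if margin <= 0:
        raise ValueError("margin must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    planted = {
        f"q{int(i):04d}"
        for i in rng.choice(n_queries, size=n_planted, replace=False)
    }
    rows: list[str] = []
    expected: dict[str, tuple[float | None, float | None]] = {}

    def emit(query: str, db: str, bitscore: float) -> None:
        subject = f"{db}|s{rng.integers(0, 99999):05d}"
        rows.append(
            f"{query}\t{subject}\t{rng.uniform(30, 99):.1f}\t"
            f"{rng.integers(50, 500)}\t{rng.integers(0, 50)}\t"
            f"{rng.integers(0, 5)}\t1\t100\t1\t100\t1e-10\t{bitscore:.1f}"
        )

    for i in range(n_queries):
        query = f"q{i:04d}"
        if query in planted:
            nonmet = min_score + margin + float(rng.uniform(0, 60))
            # half the planted queries have no metazoan hit at all
            if rng.random() < 0.5:
                met: float | None = None
                if nonmet < min_h + margin:
                    nonmet = min_h + margin + float(rng.uniform(0, 30))
            else:
                ceiling = nonmet - (min_h + margin)
                met = float(rng.uniform(0, max(ceiling, 0.0)))
        else:
            if rng.random() < 0.5:
                # weak non-metazoan signal
                nonmet = float(rng.uniform(25, min_score - margin))
                met = float(rng.uniform(nonmet, nonmet + 100))
            else:
                # strong non-metazoan score but small h
                nonmet = min_score + float(rng.uniform(0, 100))
                met = nonmet - (min_h - margin) + float(rng.uniform(0, 80))
        for db in NONMETAZOAN_DBS:
            # best non-metazoan hit plus weaker decoys
            emit(query, db, nonmet if db == NONMETAZOAN_DBS[0] else nonmet * 0.5)
        if met is not None:
            emit(query, METAZOAN_DBS[0], met)
            emit(query, METAZOAN_DBS[1], met * 0.7)
        expected[query] = (met, nonmet)

    hits_path = out_dir / "best_hits.tsv"
    hits_path.write_text("\n".join(rows) + "\n")
    classes_path = out_dir / "db_classes.tsv"
    with open(classes_path, "w") as fh:
        for db in METAZOAN_DBS:
            fh.write(f"{db}\tmetazoan\n")
        for db in NONMETAZOAN_DBS:
            fh.write(f"{db}\tnonmetazoan\n")
    return hits_path, classes_path, HgtTruth(planted, expected)


# ---------------------------------------------------------------------------
# repeat landscapes


@dataclass
class RepeatTruth:
    masked_bp_by_class: dict[str, int]
    total_masked_bp: int
    assembly_length: int

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.total_masked_bp / self.assembly_length


TE_CLASSES = ("DNA/hAT", "LINE/L2", "LTR/Gypsy", "RC/Helitron", "Unknown")

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query     matching"
    "  repeat         position in repeat\n"
    "score  div. del. ins.  sequence  begin end    (left)   repeat"
    "    class/family  begin  end (left)  ID\n"
    "\n"
)


def generate_repeat_landscape(
    scaffolds: list[Scaffold],
    target_coverage_pct: float,
    seed: int,
    out_dir: str | Path,
    overlap_fraction: float = 0.3,
) -> tuple[Path, RepeatTruth]:
    """RepeatMasker ``.out`` file whose resolved TE coverage is known exactly.

    A fraction of the planted intervals is emitted as overlapping hit pairs
    (high score over low score) to exercise score-based overlap resolution;
    the ledger accounts for the per-base winner.  Simple repeats are added
    in unmasked regions and are not part of the target coverage.
    """
    if not 0.0 <= target_coverage_pct < 100.0:
        raise ValueError("target_coverage_pct must be in [0, 100)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    total_bp = sum(sc.length for sc in scaffolds)
    target_bp = int(round(total_bp * target_coverage_pct / 100.0))

    masked: dict[str, int] = {}
    lines: list[str] = []
    hit_id = 0

    def emit(scaffold: str, start: int, end: int, score: int, cls: str,
             flagged: bool = False) -> None:
        nonlocal hit_id
        hit_id += 1
        name = f"rep{hit_id:04d}"
        div = rng.uniform(0.5, 25.0)
        star = " *" if flagged else ""
        lines.append(
            f"{score:5d} {div:4.1f}  0.0  0.0  {scaffold} {start:7d} {end:7d} "
            f"(0) + {name}  {cls} 1 {end - start + 1} (0) {hit_id}{star}"
        )

    remaining = target_bp
    cursor_by_scaffold = {sc.id: 1 for sc in scaffolds}
    scaffold_cycle = [sc for sc in scaffolds]
    idx = 0
    free_regions: list[tuple[str, int, int]] = []
    while remaining > 0:
        sc = scaffold_cycle[idx % len(scaffold_cycle)]
        idx += 1
        cursor = cursor_by_scaffold[sc.id]
        if cursor > sc.length - 10:
            if all(
                cursor_by_scaffold[s.id] > s.length - 10 for s in scaffold_cycle
            ):
                raise ValueError(
                    "generate_repeat_landscape: target coverage infeasible for "
                    "the supplied scaffold lengths"
                )
            continue
        gap = int(rng.integers(5, 50))
        start = cursor + gap
        length = int(min(remaining, rng.integers(20, 200)))
        end = start + length - 1
        if end > sc.length:
            cursor_by_scaffold[sc.id] = sc.length + 1
            continue
        cls = TE_CLASSES[int(rng.integers(len(TE_CLASSES)))]
        if length >= 40 and rng.random() < overlap_fraction:
            # split into an overlapping pair: high score wins the overlap
            mid = start + length // 2
            overlap = int(rng.integers(5, min(20, length // 3)))
            cls2 = TE_CLASSES[int(rng.integers(len(TE_CLASSES)))]
            emit(sc.id, start, mid, 500, cls)
            emit(sc.id, mid - overlap + 1, end, 300, cls2, flagged=True)
            masked[cls] = masked.get(cls, 0) + (mid - start + 1)
            if cls2 != cls:
                masked[cls2] = masked.get(cls2, 0) + (end - mid)
            else:
                masked[cls] = masked.get(cls, 0) + (end - mid)
        else:
            emit(sc.id, start, end, int(rng.integers(250, 2000)), cls)
            masked[cls] = masked.get(cls, 0) + length
        free_regions.append((sc.id, cursor, start - 1))
        cursor_by_scaffold[sc.id] = end + 1
        remaining -= length

    # sprinkle simple repeats into leftover gaps; excluded by the TE filter
    for sid, lo, hi in free_regions[:5]:
        if hi - lo >= 12:
            emit(sid, lo + 1, lo + 10, 40, "Simple_repeat")

    path = out_dir / "repeats.out"
    path.write_text(_RM_HEADER + "\n".join(lines) + ("\n" if lines else ""))
    return path, RepeatTruth(masked, sum(masked.values()), total_bp)
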