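"""Intron-site projection, cross-species site tables, and Dollo inference.

Intron positions are carried on protein sequences as ``(c, p, s)`` triples:
``c`` coding nucleotides 5' of the splice junction, phase ``p = c mod 3``,
and 0-based residue index ``s = floor(c / 3)``.  A phase-0 site sits
immediately before residue ``s``; phase-1/2 sites interrupt residue ``s``'s
codon.  Projection onto a protein alignment maps ``s`` to its alignment
column, and a site is identified by the (column, phase) pair — equal
columns with different phases are distinct sites.

Gain/loss inference uses Dollo parsimony: each site originates exactly once,
at the most recent common ancestor of the species carrying it, and losses
are placed on the minimal set of branches consistent with that single
origin.  Species with no sequence in a cluster, or failing the flank rule,
are *ambiguous*, never counted as losses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .annotation_io import AnnotationError, TranscriptModel
from .genome_metrics import extract_cds_introns

__all__ = [
    "ProteinIntronAnnotation",
    "AlignedSequence",
    "AlignedOrthogroup",
    "IntronSite",
    "IntronSiteTable",
    "BranchTallies",
    "LossClassification",
    "annotate_protein_introns",
    "project_sites",
    "filter_unambiguous",
    "select_clusters",
    "dollo_events",
    "presence_histogram",
    "classify_loss_precision",
    "load_species_tree",
    "read_cluster_fasta",
    "write_cluster_fasta",
]

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ProteinIntronAnnotation:
    sequence_id: str
    species: str
    protein_length: int
    sites: tuple[tuple[int, int, int], ...]  # (c_upstream, phase, residue_index)

    def __post_init__(self) -> None:
        for c, p, s in self.sites:
            if s != c // 3 or p != c % 3:
                raise ValueError(
                    f"{self.sequence_id}: inconsistent site ({c},{p},{s})"
                )
            if not 0 <= s < self.protein_length:
                raise ValueError(
                    f"{self.sequence_id}: residue index {s} outside protein "
                    f"of {self.protein_length} residues"
                )


@dataclass(frozen=True)
class AlignedSequence:
    species: str
    aligned: str
    annotation: ProteinIntronAnnotation

    def __post_init__(self) -> None:
        degapped = sum(1 for ch in self.aligned if ch not in GAP_CHARS)
        if degapped != self.annotation.protein_length:
            raise ValueError(
                f"{self.annotation.sequence_id}: degapped length {degapped} != "
                f"annotated protein length {self.annotation.protein_length}"
            )

    def residue_columns(self) -> list[int]:
        """Alignment column of each residue, in residue order."""
        return [i for i, ch in enumerate(self.aligned) if ch not in GAP_CHARS]


@dataclass
class AlignedOrthogroup:
    cluster_id: str
    sequences: dict[str, AlignedSequence]  # keyed by species; <=1 per species

    def __post_init__(self) -> None:
        lengths = {len(s.aligned) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.cluster_id}: ragged alignment {sorted(lengths)}")
        for species, seq in self.sequences.items():
            if seq.species != species:
                raise ValueError(f"{self.cluster_id}: species key mismatch")

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.sequences.values())).aligned)


@dataclass
class IntronSite:
    column: int
    phase: int
    states: dict[str, str]  # species -> present/absent/ambiguous

    def present_species(self) -> set[str]:
        return {sp for sp, st in self.states.items() if st == PRESENT}

    def absent_species(self) -> set[str]:
        return {sp for sp, st in self.states.items() if st == ABSENT}


@dataclass
class IntronSiteTable:
    cluster_id: str
    roster: tuple[str, ...]
    sites: list[IntronSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(s.column, s.phase) for s in self.sites]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.cluster_id}: duplicate (column, phase) sites")


@dataclass(frozen=True)
class LossClassification:
    cluster_id: str
    column: int
    phase: int
    focal_species: str
    verdict: str  # "precise" | "imprecise"
    indel_residues: int

    def __post_init__(self) -> None:
        if (self.verdict == "precise") != (self.indel_residues == 0):
            raise ValueError("verdict inconsistent with indel_residues")


def annotate_protein_introns(
    transcript: TranscriptModel, allow_partial_codon: bool = False
) -> ProteinIntronAnnotation:
    """Translate a transcript's CDS introns into protein-coordinate sites."""
    total = transcript.coding_length
    if total % 3 != 0:
        if not allow_partial_codon:
            raise AnnotationError(
                f"transcript {transcript.id!r}: coding length {total} is not a "
                "multiple of 3 (pass allow_partial_codon=True to truncate)"
            )
    protein_length = total // 3
    sites = []
    for intron in extract_cds_introns(transcript):
        c = intron.c_upstream
        if c <= 0 or c >= total:
            raise AnnotationError(
                f"transcript {transcript.id!r}: invalid intron placement at "
                f"c_upstream={c} of {total} coding nt"
            )
        s = c // 3
        if s >= protein_length:  # junction inside a trailing partial codon
            raise AnnotationError(
                f"transcript {transcript.id!r}: intron at c_upstream={c} falls "
                "beyond the last complete codon"
            )
        sites.append((c, c % 3, s))
    return ProteinIntronAnnotation(
        transcript.id, transcript.gene_id, protein_length, tuple(sites)
    )


def project_sites(
    cluster: AlignedOrthogroup, roster: Sequence[str] | None = None
) -> IntronSiteTable:
    """Map every per-sequence intron onto alignment columns and merge.

    Species in the roster without a sequence in the cluster are ambiguous
    at every site; species with a sequence but no intron at a site are
    absent there.
    """
    roster = tuple(roster) if roster is not None else tuple(sorted(cluster.sequences))
    by_key: dict[tuple[int, int], IntronSite] = {}
    for species, seq in cluster.sequences.items():
        columns = seq.residue_columns()
        for c, p, s in seq.annotation.sites:
            if s >= len(columns):
                raise ValueError(
                    f"{cluster.cluster_id}/{species}: residue index {s} beyond "
                    f"degapped length {len(columns)}"
                )
            key = (columns[s], p)
            site = by_key.get(key)
            if site is None:
                states = {
                    sp: (ABSENT if sp in cluster.sequences else AMBIGUOUS)
                    for sp in roster
                }
                site = by_key[key] = IntronSite(key[0], key[1], states)
            site.states[species] = PRESENT
    sites = [by_key[k] for k in sorted(by_key)]
    return IntronSiteTable(cluster.cluster_id, roster, sites)


def _flank_ok(aligned: str, column: int, min_flank: int) -> bool:
    left = sum(1 for ch in aligned[:column] if ch not in GAP_CHARS)
    right = sum(1 for ch in aligned[column + 1 :] if ch not in GAP_CHARS)
    return left >= min_flank and right >= min_flank


def filter_unambiguous(
    table: IntronSiteTable,
    cluster: AlignedOrthogroup,
    focal: str,
    min_flank: int = 5,
    min_other_species: int = 11,
) -> IntronSiteTable:
    """Keep sites that are unambiguous in the focal species and enough others.

    A species is unambiguous at a site when it has a sequence in the cluster
    with at least ``min_flank`` non-gap residues on each side of the site's
    column; otherwise its state becomes ambiguous.  Retained sites have an
    unambiguous focal species and >= ``min_other_species`` unambiguous other
    species, and still carry the intron in at least one species.
    """
    kept: list[IntronSite] = []
    for site in table.sites:
        states = dict(site.states)
        for species in table.roster:
            seq = cluster.sequences.get(species)
            if seq is None:
                states[species] = AMBIGUOUS
            elif not _flank_ok(seq.aligned, site.column, min_flank):
                states[species] = AMBIGUOUS
        if states.get(focal, AMBIGUOUS) == AMBIGUOUS:
            continue
        n_other = sum(
            1 for sp, st in states.items() if sp != focal and st != AMBIGUOUS
        )
        if n_other < min_other_species:
            continue
        if not any(st == PRESENT for st in states.values()):
            continue
        kept.append(IntronSite(site.column, site.phase, states))
    return IntronSiteTable(table.cluster_id, table.roster, kept)


def select_clusters(
    matrix,
    focal: str,
    min_other_species: int = 14,
    max_copies: int = 3,
) -> list[str]:
    """Cluster ids usable for intron analysis.

    ``matrix`` is an orthogroup-by-species count table (an
    :class:`~genarch.family_dynamics.OrthogroupMatrix` or a pandas
    DataFrame with orthogroups as rows).  A cluster passes when the focal
    species has >=1 member, at least ``min_other_species`` other species
    are represented, and no species exceeds ``max_copies`` members.
    """
    counts = getattr(matrix, "counts", matrix)
    if focal not in counts.columns:
        raise KeyError(f"focal species {focal!r} not in roster")
    keep = (
        (counts[focal] >= 1)
        & ((counts.drop(columns=focal) >= 1).sum(axis=1) >= min_other_species)
        & (counts.le(max_copies).all(axis=1))
    )
    return list(counts.index[keep])


# ---------------------------------------------------------------------------
# species trees and Dollo parsimony


def load_species_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick species tree (path or literal string)."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.is_rooted = True
    seed = tree.seed_node
    if len(seed.child_nodes()) > 2:
        raise ValueError("species tree must be rooted (binary at the root)")
    return tree


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    leafset: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[node] = frozenset({node.taxon.label})
        else:
            leafset[node] = frozenset().union(
                *(leafset[c] for c in node.child_nodes())
            )
    return leafset


@dataclass
class BranchTallies:
    """Per-branch gain/loss counts, keyed by the branch's descendant clade."""

    tree: dendropy.Tree
    gains: dict[frozenset[str], int] = field(default_factory=dict)
    losses: dict[frozenset[str], int] = field(default_factory=dict)

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())

    def losses_for(self, *species: str) -> int:
        return self.losses.get(frozenset(species), 0)

    def gains_for(self, *species: str) -> int:
        return self.gains.get(frozenset(species), 0)


def dollo_events(
    tables: IntronSiteTable | Iterable[IntronSiteTable], tree: dendropy.Tree
) -> BranchTallies:
    """Single-origin gain/loss reconstruction over one or more site tables.

    Per site, one gain is placed at the MRCA of all present species, and
    losses at the minimal set of branches below it that explains every
    absent species.  Ambiguous species take whichever state avoids a loss.
    """
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError("dollo_events requires a rooted tree")
    if isinstance(tables, IntronSiteTable):
        tables = [tables]
    leafset = _leafsets(tree)
    tallies = BranchTallies(tree)
    for table in tables:
        tree_leaves = leafset[tree.seed_node]
        missing = set(table.roster) - tree_leaves
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        for site in table.sites:
            present = site.present_species()
            absent = site.absent_species()
            if not present:
                raise ValueError(
                    f"{table.cluster_id}: site ({site.column},{site.phase}) "
                    "has no present species"
                )
            gain_node = _mrca(tree, leafset, present)
            tallies.gains[leafset[gain_node]] = (
                tallies.gains.get(leafset[gain_node], 0) + 1
            )
            for lost in _minimal_loss_branches(gain_node, leafset, present, absent):
                tallies.losses[leafset[lost]] = tallies.losses.get(leafset[lost], 0) + 1
    return tallies


def _mrca(
    tree: dendropy.Tree,
    leafset: Mapping[dendropy.Node, frozenset[str]],
    species: set[str],
) -> dendropy.Node:
    node = tree.seed_node
    if not species <= leafset[node]:
        raise ValueError(f"species {sorted(species - leafset[node])} not in tree")
    while True:
        for child in node.child_nodes():
            if species <= leafset[child]:
                node = child
                break
        else:
            return node


def _minimal_loss_branches(
    gain_node: dendropy.Node,
    leafset: Mapping[dendropy.Node, frozenset[str]],
    present: set[str],
    absent: set[str],
) -> list[dendropy.Node]:
    """Roots of maximal subtrees under the gain with absences and no presence."""
    losses: list[dendropy.Node] = []
    stack = [gain_node]
    while stack:
        node = stack.pop()
        leaves = leafset[node]
        if leaves & present:
            stack.extend(node.child_nodes())
        elif leaves & absent:
            losses.append(node)
        # all-ambiguous subtrees stay notionally present: no loss
    return losses


def presence_histogram(
    tables: IntronSiteTable | Iterable[IntronSiteTable],
) -> dict[int, int]:
    """Counts of sites keyed by their number of present species."""
    if isinstance(tables, IntronSiteTable):
        tables = [tables]
    histogram: dict[int, int] = {}
    for table in tables:
        for site in table.sites:
            n = len(site.present_species())
            histogram[n] = histogram.get(n, 0) + 1
    return histogram


def classify_loss_precision(
    cluster: AlignedOrthogroup,
    site: IntronSite,
    focal: str,
    window: int = 5,
) -> LossClassification:
    """Call a focal-species intron loss precise or imprecise.

    Within ``window`` columns either side of the site, a column is
    discordant when the focal sequence has a residue where at least half of
    the intron-bearing sequences have gaps, or a gap where at least half
    have residues.  Zero discordant columns => precise.
    """
    if site.states.get(focal) == PRESENT:
        raise ValueError(f"{focal!r} still carries the intron at this site")
    focal_seq = cluster.sequences.get(focal)
    if focal_seq is None:
        raise ValueError(f"{focal!r} has no sequence in {cluster.cluster_id!r}")
    bearers = [
        cluster.sequences[sp]
        for sp in site.present_species()
        if sp in cluster.sequences
    ]
    if not bearers:
        raise ValueError("site has no intron-bearing sequences in the cluster")
    length = cluster.alignment_length
    lo = max(0, site.column - window)
    hi = min(length - 1, site.column + window)
    indel = 0
    for col in range(lo, hi + 1):
        focal_gap = focal_seq.aligned[col] in GAP_CHARS
        bearer_gaps = sum(1 for b in bearers if b.aligned[col] in GAP_CHARS)
        majority_gap = bearer_gaps * 2 >= len(bearers)
        majority_residue = (len(bearers) - bearer_gaps) * 2 >= len(bearers)
        if not focal_gap and majority_gap:
            indel += 1
        elif focal_gap and majority_residue:
            indel += 1
    verdict = "precise" if indel == 0 else "imprecise"
    return LossClassification(
        cluster.cluster_id, site.column, site.phase, focal, verdict, indel
    )


# ---------------------------------------------------------------------------
# cluster FASTA dialect: >species|sequence_id|i:c,p;c,p;...

_HEADER_RE = re.compile(r"^(?P<species>[^|]+)\|(?P<seqid>[^|]+?)(\|i:(?P<sites>.*))?$")


def read_cluster_fasta(path: str | Path, cluster_id: str | None = None) -> AlignedOrthogroup:
    """Read an aligned cluster FASTA with header-encoded intron positions."""
    path = Path(path)
    sequences: dict[str, AlignedSequence] = {}
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        m = _HEADER_RE.match(header)
        if not m:
            raise ValueError(f"{path}: malformed header {header!r}")
        species, seqid = m.group("species"), m.group("seqid")
        aligned = "".join(chunks)
        protein_length = sum(1 for ch in aligned if ch not in GAP_CHARS)
        sites = []
        raw = m.group("sites")
        if raw:
            for token in raw.split(";"):
                if not token:
                    continue
                c_str, p_str = token.split(",")
                c, p = int(c_str), int(p_str)
                sites.append((c, p, c // 3))
        annotation = ProteinIntronAnnotation(seqid, species, protein_length, tuple(sites))
        if species in sequences:
            raise ValueError(f"{path}: more than one sequence for {species!r}")
        sequences[species] = AlignedSequence(species, aligned, annotation)

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            elif line:
                chunks.append(line.strip())
        flush()
    if not sequences:
        raise ValueError(f"{path}: no sequences found")
    return AlignedOrthogroup(cluster_id or path.stem, sequences)


def write_cluster_fasta(cluster: AlignedOrthogroup, path: str | Path) -> None:
    with open(path, "w") as fh:
        for species in sorted(cluster.sequences):
            seq = cluster.sequences[species]
            header = f">{species}|{seq.annotation.sequence_id}"
            if seq.annotation.sites:
                header += "|i:" + ";".join(
                    f"{c},{p}" for c, p, _ in seq.annotation.sites
                )
            fh.write(header + "\n")
            fh.write(seq.aligned + "\n")
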