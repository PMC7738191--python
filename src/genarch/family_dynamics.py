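"""Orthogroup count-matrix filters.

All operations are deterministic set filters over an orthogroup x species
count table (OrthoFinder ``Orthogroups.GeneCount`` layout).  Birth-death
modeling of family sizes is deliberately out of scope; this module only
prepares inputs and computes the deterministic summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OrthogroupMatrix",
    "CafeInputSets",
    "cafe_prepare",
    "mini_expansions",
    "absent_conserved",
    "single_copy",
    "essential_overlap",
]


@dataclass
class OrthogroupMatrix:
    """Orthogroup-by-species non-negative integer count table."""

    counts: pd.DataFrame
    species_classes: dict[str, str] | None = None  # e.g. arthropod / outgroup

    def __post_init__(self) -> None:
        if self.counts.columns.empty:
            raise ValueError("species roster is empty")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate orthogroup ids: {dupes[:5]}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in orthogroup matrix")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.counts.index)

    def species_of_class(self, label: str) -> list[str]:
        if self.species_classes is None:
            raise ValueError("no species class labels supplied")
        return [sp for sp in self.species if self.species_classes.get(sp) == label]

    @classmethod
    def from_tsv(
        cls, path: str | Path, classes_path: str | Path | None = None
    ) -> "OrthogroupMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        # OrthoFinder appends a Total column; drop it if present
        if "Total" in counts.columns:
            counts = counts.drop(columns="Total")
        counts = counts.astype(int)
        classes = None
        if classes_path is not None:
            table = pd.read_csv(
                classes_path, sep="\t", header=None, names=["species", "class"]
            )
            classes = dict(zip(table["species"], table["class"]))
        return cls(counts, classes)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="Orthogroup")


@dataclass(frozen=True)
class CafeInputSets:
    retained: tuple[str, ...]
    small: tuple[str, ...]   # <large_cutoff copies in every species
    large: tuple[str, ...]   # >=large_cutoff copies in >=1 species

    def __post_init__(self) -> None:
        if set(self.small) | set(self.large) != set(self.retained):
            raise ValueError("small and large sets do not partition retained")
        if set(self.small) & set(self.large):
            raise ValueError("small and large sets overlap")


def cafe_prepare(
    matrix: OrthogroupMatrix, min_species: int = 10, large_cutoff: int = 100
) -> CafeInputSets:
    """Presence filter and small/large split of the count matrix."""
    counts = matrix.counts
    if min_species > len(counts.columns):
        raise ValueError(
            f"min_species={min_species} exceeds roster size {len(counts.columns)}"
        )
    retained_mask = (counts >= 1).sum(axis=1) >= min_species
    retained = counts.index[retained_mask]
    large_mask = (counts.loc[retained] >= large_cutoff).any(axis=1)
    large = retained[large_mask]
    small = retained[~large_mask]
    return CafeInputSets(tuple(retained), tuple(small), tuple(large))


def mini_expansions(
    matrix: OrthogroupMatrix,
    focal: str,
    relatives: Sequence[str],
    min_members: int = 5,
    fold: float = 2.0,
) -> list[str]:
    """Orthogroups expanded in the focal species relative to close relatives.

    Kept when the focal count exceeds ``min_members`` (strict) and is at
    least ``fold`` times the mean count across ``relatives`` (inclusive).
    """
    if focal in relatives:
        raise ValueError("focal species may not be among the relatives")
    counts = matrix.counts
    relative_mean = counts[list(relatives)].mean(axis=1)
    keep = (counts[focal] > min_members) & (counts[focal] >= fold * relative_mean)
    return list(counts.index[keep])


def absent_conserved(
    matrix: OrthogroupMatrix, focal: str, required: Sequence[str]
) -> list[str]:
    """Orthogroups missing from the focal species but present in every
    required species."""
    required = list(required)
    if not required:
        raise ValueError("required species set is empty")
    if focal in required:
        raise ValueError("required species set must exclude the focal species")
    counts = matrix.counts
    keep = (counts[focal] == 0) & (counts[required] >= 1).all(axis=1)
    return list(counts.index[keep])


def single_copy(matrix: OrthogroupMatrix) -> list[str]:
    """Orthogroups with exactly one member in every species."""
    counts = matrix.counts
    return list(counts.index[(counts == 1).all(axis=1)])


def essential_overlap(
    matrix: OrthogroupMatrix,
    gene_to_og: Mapping[str, str],
    essential_genes: Sequence[str],
    clade: Sequence[str],
    focal: str,
) -> tuple[int, int, int]:
    """Overlap of essential genes' orthogroups with clade/focal absences.

    Returns ``(n_essential_ogs, n_absent_in_clade, n_absent_in_focal_only)``
    where the last counts orthogroups with zero focal members but at least
    one member in some other clade species.  Essential genes with no
    orthogroup mapping are logged and skipped.
    """
    counts = matrix.counts
    ogs: set[str] = set()
    for gene in essential_genes:
        og = gene_to_og.get(gene)
        if og is None:
            logger.warning("essential gene %r not mapped to any orthogroup", gene)
            continue
        if og in counts.index:
            ogs.add(og)
    clade = list(clade)
    others = [sp for sp in clade if sp != focal]
    n_absent_clade = 0
    n_absent_focal_only = 0
    for og in ogs:
        row = counts.loc[og]
        if all(row[sp] == 0 for sp in clade):
            n_absent_clade += 1
        elif row[focal] == 0 and any(row[sp] >= 1 for sp in others):
            n_absent_focal_only += 1
    return len(ogs), n_absent_clade, n_absent_focal_only
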