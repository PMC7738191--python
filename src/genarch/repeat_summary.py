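"""RepeatMasker output parsing and per-base TE coverage.

Overlapping hits are resolved per base in favour of the highest
Smith-Waterman score (ties go to the earlier hit in file order), so no
base is counted in more than one repeat class.  The coverage denominator
is the supplied assembly length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation_io import GenomeAnnotation, Scaffold
from .genome_metrics import merge_cds_union

__all__ = [
    "RepeatHit",
    "CoverageReport",
    "DEFAULT_NON_TE_CLASSES",
    "parse_repeatmasker_out",
    "te_coverage",
    "window_density",
]

# RepeatMasker classes that are repeats but not transposable elements
DEFAULT_NON_TE_CLASSES = frozenset(
    {"Simple_repeat", "Low_complexity", "Satellite", "rRNA", "snRNA", "tRNA",
     "scRNA", "srpRNA", "ARTEFACT"}
)


@dataclass(frozen=True)
class RepeatHit:
    scaffold_id: str
    start: int
    end: int
    sw_score: int
    repeat_id: str
    repeat_class: str
    overlap_flagged: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"repeat hit on {self.scaffold_id}: start {self.start} > end {self.end}"
            )
        if self.sw_score < 0:
            raise ValueError("negative Smith-Waterman score")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CoverageReport:
    assembly_length: int
    masked_bp_by_class: dict[str, int]

    @property
    def total_masked_bp(self) -> int:
        return sum(self.masked_bp_by_class.values())

    @property
    def total_pct(self) -> float:
        return 100.0 * self.total_masked_bp / self.assembly_length

    def pct_of(self, repeat_class: str) -> float:
        return 100.0 * self.masked_bp_by_class.get(repeat_class, 0) / self.assembly_length


def parse_repeatmasker_out(path: str | Path) -> list[RepeatHit]:
    """Parse a standard RepeatMasker ``.out`` file (3 header lines)."""
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            # header lines start with the "SW"/"score" banner words
            if fields[0] in ("SW", "score") or fields[0].startswith("perc"):
                continue
            if len(fields) < 14:
                raise ValueError(
                    f"{path}:{lineno}: expected >=14 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            try:
                sw_score = int(fields[0])
                start = int(fields[5])
                end = int(fields[6])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed numeric field")
            hits.append(
                RepeatHit(
                    scaffold_id=fields[4],
                    start=start,
                    end=end,
                    sw_score=sw_score,
                    repeat_id=fields[9],
                    repeat_class=fields[10],
                    overlap_flagged=fields[-1] == "*",
                )
            )
    return hits


def _assign_hits(
    hits: Sequence[RepeatHit], lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-scaffold array of winning hit indices (-1 = unmasked)."""
    winner = {sid: np.full(n, -1, dtype=np.int64) for sid, n in lengths.items()}
    score = {sid: np.full(n, -1, dtype=np.int64) for sid, n in lengths.items()}
    for idx, hit in enumerate(hits):
        if hit.scaffold_id not in lengths:
            raise ValueError(f"hit on unknown scaffold {hit.scaffold_id!r}")
        if hit.end > lengths[hit.scaffold_id]:
            raise ValueError(
                f"hit {hit.repeat_id!r} ends at {hit.end}, beyond scaffold "
                f"{hit.scaffold_id!r} length {lengths[hit.scaffold_id]}"
            )
        sl = slice(hit.start - 1, hit.end)
        better = hit.sw_score > score[hit.scaffold_id][sl]  # strict: ties -> first
        score[hit.scaffold_id][sl][better] = hit.sw_score
        winner[hit.scaffold_id][sl][better] = idx
    return winner


def te_coverage(
    hits: Sequence[RepeatHit],
    scaffolds: Sequence[Scaffold],
    exclude_classes: Iterable[str] | None = DEFAULT_NON_TE_CLASSES,
) -> CoverageReport:
    """Per-class and total masked coverage after overlap resolution.

    ``exclude_classes`` drops non-TE annotation classes before assignment;
    pass ``None`` (or an empty set) to count every class.
    """
    excluded = frozenset(exclude_classes or ())
    kept = [h for h in hits if h.repeat_class not in excluded]
    lengths = {sc.id: sc.length for sc in scaffolds}
    winner = _assign_hits(kept, lengths)
    masked: dict[str, int] = {}
    for array in winner.values():
        indices, counts = np.unique(array[array >= 0], return_counts=True)
        for idx, n in zip(indices, counts):
            cls = kept[idx].repeat_class
            masked[cls] = masked.get(cls, 0) + int(n)
    return CoverageReport(sum(lengths.values()), masked)


def window_density(
    annotation: GenomeAnnotation,
    hits: Sequence[RepeatHit],
    window: int,
    scaffolds: Sequence[Scaffold] | None = None,
    exclude_classes: Iterable[str] | None = DEFAULT_NON_TE_CLASSES,
) -> list[tuple[str, int, int, int, int]]:
    """Coding and TE-masked bp in non-overlapping windows per scaffold.

    Returns ``(scaffold_id, window_start, window_end, coding_bp, te_bp)``
    rows; the last window of a scaffold is truncated to the scaffold end.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if scaffolds is None:
        scaffolds = annotation.scaffolds
    if not scaffolds:
        raise ValueError("window_density: scaffold lengths are required")
    lengths = {sc.id: sc.length for sc in scaffolds}

    excluded = frozenset(exclude_classes or ())
    kept = [h for h in hits if h.repeat_class not in excluded]
    winner = _assign_hits(kept, lengths)

    coding_mask = {sid: np.zeros(n, dtype=bool) for sid, n in lengths.items()}
    for sid, intervals in merge_cds_union(annotation).items():
        for start, end in intervals:
            coding_mask[sid][start - 1 : end] = True

    rows: list[tuple[str, int, int, int, int]] = []
    for sc in scaffolds:
        te_mask = winner[sc.id] >= 0
        for w_start in range(1, sc.length + 1, window):
            w_end = min(w_start + window - 1, sc.length)
            sl = slice(w_start - 1, w_end)
            rows.append(
                (
                    sc.id,
                    w_start,
                    w_end,
                    int(coding_mask[sc.id][sl].sum()),
                    int(te_mask[sl].sum()),
                )
            )
    return rows
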