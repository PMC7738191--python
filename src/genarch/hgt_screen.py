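"""Horizontal-gene-transfer screen from best-hit bitscores.

For each query protein the h-index is the best non-metazoan bitscore minus
the best metazoan bitscore; a query with no metazoan hit scores h equal to
its best non-metazoan bitscore (missing metazoan hit treated as 0, the
permissive convention that cannot miss a true candidate).  Candidates
require best non-metazoan bitscore >= 75 and h >= 30, both inclusive.

Subject sequences in the BLAST tabular input carry their source database
as an id prefix (``dbname|accession``); a two-column map assigns each
database to the ``metazoan`` or ``nonmetazoan`` class.  The focal proteome
must not appear as a subject database (self hits are excluded upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "BestHitRecord",
    "HgtCall",
    "parse_best_hits",
    "read_db_classes",
    "h_index",
    "flag_candidates",
]

METAZOAN = "metazoan"
NONMETAZOAN = "nonmetazoan"


@dataclass(frozen=True)
class BestHitRecord:
    query_id: str
    best_metazoan_bitscore: float | None
    best_nonmetazoan_bitscore: float | None

    def __post_init__(self) -> None:
        for score in (self.best_metazoan_bitscore, self.best_nonmetazoan_bitscore):
            if score is not None and score < 0:
                raise ValueError(f"{self.query_id}: negative bitscore")


@dataclass(frozen=True)
class HgtCall:
    query_id: str
    h: float
    candidate: bool


def read_db_classes(path: str | Path) -> dict[str, str]:
    classes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            db, label = parts
            if label not in (METAZOAN, NONMETAZOAN):
                raise ValueError(
                    f"{path}:{lineno}: class must be {METAZOAN!r} or "
                    f"{NONMETAZOAN!r}, got {label!r}"
                )
            classes[db] = label
    return classes


def parse_best_hits(
    path: str | Path, db_class: Mapping[str, str]
) -> list[BestHitRecord]:
    """Reduce a 12-column BLAST tabular (outfmt 6) file to per-query best
    bitscores within the metazoan and non-metazoan classes."""
    best: dict[str, dict[str, float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                bitscore = float(fields[11])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed bitscore {fields[11]!r}")
            db = subject.split("|", 1)[0]
            try:
                label = db_class[db]
            except KeyError:
                raise ValueError(
                    f"{path}:{lineno}: subject database {db!r} has no class label"
                )
            if query not in best:
                best[query] = {}
                order.append(query)
            scores = best[query]
            if label not in scores or bitscore > scores[label]:
                scores[label] = bitscore
    return [
        BestHitRecord(q, best[q].get(METAZOAN), best[q].get(NONMETAZOAN))
        for q in order
    ]


def h_index(record: BestHitRecord) -> float:
    """Best non-metazoan minus best metazoan bitscore (absent metazoan -> 0)."""
    if record.best_nonmetazoan_bitscore is None:
        raise ValueError(f"{record.query_id}: no non-metazoan hit; no call is made")
    metazoan = record.best_metazoan_bitscore or 0.0
    return record.best_nonmetazoan_bitscore - metazoan


def flag_candidates(
    records: Iterable[BestHitRecord],
    min_score: float = 75.0,
    min_h: float = 30.0,
) -> list[HgtCall]:
    """Score all records; queries lacking a non-metazoan hit are skipped."""
    calls: list[HgtCall] = []
    for record in records:
        if record.best_nonmetazoan_bitscore is None:
            logger.info("query %r has no non-metazoan hit; skipped", record.query_id)
            continue
        h = h_index(record)
        candidate = record.best_nonmetazoan_bitscore >= min_score and h >= min_h
        calls.append(HgtCall(record.query_id, h, candidate))
    return calls
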