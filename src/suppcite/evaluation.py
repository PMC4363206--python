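"""Scoring predicted annotations against gold-standard accession lists.

Evaluation is at the level of unique ``(database, accession)`` pairs per
article — the granularity of publisher-supplied accession tagging, which
serves as the gold standard under the automatic protocol.  The manual
protocol models the reviewed reclassification of automatic false positives:
identifiers the tool found that the publisher had simply not tagged can be
moved from FP to TP after human inspection, which enlarges the effective
gold set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pattern_registry import Database, conforms

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "GoldStandard",
    "align_to_gold",
    "apply_manual_overrides",
    "score",
    "round_half_up",
    "metrics_report",
]

log = logging.getLogger(__name__)

Pair = tuple[Database, str]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding, as used in printed report tables (bankers'
    rounding would flip some .xx5 cells)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive and false negative counts; ``tp + fn`` is the
    gold-set size and ``tp + fp`` the predicted-set size."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F-score as percentages in [0, 100].

    Unrounded values are retained; :meth:`rounded` gives the 2-decimal
    report form.
    """

    precision: float
    recall: float
    f_score: float

    def rounded(self, ndigits: int = 2) -> "Metrics":
        return Metrics(
            round_half_up(self.precision, ndigits),
            round_half_up(self.recall, ndigits),
            round_half_up(self.f_score, ndigits),
        )


class GoldStandard:
    """Per-article sets of gold ``(database, accession)`` pairs."""

    def __init__(self, mapping: Mapping[str, Iterable[Pair]]):
        self.mapping: dict[str, set[Pair]] = {
            art: {(Database.coerce(db), acc.upper()) for db, acc in pairs}
            for art, pairs in mapping.items()
        }
        for art, pairs in self.mapping.items():
            for db, acc in pairs:
                if not conforms(db, acc):
                    log.warning(
                        "gold accession %s (%s, article %s) does not conform "
                        "to the database pattern; kept",
                        acc, db.value, art,
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GoldStandard":
        """Read a three-column (article_id, db, accession) TSV."""
        frame = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"article_id", "db", "accession"} - set(frame.columns)
        if missing:
            raise ValueError(f"gold standard TSV missing columns: {missing}")
        mapping: dict[str, set[Pair]] = {}
        for row in frame.itertuples(index=False):
            mapping.setdefault(row.article_id, set()).add(
                (Database.coerce(row.db), row.accession.upper())
            )
        return cls(mapping)

    def __getitem__(self, article_id: str) -> set[Pair]:
        return self.mapping.get(article_id, set())

    @property
    def size(self) -> int:
        return sum(len(p) for p in self.mapping.values())


def align_to_gold(
    predicted: Mapping[str, Iterable[Pair]], gold: GoldStandard
) -> ConfusionCounts:
    """Set comparison of unique pairs per article, summed over articles.

    An article present in the predictions but absent from the gold standard
    contributes only false positives (its gold set is empty), with a
    warning.
    """
    pred_map = {
        art: {(Database.coerce(db), acc.upper()) for db, acc in pairs}
        for art, pairs in predicted.items()
    }
    tp = fp = fn = 0
    for art in pred_map:
        if art not in gold.mapping:
            log.warning("article %s has predictions but no gold entry", art)
    for art in sorted(set(pred_map) | set(gold.mapping)):
        p = pred_map.get(art, set())
        g = gold[art]
        tp += len(p & g)
        fp += len(p - g)
        fn += len(g - p)
    return ConfusionCounts(tp, fp, fn)


def apply_manual_overrides(
    counts: ConfusionCounts, reassignments: int | Sequence
) -> ConfusionCounts:
    """Move reviewed false positives to true positives.

    ``reassignments`` is the list of inspected FP items (or their count).
    Each reassignment does fp→tp; false negatives are untouched, and the
    effective gold set grows by the reassigned items.
    """
    n = reassignments if isinstance(reassignments, int) else len(reassignments)
    if n < 0:
        raise ValueError("cannot reassign a negative number of items")
    if n > counts.fp:
        raise ValueError(
            f"cannot reassign {n} items: only {counts.fp} false positives"
        )
    return ConfusionCounts(counts.tp + n, counts.fp - n, counts.fn)


def score(counts: ConfusionCounts) -> Metrics:
    """Precision, recall and their harmonic mean, as percentages.

    Precision is 100 when there are no false positives and at least one true
    positive; with zero true positives all three metrics are 0.  Metrics are
    undefined (an error) when tp = fp = fn = 0.
    """
    if counts.tp == 0 and counts.fp == 0 and counts.fn == 0:
        raise ValueError("metrics undefined for all-zero counts")
    precision = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return Metrics(precision, recall, f)


def metrics_report(
    rows: Mapping[str, ConfusionCounts], path: str | Path | None = None
) -> pd.DataFrame:
    """Tabulate counts and 2-decimal metrics, one row per labelled
    evaluation (e.g. ``"ENA/automatic"``)."""
    records = []
    for label, counts in rows.items():
        m = score(counts).rounded()
        records.append(
            {
                "evaluation": label,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "precision_pct": m.precision,
                "recall_pct": m.recall,
                "f_score_pct": m.f_score,
            }
        )
    frame = pd.DataFrame(
        records,
        columns=["evaluation", "tp", "fp", "fn",
                 "precision_pct", "recall_pct", "f_score_pct"],
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
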