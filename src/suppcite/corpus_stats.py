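"""Corpus-level citation statistics.

Given per-article annotations, this module computes the descriptive
statistics of database citation practice: per-database mention counts in
article bodies vs supplementary data and their ratio; shared citations
(unique pairs appearing in both body and supplementary data of the same
article); the concentration of supplementary citations in the top fraction
of articles; corpus-level breakdown percentages; and yearly averages.

Counting convention: the body/supplementary totals are mention counts
(every accepted span counts once), while shared citations are unique
``(database, accession)`` pairs per article — a string cannot be "shared"
twice.  The shared percentage is taken against the supplementary mention
total.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotator import DocumentAnnotations
from .document_io import DocumentRecord, Triage
from .evaluation import round_half_up
from .pattern_registry import Database, get_registry

__all__ = [
    "CitationStatsRow",
    "ConcentrationResult",
    "CorpusBreakdown",
    "citation_distribution",
    "top_fraction_concentration",
    "corpus_breakdown",
    "yearly_averages",
    "write_distribution_report",
    "write_concentration_report",
]


@dataclass(frozen=True)
class CitationStatsRow:
    """Per-database body/supplementary citation totals and derived columns.

    ``ratio`` is supplementary mentions per body mention (None when the body
    count is zero — reported as undefined, never as infinity); ``shared_pct``
    is the shared unique-pair count as a percentage of supplementary
    mentions.
    """

    db_id: Database
    supp_count: int
    body_count: int
    shared_count: int
    ratio: float | None
    shared_pct: float | None

    @classmethod
    def from_counts(
        cls,
        db_id: Database | str,
        supp_count: int,
        body_count: int,
        shared_count: int = 0,
    ) -> "CitationStatsRow":
        db = Database.coerce(db_id)
        ratio = supp_count / body_count if body_count > 0 else None
        shared_pct = 100.0 * shared_count / supp_count if supp_count > 0 else None
        return cls(db, supp_count, body_count, shared_count, ratio, shared_pct)


@dataclass(frozen=True)
class ConcentrationResult:
    """How much of a database's supplementary citation volume sits in the
    most citation-rich articles."""

    db_id: Database
    n_articles: int          # articles with >=1 supplementary citation of db
    fraction: float
    n_top: int               # ceil(fraction * n_articles)
    pct_in_top: float


@dataclass(frozen=True)
class CorpusBreakdown:
    """Corpus-wide counts with their derived percentages.

    Percentages of articles are against the total article count; the
    cited-file percentage is against the mineable-file count.
    """

    n_articles_total: int
    n_with_mineable_supp: int
    n_body_cited: int
    n_files_total: int
    n_files_mineable: int
    n_supp_cited_files: int
    n_both_body_and_supp: int

    @property
    def pct_with_mineable_supp(self) -> float:
        return _pct(self.n_with_mineable_supp, self.n_articles_total)

    @property
    def pct_body_cited(self) -> float:
        return _pct(self.n_body_cited, self.n_articles_total)

    @property
    def pct_supp_cited_files(self) -> float:
        return _pct(self.n_supp_cited_files, self.n_files_mineable)

    @property
    def pct_both_body_and_supp(self) -> float:
        return _pct(self.n_both_body_and_supp, self.n_articles_total)

    def to_dict(self) -> dict:
        return {
            "n_articles_total": self.n_articles_total,
            "n_with_mineable_supp": self.n_with_mineable_supp,
            "n_body_cited": self.n_body_cited,
            "n_files_total": self.n_files_total,
            "n_files_mineable": self.n_files_mineable,
            "n_supp_cited_files": self.n_supp_cited_files,
            "n_both_body_and_supp": self.n_both_body_and_supp,
            "pct_with_mineable_supp": round_half_up(self.pct_with_mineable_supp, 2),
            "pct_body_cited": round_half_up(self.pct_body_cited, 2),
            "pct_supp_cited_files": round_half_up(self.pct_supp_cited_files, 2),
            "pct_both_body_and_supp": round_half_up(self.pct_both_body_and_supp, 2),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def _pct(numer: int, denom: int) -> float:
    return 100.0 * numer / denom if denom else 0.0


def citation_distribution(
    corpus: Iterable[DocumentAnnotations],
    registry=None,
) -> list[CitationStatsRow]:
    """One row per database: mention counts per section plus shared unique
    pairs, rows ordered by descending ratio (undefined ratios last)."""
    if registry is None:
        registry = get_registry()
    body = Counter()
    supp = Counter()
    shared = Counter()
    for da in corpus:
        for ann in da.body:
            body[ann.db_id] += 1
        for ann in da.supp_annotations:
            supp[ann.db_id] += 1
        for db, _acc in da.shared_pairs:
            shared[db] += 1
    rows = [
        CitationStatsRow.from_counts(
            row.db_id, supp[row.db_id], body[row.db_id], shared[row.db_id]
        )
        for row in registry
    ]
    return sorted(
        rows,
        key=lambda r: (r.ratio is None, -(r.ratio or 0.0), r.db_id.value),
    )


def top_fraction_concentration(
    corpus: Iterable[DocumentAnnotations],
    db_id: Database | str,
    fraction: float = 0.05,
) -> ConcentrationResult:
    """Share of a database's supplementary mentions held by the top
    ``fraction`` of its citing articles.

    Articles with at least one supplementary citation of the database are
    ranked by their supplementary mention count (descending, ties broken by
    article id for determinism); the top ``ceil(fraction * n)`` articles'
    share of the database's total supplementary mentions is reported.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    db = Database.coerce(db_id)
    per_article = Counter()
    for da in corpus:
        n = sum(1 for ann in da.supp_annotations if ann.db_id == db)
        if n:
            per_article[da.article_id] += n
    if not per_article:
        raise ValueError(f"no supplementary citations for {db.value}")
    ranked = sorted(per_article.items(), key=lambda kv: (-kv[1], kv[0]))
    n_articles = len(ranked)
    n_top = math.ceil(fraction * n_articles)
    total = sum(c for _, c in ranked)
    in_top = sum(c for _, c in ranked[:n_top])
    return ConcentrationResult(
        db_id=db,
        n_articles=n_articles,
        fraction=fraction,
        n_top=n_top,
        pct_in_top=100.0 * in_top / total,
    )


def corpus_breakdown(
    corpus: Sequence[tuple[DocumentRecord, DocumentAnnotations]],
) -> CorpusBreakdown:
    """Corpus-wide counts over (document, annotations) pairs."""
    n_total = len(corpus)
    n_with_supp = 0
    n_body_cited = 0
    n_both = 0
    n_files_total = 0
    n_files_mineable = 0
    n_cited_files = 0
    for doc, da in corpus:
        n_files_total += len(doc.supp_manifest)
        mineable = doc.mineable_files
        n_files_mineable += len(mineable)
        if mineable:
            n_with_supp += 1
        if da.body:
            n_body_cited += 1
        if da.body and da.supp_annotations:
            n_both += 1
        n_cited_files += sum(1 for anns in da.supp.values() if anns)
    return CorpusBreakdown(
        n_articles_total=n_total,
        n_with_mineable_supp=n_with_supp,
        n_body_cited=n_body_cited,
        n_files_total=n_files_total,
        n_files_mineable=n_files_mineable,
        n_supp_cited_files=n_cited_files,
        n_both_body_and_supp=n_both,
    )


def yearly_averages(
    corpus: Sequence[tuple[DocumentRecord, DocumentAnnotations]],
    exclude_db: Iterable[Database | str] | None = None,
) -> pd.DataFrame:
    """Mean citation mentions per article and year, over articles that have
    mineable supplementary data.

    Returns a frame indexed by year with columns ``n_articles``,
    ``mean_body`` and ``mean_supp``.  ``exclude_db`` removes the given
    databases from the counts (e.g. to view body trends with and without the
    dominant nucleotide-archive citations).
    """
    excluded = {Database.coerce(d) for d in (exclude_db or ())}
    per_year: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for doc, da in corpus:
        if doc.pub_year is None or not doc.mineable_files:
            continue
        n_body = sum(1 for a in da.body if a.db_id not in excluded)
        n_supp = sum(1 for a in da.supp_annotations if a.db_id not in excluded)
        per_year[doc.pub_year].append((n_body, n_supp))
    records = [
        {
            "year": year,
            "n_articles": len(counts),
            "mean_body": sum(b for b, _ in counts) / len(counts),
            "mean_supp": sum(s for _, s in counts) / len(counts),
        }
        for year, counts in sorted(per_year.items())
    ]
    return pd.DataFrame(
        records, columns=["year", "n_articles", "mean_body", "mean_supp"]
    ).set_index("year")


# ---------------------------------------------------------------------------
# Reports

def write_distribution_report(
    rows: Sequence[CitationStatsRow], path: str | Path
) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "db": r.db_id.value,
                "supp_count": r.supp_count,
                "body_count": r.body_count,
                "ratio": (
                    round_half_up(r.ratio, 2) if r.ratio is not None else ""
                ),
                "shared_count": r.shared_count,
                "shared_pct": (
                    round_half_up(r.shared_pct, 2)
                    if r.shared_pct is not None
                    else ""
                ),
            }
            for r in rows
        ],
        columns=["db", "supp_count", "body_count", "ratio",
                 "shared_count", "shared_pct"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame


def write_concentration_report(
    results: Sequence[ConcentrationResult], path: str | Path
) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "db": r.db_id.value,
                "n_articles": r.n_articles,
                "fraction": r.fraction,
                "n_top": r.n_top,
                "pct_in_top": round_half_up(r.pct_in_top, 2),
            }
            for r in results
        ],
        columns=["db", "n_articles", "fraction", "n_top", "pct_in_top"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame
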