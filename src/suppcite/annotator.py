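"""Cue-gated accession-mention annotation.

The pipeline has three stages: (1) :func:`find_candidates` scans text with
every database's patterns and keeps all word-boundary-delimited matches —
overlapping candidates from different databases may coexist at this stage;
(2) :func:`apply_context_filter` keeps a candidate only when one of its
database's cue words occurs nearby (window mode) or anywhere in the section
(section mode); (3) :func:`resolve_overlaps` makes the surviving spans
pairwise disjoint, preferring the candidate whose licensing cue is closest.

Text is treated as a flat character sequence; :func:`annotate_text`
whitespace-normalizes it (runs of whitespace collapse to a single space)
before matching, so annotation offsets index the normalized text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pattern_registry import (
    Database,
    DatabasePattern,
    get_registry,
    normalize_accession,
)

__all__ = [
    "AnnotatorConfig",
    "Candidate",
    "Annotation",
    "DocumentAnnotations",
    "ValidationStatus",
    "normalize_text",
    "find_candidates",
    "apply_context_filter",
    "resolve_overlaps",
    "annotate_text",
    "annotate_document",
    "annotations_to_frame",
    "write_annotations",
]

_WS = re.compile(r"\s+")

#: Fixed column order of the serialized annotation table.
ANNOTATION_COLUMNS = [
    "article_id",
    "section",
    "db",
    "accession",
    "normalized_accession",
    "start",
    "end",
    "cue",
    "cue_distance",
    "validation_status",
]


class ValidationStatus(str, Enum):
    UNVALIDATED = "unvalidated"
    VALID = "valid"
    INVALID = "invalid"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class AnnotatorConfig:
    """Cue-gating policy.

    ``cue_mode`` is ``"window"`` (cue must occur as a word within
    ``cue_window`` characters on either side of the candidate span) or
    ``"section"`` (cue anywhere in the same section suffices).  Cue matching
    is case-insensitive and word-bounded, and a cue inside the candidate span
    itself never licenses the match.
    """

    cue_mode: str = "window"
    cue_window: int = 300

    def __post_init__(self) -> None:
        if self.cue_mode not in ("window", "section"):
            raise ValueError(f"unknown cue mode: {self.cue_mode!r}")
        if self.cue_window <= 0:
            raise ValueError("cue_window must be positive")


@dataclass(frozen=True)
class Candidate:
    """A raw pattern match before overlap resolution.

    Offsets are 0-based half-open into the source text; ``surface`` equals
    ``text[start:end]``.  ``cue``/``cue_distance`` are filled by the context
    filter (distance counts the characters between cue and candidate spans).
    """

    db_id: Database
    surface: str
    start: int
    end: int
    pattern_index: int
    cue: str | None = None
    cue_distance: int | None = None

    def overlaps(self, other: "Candidate") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Annotation:
    """One accepted accession mention."""

    db_id: Database
    surface: str
    start: int
    end: int
    pattern_index: int
    normalized_accession: str
    cue: str | None
    cue_distance: int | None
    section: str
    validation_status: ValidationStatus = ValidationStatus.UNVALIDATED

    @property
    def pair(self) -> tuple[Database, str]:
        """The unique-citation key: (database, versionless accession)."""
        return (self.db_id, self.normalized_accession)


@dataclass
class DocumentAnnotations:
    """Per-section annotations for one article plus derived unique-pair sets."""

    article_id: str
    body: list[Annotation] = field(default_factory=list)
    supp: dict[str, list[Annotation]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def supp_annotations(self) -> list[Annotation]:
        return [a for anns in self.supp.values() for a in anns]

    @property
    def body_pairs(self) -> set[tuple[Database, str]]:
        return {a.pair for a in self.body}

    @property
    def supp_pairs(self) -> set[tuple[Database, str]]:
        return {a.pair for a in self.supp_annotations}

    @property
    def shared_pairs(self) -> set[tuple[Database, str]]:
        """Unique citations occurring in both body and supplementary data."""
        return self.body_pairs & self.supp_pairs

    def all_annotations(self) -> list[Annotation]:
        return self.body + self.supp_annotations


def normalize_text(text: str) -> str:
    """Collapse whitespace runs to single spaces (reproducible offsets
    across readers)."""
    return _WS.sub(" ", text).strip()


def _boundary_compile(pattern: str, flags: int) -> re.Pattern[str]:
    # A candidate must be delimited: neighbouring characters may not be
    # alphanumeric.  \b is wrong for patterns with internal hyphens.
    return re.compile(rf"(?<![A-Za-z0-9])(?:{pattern})(?![A-Za-z0-9])", flags)


def find_candidates(
    text: str, registry: Sequence[DatabasePattern] | None = None
) -> list[Candidate]:
    """All word-boundary-delimited pattern matches, sorted by (start, end).

    Within one database, a span matched by several of its patterns is
    reported once, with the lowest matching pattern index.  Across databases
    overlapping candidates are kept — disambiguation happens later.
    """
    if registry is None:
        registry = get_registry()
    found: dict[tuple[Database, int, int], Candidate] = {}
    for row in registry:
        for idx, pattern in enumerate(row.patterns):
            rx = _boundary_compile(pattern, row.flags)
            for m in rx.finditer(text):
                key = (row.db_id, m.start(), m.end())
                if key not in found:
                    found[key] = Candidate(
                        db_id=row.db_id,
                        surface=m.group(0),
                        start=m.start(),
                        end=m.end(),
                        pattern_index=idx,
                    )
    return sorted(found.values(), key=lambda c: (c.start, c.end, c.db_id.value))


def _cue_spans(text: str, cues: Sequence[str]) -> list[tuple[int, int, str]]:
    spans: list[tuple[int, int, str]] = []
    for cue in cues:
        rx = re.compile(
            rf"(?<![a-z0-9]){re.escape(cue)}(?![a-z0-9])", re.IGNORECASE
        )
        for m in rx.finditer(text):
            spans.append((m.start(), m.end(), cue))
    return spans


def apply_context_filter(
    candidates: Sequence[Candidate],
    text: str,
    registry: Sequence[DatabasePattern] | None = None,
    config: AnnotatorConfig | None = None,
) -> list[Candidate]:
    """Keep candidates licensed by a nearby contextual cue.

    A candidate survives iff its database does not require a cue, or one of
    its cue words occurs (outside the candidate span) within the configured
    window — or anywhere in the section when ``cue_mode="section"``.  The
    nearest licensing cue and its distance are recorded either way.
    """
    if registry is None:
        registry = get_registry()
    if config is None:
        config = AnnotatorConfig()
    by_db = {row.db_id: row for row in registry}
    cue_cache: dict[Database, list[tuple[int, int, str]]] = {}

    kept: list[Candidate] = []
    for cand in candidates:
        row = by_db[cand.db_id]
        if cand.db_id not in cue_cache:
            cue_cache[cand.db_id] = _cue_spans(text, row.cues)
        best: tuple[int, str] | None = None
        for cs, ce, cue in cue_cache[cand.db_id]:
            if cs >= cand.start and ce <= cand.end:
                continue  # cue inside the accession token does not self-license
            if ce <= cand.start:
                dist = cand.start - ce
            elif cs >= cand.end:
                dist = cs - cand.end
            else:
                continue  # partial overlap with the span: not an outside cue
            if best is None or dist < best[0]:
                best = (dist, cue)
        licensed = best is not None and (
            config.cue_mode == "section" or best[0] <= config.cue_window
        )
        if licensed:
            kept.append(replace(cand, cue=best[1], cue_distance=best[0]))
        elif not row.cue_required:
            kept.append(cand)
    return kept


def resolve_overlaps(
    candidates: Sequence[Candidate],
    registry: Sequence[DatabasePattern] | None = None,
) -> list[Candidate]:
    """Greedy disambiguation to pairwise non-overlapping spans.

    Preference among overlapping candidates: smallest cue distance (an
    unlicensed candidate ranks after any licensed one), then longest span,
    then highest registry priority.  Deterministic for fixed input.
    """
    if registry is None:
        registry = get_registry()
    prio = {row.db_id: row.priority for row in registry}

    def rank(c: Candidate) -> tuple:
        dist = c.cue_distance if c.cue_distance is not None else float("inf")
        return (dist, -(c.end - c.start), prio[c.db_id], c.start, c.db_id.value)

    accepted: list[Candidate] = []
    for cand in sorted(candidates, key=rank):
        if not any(cand.overlaps(a) for a in accepted):
            accepted.append(cand)
    return sorted(accepted, key=lambda c: (c.start, c.end))


def annotate_text(
    text: str,
    registry: Sequence[DatabasePattern] | None = None,
    config: AnnotatorConfig | None = None,
    section: str = "BODY",
) -> list[Annotation]:
    """Full pipeline over one section of text; returns annotations sorted by
    start offset (offsets index the whitespace-normalized text)."""
    if registry is None:
        registry = get_registry()
    norm = normalize_text(text)
    cands = find_candidates(norm, registry)
    cands = apply_context_filter(cands, norm, registry, config)
    cands = resolve_overlaps(cands, registry)
    return [
        Annotation(
            db_id=c.db_id,
            surface=c.surface,
            start=c.start,
            end=c.end,
            pattern_index=c.pattern_index,
            normalized_accession=normalize_accession(c.db_id, c.surface),
            cue=c.cue,
            cue_distance=c.cue_distance,
            section=section,
        )
        for c in cands
    ]


def annotate_document(
    doc,
    registry: Sequence[DatabasePattern] | None = None,
    config: AnnotatorConfig | None = None,
) -> DocumentAnnotations:
    """Annotate an article body and each mineable supplementary text
    independently.

    ``doc`` is a :class:`~suppcite.document_io.DocumentRecord` whose
    supplementary texts have already been extracted.  A manifest entry
    triaged mineable but lacking extracted text is skipped with a recorded
    warning rather than failing the run.
    """
    from .document_io import Triage  # local import to avoid a cycle

    result = DocumentAnnotations(article_id=doc.article_id)
    result.body = annotate_text(doc.body_text, registry, config, section="BODY")
    for supp in doc.supp_manifest:
        if supp.triage is not Triage.MINEABLE:
            continue
        if supp.text is None:
            result.warnings.append(
                f"{doc.article_id}: mineable file {supp.filename!r} has no "
                "extracted text; skipped"
            )
            continue
        result.supp[supp.filename] = annotate_text(
            supp.text, registry, config, section=f"SUPP:{supp.filename}"
        )
    return result


# ---------------------------------------------------------------------------
# Serialization

def annotations_to_frame(
    doc_annotations: Iterable[DocumentAnnotations] | DocumentAnnotations,
) -> pd.DataFrame:
    """Flatten annotations into a table with a fixed, diff-stable column
    order."""
    if isinstance(doc_annotations, DocumentAnnotations):
        doc_annotations = [doc_annotations]
    rows = []
    for da in doc_annotations:
        for ann in da.all_annotations():
            rows.append(
                {
                    "article_id": da.article_id,
                    "section": ann.section,
                    "db": ann.db_id.value,
                    "accession": ann.surface,
                    "normalized_accession": ann.normalized_accession,
                    "start": ann.start,
                    "end": ann.end,
                    "cue": ann.cue if ann.cue is not None else "",
                    "cue_distance": (
                        ann.cue_distance if ann.cue_distance is not None else ""
                    ),
                    "validation_status": ann.validation_status.value,
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(
    doc_annotations: Iterable[DocumentAnnotations] | DocumentAnnotations,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    frame = annotations_to_frame(doc_annotations)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(frame.to_dict(orient="records"), indent=1) + "\n"
        )
    return frame
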