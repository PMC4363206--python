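"""Extraction patterns and contextual cues for the ten supported databases.

Each biomolecular database is described by a small set of anchored regular
expressions over accession-number syntax plus a list of contextual cue words
(e.g. ``swissprot`` for UniProt, ``pdb`` for PDBe).  A raw pattern match alone
is weak evidence — short numeric or alphanumeric accessions collide with
ordinary prose tokens — so downstream annotation only accepts a match when a
cue word occurs nearby.  This module owns the pattern/cue registry and answers
whole-token syntactic-conformance queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import cached_property, lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Database",
    "DatabasePattern",
    "UnknownDatabaseError",
    "get_registry",
    "get_entry",
    "conforms",
    "normalize_accession",
    "load_registry",
    "save_registry",
]


class UnknownDatabaseError(KeyError):
    """Raised when a database identifier is not one of the ten known ones."""


class Database(str, Enum):
    """The ten databases covered by the annotator.

    ENA, ArrayExpress and PDBe are primary (submission) archives; the other
    seven are added-value resources derived from primary submissions.
    """

    ENA = "ENA"
    UNIPROT = "UniProt"
    PDBE = "PDBe"
    INTERPRO = "InterPro"
    PFAM = "Pfam"
    ARRAYEXPRESS = "ArrayExpress"
    OMIM = "OMIM"
    ENSEMBL = "Ensembl"
    REFSEQ = "RefSeq"
    REFSNP = "RefSNP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def coerce(cls, value: "Database | str") -> "Database":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            pass
        for member in cls:
            if member.value.lower() == str(value).lower():
                return member
        raise UnknownDatabaseError(f"unknown database: {value!r}")


@dataclass(frozen=True)
class DatabasePattern:
    """One database's accession patterns, cues and matching policy.

    Parameters
    ----------
    db_id
        Which database this entry describes.
    patterns
        Ordered anchored regular expressions over the accession language.
        They are applied whole-token (``fullmatch``) by :func:`conforms` and
        with word-boundary guards by the annotator.
    cues
        Lowercase cue words whose nearby occurrence licenses a match.
    cue_required
        Whether a match without a licensing cue is discarded.
    priority
        Rank used to break ties between overlapping matches from different
        databases (1 = most specific, wins last after cue distance and span
        length).
    case_insensitive
        Whether the patterns match regardless of letter case.  Accessions
        with distinctive alphabetic prefixes (``rs123456``, ``ensg…``) are
        commonly written in lowercase, while short generic patterns (ENA,
        UniProt, PDBe, OMIM) are kept strictly uppercase to limit false
        positives in prose.
    """

    db_id: Database
    patterns: tuple[str, ...]
    cues: tuple[str, ...]
    cue_required: bool = True
    priority: int = 99
    case_insensitive: bool = False

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"{self.db_id}: no patterns")
        if not self.cues:
            raise ValueError(f"{self.db_id}: cue list must be non-empty")
        for pat in self.patterns:
            re.compile(pat)

    @property
    def flags(self) -> int:
        return re.IGNORECASE if self.case_insensitive else 0

    @cached_property
    def compiled(self) -> tuple[re.Pattern[str], ...]:
        """Whole-token compiled forms of ``patterns``."""
        return tuple(re.compile(f"(?:{p})", self.flags) for p in self.patterns)

    def conforms(self, token: str) -> bool:
        return any(c.fullmatch(token) for c in self.compiled)


# The registry rows.  Character-class typography is normalised to ASCII
# regex syntax ("[A-Z, 0-9]" means the class A-Z plus 0-9).  Priority runs
# most-specific first; OMIM (six bare digits) and PDBe (one digit + three
# alphanumerics) are the most collision-prone and rank last.
_DEFAULT_ROWS: tuple[DatabasePattern, ...] = (
    DatabasePattern(
        Database.ENSEMBL,
        patterns=("ENS[A-Z]*G[0-9]{11}",),
        cues=("ensembl",),
        priority=1,
        case_insensitive=True,
    ),
    DatabasePattern(
        Database.ARRAYEXPRESS,
        patterns=("E-[A-Z]{4}-[0-9]+",),
        cues=("arrayexpress",),
        priority=2,
        case_insensitive=True,
    ),
    DatabasePattern(
        Database.INTERPRO,
        patterns=("IPR[0-9]{6}",),
        cues=("interpro",),
        priority=3,
        case_insensitive=True,
    ),
    DatabasePattern(
        Database.PFAM,
        patterns=("PF(AM)?[0-9]{5}",),
        cues=("hmm", "family", "pfam"),
        priority=4,
        case_insensitive=True,
    ),
    DatabasePattern(
        Database.REFSEQ,
        patterns=(
            "(AC|AP|NC|NG|NM|NP|NR|NT|NW|NZ|XM|XP|XR|YP|ZP|NS)"
            "_([A-Z]{4})*[0-9]{6,9}(?:[.][0-9]+)?",
        ),
        cues=("refseq",),
        priority=5,
        case_insensitive=True,
    ),
    DatabasePattern(
        Database.REFSNP,
        patterns=("RS[0-9]{5,9}",),
        cues=("snp",),
        priority=6,
        case_insensitive=True,
    ),
    DatabasePattern(
        Database.UNIPROT,
        patterns=(
            "[A-NR-Z][0-9][A-Z][A-Z0-9][A-Z0-9][0-9]",
            "[OPQ][0-9][A-Z0-9][A-Z0-9][A-Z0-9][0-9]",
        ),
        cues=("swissprot", "sprot", "uniprot"),
        priority=7,
    ),
    DatabasePattern(
        Database.ENA,
        patterns=(
            "[A-Z][0-9]{5}",
            "[A-Z]{2}[0-9]{6}",
            "[A-Z]{3}[0-9]{5}",
            "[A-Z]{4}[0-9]{8,10}",
            "[A-Z]{5}[0-9]{7}",
        ),
        cues=("genbank", "gen", "ddbj", "embl"),
        priority=8,
    ),
    DatabasePattern(
        Database.OMIM,
        patterns=("[0-9]{6}",),
        cues=("omim",),
        priority=9,
    ),
    DatabasePattern(
        Database.PDBE,
        patterns=("[0-9][A-Z0-9]{3}",),
        cues=("pdb",),
        priority=10,
    ),
)

_REFSEQ_VERSION = re.compile(r"[.][0-9]+$")


@lru_cache(maxsize=1)
def _default_registry() -> tuple[DatabasePattern, ...]:
    return tuple(sorted(_DEFAULT_ROWS, key=lambda r: r.priority))


def get_registry(
    db_subset: Iterable[Database | str] | None = None,
) -> list[DatabasePattern]:
    """Return the registry, optionally filtered, in priority order.

    Raises :class:`UnknownDatabaseError` for an unrecognised identifier in
    ``db_subset``.
    """
    registry = list(_default_registry())
    if db_subset is None:
        return registry
    wanted = {Database.coerce(d) for d in db_subset}
    return [row for row in registry if row.db_id in wanted]


def get_entry(
    db_id: Database | str, registry: Sequence[DatabasePattern] | None = None
) -> DatabasePattern:
    """Look up a single database's registry row."""
    db = Database.coerce(db_id)
    for row in registry if registry is not None else _default_registry():
        if row.db_id == db:
            return row
    raise UnknownDatabaseError(f"database not in registry: {db.value}")


def conforms(
    db_id: Database | str,
    token: str,
    registry: Sequence[DatabasePattern] | None = None,
) -> bool:
    """True iff the entire ``token`` matches one of ``db_id``'s patterns.

    The token is treated as a complete candidate string; no surrounding
    context is considered and no cue gating is applied.
    """
    return get_entry(db_id, registry).conforms(token)


def normalize_accession(db_id: Database | str, surface: str) -> str:
    """Canonical form of a matched accession: uppercase, and for RefSeq with
    the ``.N`` version suffix stripped (databases key on the versionless
    accession)."""
    db = Database.coerce(db_id)
    norm = surface.upper()
    if db is Database.REFSEQ:
        norm = _REFSEQ_VERSION.sub("", norm)
    return norm


# ---------------------------------------------------------------------------
# Config-file round trip: one record per database so users can amend cues
# without code changes.

def save_registry(registry: Sequence[DatabasePattern], path: str | Path) -> None:
    records = [
        {
            "db": row.db_id.value,
            "patterns": list(row.patterns),
            "cues": list(row.cues),
            "cue_required": row.cue_required,
            "priority": row.priority,
            "case_insensitive": row.case_insensitive,
        }
        for row in registry
    ]
    Path(path).write_text(yaml.safe_dump(records, sort_keys=False))


def load_registry(path: str | Path) -> list[DatabasePattern]:
    records = yaml.safe_load(Path(path).read_text())
    rows = [
        DatabasePattern(
            db_id=Database.coerce(rec["db"]),
            patterns=tuple(rec["patterns"]),
            cues=tuple(rec["cues"]),
            cue_required=bool(rec.get("cue_required", True)),
            priority=int(rec.get("priority", 99)),
            case_insensitive=bool(rec.get("case_insensitive", False)),
        )
        for rec in records
    ]
    seen = [r.db_id for r in rows]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate database entries in registry file")
    return sorted(rows, key=lambda r: r.priority)
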