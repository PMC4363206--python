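"""Post-hoc validation of annotated accessions.

Validation checks whether an annotated accession actually designates a
record in its database, beyond being syntactically well-formed.  The
contract is pluggable: a validator maps ``(database, normalized accession)``
to ``valid`` / ``invalid`` / ``unknown``.  Two backends are built in — a
syntactic pass-through and a table-backed lookup against user-supplied
accession lists — so runs never depend on a live web service.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .annotator import Annotation, ValidationStatus
from .pattern_registry import Database, conforms

__all__ = [
    "AccessionValidator",
    "PassthroughValidator",
    "TableValidator",
    "validate_annotations",
]

log = logging.getLogger(__name__)


class AccessionValidator(Protocol):
    """Deterministic verdict on one accession; never raises on well-formed
    input."""

    def validate(self, db_id: Database, accession: str) -> str:
        """Return ``"valid"``, ``"invalid"`` or ``"unknown"``."""
        ...


class PassthroughValidator:
    """Syntactic-only validation: every pattern-conformant accession is
    valid."""

    def validate(self, db_id: Database, accession: str) -> str:
        return "valid" if conforms(db_id, accession) else "invalid"


class TableValidator:
    """Lookup against per-database accession lists.

    An accession is valid iff listed for its database; absent from a present
    table means invalid; a database with no backing table yields unknown.
    """

    def __init__(self, tables: Mapping[Database | str, Iterable[str]]):
        self._tables: dict[Database, frozenset[str]] = {
            Database.coerce(db): frozenset(a.upper() for a in accs)
            for db, accs in tables.items()
        }

    @classmethod
    def from_dir(cls, directory: str | Path) -> "TableValidator":
        """Load one two-column (db, accession) TSV per database from a
        directory of ``*.tsv`` files."""
        tables: dict[Database, set[str]] = {}
        for path in sorted(Path(directory).glob("*.tsv")):
            for line in path.read_text().splitlines():
                line = line.strip()
                if not line or line.lower().startswith("db\t"):
                    continue
                db_name, _, acc = line.partition("\t")
                if not acc:
                    continue
                db = Database.coerce(db_name.strip())
                tables.setdefault(db, set()).add(acc.strip().upper())
        return cls(tables)

    def validate(self, db_id: Database, accession: str) -> str:
        table = self._tables.get(Database.coerce(db_id))
        if table is None:
            return "unknown"
        return "valid" if accession.upper() in table else "invalid"


_VERDICTS = {
    "valid": ValidationStatus.VALID,
    "invalid": ValidationStatus.INVALID,
    "unknown": ValidationStatus.UNVALIDATED,
}


def validate_annotations(
    annotations: Sequence[Annotation],
    validator: AccessionValidator,
    drop_invalid: bool = True,
) -> list[Annotation]:
    """Set each annotation's validation status per the validator's verdict.

    ``unknown`` maps to unvalidated.  With ``drop_invalid`` (the default),
    annotations judged invalid are removed from downstream counting.  A
    failing validator backend downgrades every annotation to unvalidated
    with a logged warning; validation never fails the run.
    """
    out: list[Annotation] = []
    for ann in annotations:
        try:
            verdict = validator.validate(ann.db_id, ann.normalized_accession)
            status = _VERDICTS.get(verdict, ValidationStatus.UNVALIDATED)
        except Exception as exc:
            log.warning("validator backend failed (%s); leaving unvalidated", exc)
            status = ValidationStatus.UNVALIDATED
        if status is ValidationStatus.INVALID and drop_invalid:
            continue
        out.append(replace(ann, validation_status=status))
    return out
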