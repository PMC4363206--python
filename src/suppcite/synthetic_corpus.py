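"""Ground-truthed synthetic corpus generation.

Emits a small article corpus in the same JATS-style XML + sibling
supplementary-directory layout that :mod:`suppcite.document_io` reads, with
every planted accession mention recorded in a ground-truth table.  The
generator exercises exactly the mechanisms the annotator relies on:

* planted accessions are sampled uniformly from each database's pattern
  language and embedded in template prose, with a licensing cue word placed
  immediately before the accession with probability ``cue_prob``;
* mentions without a cue, and decoy tokens (pattern-conformant strings that
  are not database citations), are emitted in cue-free blocks separated from
  any cued text by more than ``cue_window`` characters of filler, so a
  window-mode annotator can never license them;
* the supplementary manifest mixes mineable text formats with media and
  source-code decoy files per a configurable format mix;
* per-article mention counts are Poisson with the configured per-database
  means, with an optional heavy-tail switch that turns every k-th article
  into a "data dump" holding many times the typical supplementary count.

Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pattern_registry import (
    Database,
    DatabasePattern,
    get_entry,
    get_registry,
    normalize_accession,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "sample_accession",
    "generate_corpus",
    "strip_cues",
]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_ALNUM = _LETTERS + "0123456789"
_UNIPROT_FIRST_1 = "ABCDEFGHIJKLMNRSTUVWXYZ"  # [A-N,R-Z]
_UNIPROT_FIRST_2 = "OPQ"
_REFSEQ_PREFIXES = (
    "AC", "AP", "NC", "NG", "NM", "NP", "NR", "NT",
    "NW", "NZ", "XM", "XP", "XR", "YP", "ZP", "NS",
)
_ENSEMBL_SPECIES = ("", "MUS", "RNO", "DAR", "GAL")

# Filler prose: lowercase, digit-free, and free of every cue word, so it can
# never produce a pattern match or license one.
_FILLER = (
    "the measured expression profile remained stable across replicates "
    "and conditions throughout the described experimental protocol. "
)

_GT_COLUMNS = [
    "article_id", "section", "db", "accession", "normalized_accession",
    "has_cue",
]


def _digits(rng: np.random.Generator, n: int) -> str:
    return "".join(str(d) for d in rng.integers(0, 10, size=int(n)))


def _pick(rng: np.random.Generator, alphabet: str, n: int = 1) -> str:
    idx = rng.integers(0, len(alphabet), size=int(n))
    return "".join(alphabet[i] for i in idx)


def sample_accession(db_id: Database | str, rng: np.random.Generator) -> str:
    """Sample a string uniformly-ish from the database's pattern language.

    The returned token always satisfies ``conforms(db_id, token)``.
    """
    db = Database.coerce(db_id)
    if db is Database.ENA:
        shape = int(rng.integers(0, 5))
        if shape == 0:
            return _pick(rng, _LETTERS) + _digits(rng, 5)
        if shape == 1:
            return _pick(rng, _LETTERS, 2) + _digits(rng, 6)
        if shape == 2:
            return _pick(rng, _LETTERS, 3) + _digits(rng, 5)
        if shape == 3:
            return _pick(rng, _LETTERS, 4) + _digits(rng, int(rng.integers(8, 11)))
        return _pick(rng, _LETTERS, 5) + _digits(rng, 7)
    if db is Database.UNIPROT:
        if rng.random() < 0.5:
            return (
                _pick(rng, _UNIPROT_FIRST_1) + _digits(rng, 1)
                + _pick(rng, _LETTERS) + _pick(rng, _ALNUM, 2) + _digits(rng, 1)
            )
        return (
            _pick(rng, _UNIPROT_FIRST_2) + _digits(rng, 1)
            + _pick(rng, _ALNUM, 3) + _digits(rng, 1)
        )
    if db is Database.PDBE:
        return _digits(rng, 1) + _pick(rng, _ALNUM, 3)
    if db is Database.INTERPRO:
        return "IPR" + _digits(rng, 6)
    if db is Database.PFAM:
        stem = "PFAM" if rng.random() < 0.1 else "PF"
        return stem + _digits(rng, 5)
    if db is Database.ARRAYEXPRESS:
        return "E-" + _pick(rng, _LETTERS, 4) + "-" + _digits(rng, int(rng.integers(1, 6)))
    if db is Database.OMIM:
        return str(rng.integers(1, 7)) + _digits(rng, 5)
    if db is Database.ENSEMBL:
        species = _ENSEMBL_SPECIES[int(rng.integers(0, len(_ENSEMBL_SPECIES)))]
        return "ENS" + species + "G" + _digits(rng, 11)
    if db is Database.REFSEQ:
        prefix = _REFSEQ_PREFIXES[int(rng.integers(0, len(_REFSEQ_PREFIXES)))]
        acc = prefix + "_" + _digits(rng, int(rng.integers(6, 10)))
        if rng.random() < 0.3:
            acc += "." + str(rng.integers(1, 10))
        return acc
    if db is Database.REFSNP:
        return "RS" + _digits(rng, int(rng.integers(5, 10)))
    raise AssertionError(f"unhandled database {db}")  # pragma: no cover


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    ``body_rate`` and ``supp_rate`` are expected mentions per article per
    database (Poisson means; a mapping gives per-database control).  The
    format mix gives the type fractions for the extra supplementary files
    drawn per article (every article also carries one guaranteed plain-text
    supplementary file so supplementary mentions always have a mineable
    home); ``media`` and ``source`` entries produce non-mineable decoy files.
    """

    n_articles: int = 50
    year_range: tuple[int, int] = (1990, 2014)
    body_rate: float | Mapping[Database | str, float] = 0.3
    supp_rate: float | Mapping[Database | str, float] = 1.5
    cue_prob: float = 0.9
    decoy_rate: float = 0.5
    shared_prob: float = 0.1
    format_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "txt": 0.35, "tsv": 0.25, "html": 0.15, "media": 0.15, "source": 0.10,
        }
    )
    extra_files_per_article: int = 2
    cue_window: int = 300
    heavy_tail: bool = False
    dump_every: int = 20
    dump_factor: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 0:
            raise ValueError("n_articles must be non-negative")
        for name in ("cue_prob", "shared_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("decoy_rate",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for db in get_registry():
            if self._rate(self.body_rate, db.db_id) < 0 or self._rate(
                self.supp_rate, db.db_id
            ) < 0:
                raise ValueError("rates must be non-negative")
        total = sum(self.format_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("format mix fractions must sum to 1")
        unknown = set(self.format_mix) - {"txt", "tsv", "html", "media", "source"}
        if unknown:
            raise ValueError(f"unknown format mix keys: {unknown}")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("empty year range")

    @staticmethod
    def _rate(rate, db: Database) -> float:
        if isinstance(rate, Mapping):
            lookup = {Database.coerce(k): v for k, v in rate.items()}
            return float(lookup.get(db, 0.0))
        return float(rate)

    def body_rate_for(self, db: Database) -> float:
        return self._rate(self.body_rate, db)

    def supp_rate_for(self, db: Database) -> float:
        return self._rate(self.supp_rate, db)


@dataclass
class GroundTruth:
    """Planted mentions (and decoys) with their section locators.

    ``mentions`` has one row per planted citation mention with columns
    article_id, section, db, accession (surface form), normalized_accession
    and has_cue; ``decoys`` records planted pattern-conformant non-citations.
    """

    mentions: pd.DataFrame
    decoys: pd.DataFrame

    def unique_pairs_by_article(
        self, cued_only: bool = True
    ) -> dict[str, set[tuple[Database, str]]]:
        frame = self.mentions
        if cued_only and len(frame):
            frame = frame[frame["has_cue"]]
        out: dict[str, set[tuple[Database, str]]] = {}
        for row in frame.itertuples(index=False):
            out.setdefault(row.article_id, set()).add(
                (Database.coerce(row.db), row.normalized_accession)
            )
        return out

    def mention_keys(self, cued_only: bool = True) -> set[tuple]:
        """Set of (article_id, section, db, normalized_accession) keys."""
        frame = self.mentions
        if cued_only and len(frame):
            frame = frame[frame["has_cue"]]
        return {
            (r.article_id, r.section, r.db, r.normalized_accession)
            for r in frame.itertuples(index=False)
        }

    def to_tsv(self, path: str | Path) -> None:
        self.mentions.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Text assembly

@dataclass
class _Mention:
    db: Database
    accession: str
    has_cue: bool
    cue: str | None


def _sentence_cued(cue: str, acc: str) -> str:
    return f"the {cue} entry {acc} was examined in detail."

def _sentence_uncued(acc: str) -> str:
    return f"identifier {acc} was listed among the outputs."

def _sentence_decoy(acc: str) -> str:
    return f"token {acc} appears here without supporting context."


def _pad(width: int) -> str:
    reps = math.ceil((width + 50) / len(_FILLER)) + 1
    return _FILLER * reps


def _assemble_prose(
    mentions: Sequence[_Mention], decoys: Sequence[str], window: int
) -> str:
    """Cued sentences first, then a cue-free block (uncued mentions and
    decoys) separated by more than ``window`` characters of neutral filler."""
    cued = [_sentence_cued(m.cue, m.accession) for m in mentions if m.has_cue]
    free = [_sentence_uncued(m.accession) for m in mentions if not m.has_cue]
    free += [_sentence_decoy(a) for a in decoys]
    parts = [_FILLER] + cued
    if free:
        parts.append(_pad(window))
        parts += free
    parts.append(_FILLER)
    return " ".join(parts)


def _supp_content(
    fmt: str, mentions: Sequence[_Mention], decoys: Sequence[str], window: int
) -> str:
    if fmt == "tsv":
        cued = [f"{m.cue}\t{m.accession}" for m in mentions if m.has_cue]
        free = [f"listed\t{m.accession}" for m in mentions if not m.has_cue]
        free += [f"listed\t{a}" for a in decoys]
        pad_rows = [_FILLER.strip().replace(" ", "\t")] * (
            math.ceil((window + 50) / len(_FILLER)) + 1
        )
        lines = ["label\tvalue"] + cued + (pad_rows + free if free else [])
        return "\n".join(lines) + "\n"
    prose = _assemble_prose(mentions, decoys, window)
    if fmt == "html":
        return (
            "<html><head><title>supplementary table</title></head>"
            f"<body><p>{prose}</p></body></html>\n"
        )
    return prose + "\n"


_FORMAT_INFO = {
    "txt": (".txt", "text", "plain"),
    "tsv": (".tsv", "text", "tab-separated-values"),
    "html": (".html", "text", "html"),
    "media": (".png", "image", "png"),
    "source": (".py", "text", "plain"),
}

_MEDIA_BYTES = b"\x89PNG\r\n\x1a\n not a real image payload"
_SOURCE_TEXT = "def main():\n    return 0\n"


# ---------------------------------------------------------------------------
# Corpus generation

def generate_corpus(
    config: SynthConfig, out_dir: str | Path
) -> GroundTruth:
    """Write the corpus under ``out_dir`` and return the ground truth.

    Layout: ``<article_id>.xml`` plus supplementary files in
    ``<article_id>_files/``; the ground truth is also written to
    ``ground_truth.tsv``.  Byte-identical output for a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    registry = get_registry()
    dbs = [row.db_id for row in registry]

    gt_rows: list[dict] = []
    decoy_rows: list[dict] = []

    for i in range(config.n_articles):
        article_id = f"PMC{i + 1:07d}"
        year = int(
            rng.integers(config.year_range[0], config.year_range[1] + 1)
        )
        dump = (
            config.heavy_tail
            and config.dump_every > 0
            and (i + 1) % config.dump_every == 0
        )

        def plant(db: Database, n: int) -> list[_Mention]:
            out = []
            for _ in range(n):
                acc = sample_accession(db, rng)
                has_cue = bool(rng.random() < config.cue_prob)
                cues = get_entry(db, registry).cues
                cue = cues[int(rng.integers(0, len(cues)))] if has_cue else None
                out.append(_Mention(db, acc, has_cue, cue))
            return out

        body_mentions: list[_Mention] = []
        supp_mentions: list[_Mention] = []
        for db in dbs:
            body_mentions += plant(db, int(rng.poisson(config.body_rate_for(db))))
            n_supp = int(rng.poisson(config.supp_rate_for(db)))
            if dump:
                n_supp *= config.dump_factor
            supp_mentions += plant(db, n_supp)

        # A body citation is repeated in the supplementary data with
        # probability shared_prob (only cued copies, so a window-mode
        # annotator can recover the shared pair).
        for m in body_mentions:
            if m.has_cue and rng.random() < config.shared_prob:
                cues = get_entry(m.db, registry).cues
                supp_mentions.append(
                    _Mention(m.db, m.accession, True,
                             cues[int(rng.integers(0, len(cues)))])
                )

        n_decoys = int(rng.poisson(config.decoy_rate))
        body_decoys = [
            sample_accession(dbs[int(rng.integers(0, len(dbs)))], rng)
            for _ in range(n_decoys)
        ]

        # Supplementary file plan: one guaranteed txt file plus extras from
        # the format mix.
        fmt_names = sorted(config.format_mix)
        probs = np.array([config.format_mix[f] for f in fmt_names])
        extra = [
            fmt_names[int(k)]
            for k in rng.choice(len(fmt_names), size=config.extra_files_per_article,
                                p=probs / probs.sum())
        ]
        file_plan = ["txt"] + extra

        mineable_slots = [
            j for j, f in enumerate(file_plan) if f in ("txt", "tsv", "html")
        ]
        per_file: dict[int, list[_Mention]] = {j: [] for j in mineable_slots}
        for m in supp_mentions:
            slot = mineable_slots[int(rng.integers(0, len(mineable_slots)))]
            per_file[slot].append(m)

        supp_dir = out_dir / f"{article_id}_files"
        supp_dir.mkdir(exist_ok=True)
        manifest_xml: list[str] = []
        for j, fmt in enumerate(file_plan):
            ext, mime, sub = _FORMAT_INFO[fmt]
            fname = f"{article_id}_s{j + 1}{ext}"
            path = supp_dir / fname
            if fmt == "media":
                path.write_bytes(_MEDIA_BYTES)
            elif fmt == "source":
                # a decoy accession inside source code: triage must screen it
                path.write_text(
                    _SOURCE_TEXT + f"ACCESSION = '{sample_accession(dbs[0], rng)}'\n"
                )
            else:
                path.write_text(
                    _supp_content(fmt, per_file[j], [], config.cue_window)
                )
                for m in per_file[j]:
                    gt_rows.append(
                        {
                            "article_id": article_id,
                            "section": f"SUPP:{fname}",
                            "db": m.db.value,
                            "accession": m.accession,
                            "normalized_accession": normalize_accession(
                                m.db, m.accession
                            ),
                            "has_cue": m.has_cue,
                        }
                    )
            manifest_xml.append(
                f'      <supplementary-material mimetype="{mime}" '
                f'mime-subtype="{sub}" xlink:href="{fname}"/>'
            )

        body_prose = _assemble_prose(body_mentions, body_decoys, config.cue_window)
        for m in body_mentions:
            gt_rows.append(
                {
                    "article_id": article_id,
                    "section": "BODY",
                    "db": m.db.value,
                    "accession": m.accession,
                    "normalized_accession": normalize_accession(m.db, m.accession),
                    "has_cue": m.has_cue,
                }
            )
        for acc in body_decoys:
            decoy_rows.append({"article_id": article_id, "accession": acc})

        xml = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            '<article xmlns:xlink="http://www.w3.org/1999/xlink">\n'
            "  <front>\n    <article-meta>\n"
            f'      <article-id pub-id-type="pmcid">{article_id}</article-id>\n'
            f"      <pub-date><year>{year}</year></pub-date>\n"
            "    </article-meta>\n  </front>\n"
            "  <body>\n"
            f"    <sec><p>{body_prose}</p></sec>\n"
            "    <sec>\n" + "\n".join(manifest_xml) + "\n    </sec>\n"
            "  </body>\n"
            "</article>\n"
        )
        (out_dir / f"{article_id}.xml").write_text(xml)

    mentions = pd.DataFrame(gt_rows, columns=_GT_COLUMNS)
    decoys = pd.DataFrame(decoy_rows, columns=["article_id", "accession"])
    truth = GroundTruth(mentions=mentions, decoys=decoys)
    truth.to_tsv(out_dir / "ground_truth.tsv")
    return truth


def strip_cues(
    text: str, registry: Sequence[DatabasePattern] | None = None
) -> str:
    """Replace every cue-word occurrence with a neutral token (cue-ablation
    helper for testing that cue gating is what licenses annotations)."""
    if registry is None:
        registry = get_registry()
    out = text
    for row in registry:
        for cue in row.cues:
            out = re.sub(
                rf"(?<![a-z0-9]){re.escape(cue)}(?![a-z0-9])",
                "item",
                out,
                flags=re.IGNORECASE,
            )
    return out
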