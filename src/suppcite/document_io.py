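"""Reading article XML, supplementary-file triage and text extraction.

Articles arrive as JATS-style XML: the narrative lives under ``<body>`` and
supplementary files are declared as ``<supplementary-material>`` links with
MIME type/subtype attributes.  Supplementary files go through a three-step
triage before mining: (1) media files (image/audio/video MIME classes) are
screened out as not text-convertible, (2) files with known source-code
extensions are screened out as unlikely to contain accession numbers, and
(3) the remaining text-convertible files have their text extracted.  Built-in
extractors cover TXT/CSV/TSV/XML/HTML (and XLSX via openpyxl); other formats
(PDF, DOC, XLS, ...) route through a pluggable adapter registry, and an
extraction failure marks the file rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd
from lxml import etree, html as lxml_html

__all__ = [
    "Triage",
    "SuppFile",
    "DocumentRecord",
    "IOConfig",
    "parse_article_xml",
    "triage_supplementary",
    "extract_text",
    "load_document",
    "read_corpus",
    "write_triage_report",
]

log = logging.getLogger(__name__)

XLINK = "{http://www.w3.org/1999/xlink}href"


class Triage(str, Enum):
    MINEABLE = "mineable"
    EXCLUDED_MEDIA = "excluded_media"
    EXCLUDED_SOURCE_CODE = "excluded_source_code"
    EXCLUDED_UNCONVERTIBLE = "excluded_unconvertible"
    EXTRACTION_FAILED = "extraction_failed"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class SuppFile:
    """One supplementary-file manifest entry."""

    filename: str
    mime_type: str = ""
    mime_subtype: str = ""
    triage: Triage | None = None
    reason: str = ""
    text: str | None = None

    @property
    def extension(self) -> str:
        return Path(self.filename).suffix.lower()


@dataclass
class DocumentRecord:
    """One article: identifier, publication year, body text and
    supplementary-file manifest."""

    article_id: str
    pub_year: int | None
    body_text: str
    supp_manifest: list[SuppFile] = field(default_factory=list)

    @property
    def mineable_files(self) -> list[SuppFile]:
        return [f for f in self.supp_manifest if f.triage is Triage.MINEABLE]


@dataclass(frozen=True)
class IOConfig:
    """Triage policy knobs.

    ``source_code_extensions`` implements the screen for text files unlikely
    to contain accession numbers; ``text_convertible_extensions`` is the set
    of formats considered convertible to text.  MIME is trusted over the
    extension when both are present and conflict, since triage is defined on
    the MIME declared in the file link; the extension is the fallback.
    """

    source_code_extensions: frozenset[str] = frozenset(
        {".c", ".cpp", ".h", ".py", ".pl", ".java", ".r", ".m", ".sh", ".js"}
    )
    text_convertible_extensions: frozenset[str] = frozenset(
        {
            ".txt", ".text", ".csv", ".tsv", ".tab", ".xml", ".html", ".htm",
            ".pdf", ".doc", ".docx", ".xls", ".xlsx", ".rtf",
        }
    )
    min_year: int = 1990  # corpus-era filter: pre-1990 articles are dropped


_MEDIA_CLASSES = {"image", "audio", "video"}
_TEXT_MIME_CLASSES = {"text"}
_TEXT_MIME_SUBTYPES = {
    "plain", "csv", "tab-separated-values", "xml", "html", "pdf", "msword",
    "vnd.ms-excel", "rtf",
    "vnd.openxmlformats-officedocument.spreadsheetml.sheet",
    "vnd.openxmlformats-officedocument.wordprocessingml.document",
}


# ---------------------------------------------------------------------------
# XML parsing

def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def parse_article_xml(source: str | Path | bytes) -> DocumentRecord:
    """Parse a JATS-style article into a :class:`DocumentRecord`.

    ``body_text`` concatenates the character data of the article body
    (figure and table text included); reference lists are excluded, since
    bibliographies are dense in identifier-like tokens that are not database
    citations.  The manifest gets one entry per ``<supplementary-material>``
    link, with MIME type/subtype read from the link attributes.
    """
    parser = etree.XMLParser(remove_comments=True)
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source, parser)
            name = "<bytes>"
        else:
            root = etree.parse(str(source), parser).getroot()
            name = str(source)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed article XML in {source!r}: {exc}") from exc

    article_id = ""
    for el in root.iter():
        if _local(el.tag) == "article-id" and el.get("pub-id-type") in (
            "pmcid", "pmc", "accession", None,
        ):
            article_id = (el.text or "").strip()
            if article_id:
                break
    if not article_id:
        article_id = Path(name).stem if name != "<bytes>" else "unknown"

    pub_year: int | None = None
    for el in root.iter():
        if _local(el.tag) == "pub-date":
            for child in el.iter():
                if _local(child.tag) == "year" and (child.text or "").strip():
                    try:
                        pub_year = int(child.text.strip())
                    except ValueError:
                        pass
                    break
        if pub_year is not None:
            break

    body = None
    for el in root.iter():
        if _local(el.tag) == "body":
            body = el
            break
    if body is None:
        log.warning("%s: article has no <body>; body_text empty", article_id)
        body_text = ""
    else:
        chunks: list[str] = []

        def walk(el) -> None:
            if _local(el.tag) == "ref-list":
                return
            if el.text:
                chunks.append(el.text)
            for child in el:
                walk(child)
                if child.tail:
                    chunks.append(child.tail)

        walk(body)
        body_text = " ".join(chunks)

    manifest: list[SuppFile] = []
    for el in root.iter():
        if _local(el.tag) != "supplementary-material":
            continue
        href = el.get(XLINK)
        mime = el.get("mimetype", "")
        sub = el.get("mime-subtype", "")
        if href is None or not mime:
            for child in el.iter():
                if _local(child.tag) in ("media", "graphic"):
                    href = href or child.get(XLINK)
                    mime = mime or child.get("mimetype", "")
                    sub = sub or child.get("mime-subtype", "")
        if href:
            manifest.append(
                SuppFile(filename=href, mime_type=mime, mime_subtype=sub)
            )

    return DocumentRecord(
        article_id=article_id,
        pub_year=pub_year,
        body_text=body_text,
        supp_manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Triage

def triage_supplementary(
    manifest: Sequence[SuppFile], config: IOConfig | None = None
) -> list[SuppFile]:
    """Label every manifest entry with exactly one triage decision.

    Idempotent; re-running on already-triaged entries reproduces the labels
    (entries already marked ``extraction_failed`` keep that mark).
    """
    if config is None:
        config = IOConfig()
    out: list[SuppFile] = []
    for supp in manifest:
        if supp.triage is Triage.EXTRACTION_FAILED:
            out.append(supp)
            continue
        mime_class = supp.mime_type.strip().lower()
        ext = supp.extension
        if mime_class in _MEDIA_CLASSES:
            label, reason = Triage.EXCLUDED_MEDIA, f"media mime type {mime_class!r}"
        elif ext in config.source_code_extensions:
            label, reason = (
                Triage.EXCLUDED_SOURCE_CODE,
                f"source code extension {ext!r}",
            )
        elif (
            mime_class in _TEXT_MIME_CLASSES
            or supp.mime_subtype.strip().lower() in _TEXT_MIME_SUBTYPES
            or ext in config.text_convertible_extensions
        ):
            label, reason = Triage.MINEABLE, "text convertible"
        else:
            label, reason = Triage.EXCLUDED_UNCONVERTIBLE, "unconvertible"
        out.append(replace(supp, triage=label, reason=reason))
    return out


# ---------------------------------------------------------------------------
# Text extraction

def _decode(data: bytes) -> str:
    for enc in ("utf-8-sig", "utf-8"):
        try:
            return data.decode(enc)
        except UnicodeDecodeError:
            continue
    return data.decode("latin-1")  # last-resort single-byte fallback


def _extract_plain(data: bytes) -> str:
    return _decode(data)


def _extract_html(data: bytes) -> str:
    doc = lxml_html.fromstring(data)
    return doc.text_content()


def _extract_xml(data: bytes) -> str:
    parser = etree.XMLParser(recover=True)
    root = etree.fromstring(data, parser)
    if root is None:
        raise ValueError("unparseable XML")
    return " ".join(t for t in root.itertext())


def _extract_xlsx(data: bytes) -> str:
    import io

    import openpyxl

    wb = openpyxl.load_workbook(io.BytesIO(data), read_only=True, data_only=True)
    cells: list[str] = []
    for ws in wb.worksheets:
        for row in ws.iter_rows(values_only=True):
            cells.extend(str(v) for v in row if v is not None)
    return " ".join(cells)


#: Built-in extractors keyed by lowercase file extension.
BUILTIN_ADAPTERS: dict[str, Callable[[bytes], str]] = {
    ".txt": _extract_plain,
    ".text": _extract_plain,
    ".csv": _extract_plain,
    ".tsv": _extract_plain,
    ".tab": _extract_plain,
    ".html": _extract_html,
    ".htm": _extract_html,
    ".xml": _extract_xml,
    ".xlsx": _extract_xlsx,
}


def extract_text(
    supp: SuppFile,
    data: bytes,
    adapters: Mapping[str, Callable[[bytes], str]] | None = None,
) -> SuppFile:
    """Extract character data from a mineable file's bytes.

    Adapters registered by the caller take precedence over the built-ins, so
    external PDF/DOC/XLS converters can be plugged in.  Any failure — no
    adapter for the format, or the adapter raising — returns the entry marked
    ``extraction_failed`` instead of propagating.
    """
    if supp.triage is not Triage.MINEABLE:
        raise ValueError(
            f"extract_text requires a mineable entry, got {supp.triage}"
        )
    table = dict(BUILTIN_ADAPTERS)
    if adapters:
        table.update(adapters)
    adapter = table.get(supp.extension)
    if adapter is None and supp.mime_type.strip().lower() == "text":
        adapter = _extract_plain
    if adapter is None:
        return replace(
            supp,
            triage=Triage.EXTRACTION_FAILED,
            reason=f"no adapter for {supp.extension!r}",
        )
    try:
        return replace(supp, text=adapter(data))
    except Exception as exc:  # adapter failure must not abort the corpus run
        log.warning("extraction failed for %s: %s", supp.filename, exc)
        return replace(
            supp, triage=Triage.EXTRACTION_FAILED, reason=f"extraction error: {exc}"
        )


# ---------------------------------------------------------------------------
# Corpus-level convenience

def supp_dir_for(xml_path: Path) -> Path:
    """Supplementary files for ``X.xml`` live in the sibling directory
    ``X_files/``, keyed by filename."""
    return xml_path.parent / f"{xml_path.stem}_files"


def load_document(
    xml_path: str | Path,
    config: IOConfig | None = None,
    adapters: Mapping[str, Callable[[bytes], str]] | None = None,
) -> DocumentRecord:
    """Parse, triage and extract one article and its supplementary files."""
    xml_path = Path(xml_path)
    doc = parse_article_xml(xml_path)
    manifest = triage_supplementary(doc.supp_manifest, config)
    supp_dir = supp_dir_for(xml_path)
    out: list[SuppFile] = []
    for supp in manifest:
        if supp.triage is not Triage.MINEABLE:
            out.append(supp)
            continue
        path = supp_dir / supp.filename
        if not path.is_file():
            out.append(
                replace(
                    supp,
                    triage=Triage.EXTRACTION_FAILED,
                    reason="file missing on disk",
                )
            )
            continue
        out.append(extract_text(supp, path.read_bytes(), adapters))
    doc.supp_manifest = out
    return doc


def read_corpus(
    corpus_dir: str | Path,
    config: IOConfig | None = None,
    adapters: Mapping[str, Callable[[bytes], str]] | None = None,
    apply_year_filter: bool = False,
) -> Iterator[DocumentRecord]:
    """Yield documents for every ``*.xml`` file in ``corpus_dir`` (sorted
    for determinism)."""
    if config is None:
        config = IOConfig()
    for xml_path in sorted(Path(corpus_dir).glob("*.xml")):
        doc = load_document(xml_path, config, adapters)
        if (
            apply_year_filter
            and doc.pub_year is not None
            and doc.pub_year < config.min_year
        ):
            continue
        yield doc


def write_triage_report(
    docs: Iterable[DocumentRecord], path: str | Path
) -> pd.DataFrame:
    rows = [
        {
            "article_id": doc.article_id,
            "filename": supp.filename,
            "mime": (
                f"{supp.mime_type}/{supp.mime_subtype}"
                if supp.mime_subtype
                else supp.mime_type
            ),
            "extension": supp.extension,
            "triage": supp.triage.value if supp.triage else "",
            "reason": supp.reason,
        }
        for doc in docs
        for supp in doc.supp_manifest
    ]
    frame = pd.DataFrame(
        rows,
        columns=["article_id", "filename", "mime", "extension", "triage", "reason"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame
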