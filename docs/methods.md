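# Methods

## The annotation model

An accession citation is modelled as a pattern match licensed by context.
Each of the ten supported databases is described by (i) a small set of
anchored regular expressions over its accession grammar and (ii) a list of
lowercase cue words. Accession grammars are short and collide heavily with
ordinary text — a six-digit token fits the OMIM grammar, a letter plus five
digits fits ENA, and `P09372` fits both ENA and UniProt — so a raw match is
only weak evidence. The annotator therefore:

1. finds **candidates**: every whole-token pattern match whose neighbouring
   characters are not alphanumeric (`\b` is wrong for grammars with
   internal hyphens such as ArrayExpress `E-[A-Z]{4}-[0-9]+`, so explicit
   look-arounds are used). Overlapping candidates from different databases
   coexist at this stage;
2. applies the **cue gate**: a candidate survives iff one of its database's
   cue words occurs, case-insensitively and at word boundaries, outside the
   candidate span and within `cue_window` characters of it (mode `window`,
   default) or anywhere in the same section (mode `section`). The nearest
   licensing cue and its character distance are recorded. A cue inside the
   candidate token itself (the `PFAM` prefix of `PFAM12345`) never
   self-licenses;
3. **resolves overlaps** to pairwise-disjoint spans, greedily preferring
   the candidate with the smallest cue distance, then the longest span,
   then the highest registry priority. Priority ranks the grammars from
   most specific (Ensembl, ArrayExpress, InterPro, Pfam, RefSeq, RefSNP)
   to most collision-prone (UniProt, ENA, OMIM, PDBe), so when distances
   tie the less ambiguous reading wins. The procedure is deterministic for
   fixed input.

Accepted mentions are normalized to uppercase; RefSeq version suffixes
(`NM_000546.5` → `NM_000546`) are stripped in the normal form because the
archives key on the versionless accession.

Case policy: grammars with distinctive alphabetic prefixes (RefSNP,
RefSeq, Ensembl, InterPro, Pfam, ArrayExpress) match case-insensitively —
rs-identifiers in particular are conventionally lowercase — while the
short generic grammars (ENA, UniProt, PDBe, OMIM) are strictly uppercase
to limit false positives in prose.

Text is treated as a flat character sequence and whitespace-normalized
(runs of whitespace collapse to one space) before matching, so annotation
offsets are reproducible across readers and file formats.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `cue_mode` | `window` | cue scope: character window vs whole section |
| `cue_window` | 300 chars | one-sided licensing distance around a candidate |
| `drop_invalid` | true | remove validator-rejected annotations from counts |
| source-code extensions | `.c .cpp .h .py .pl .java .r .m .sh .js` | triage screen |
| `min_year` | 1990 | corpus-era filter on publication year |

The cue scope of the original curation tooling this emulates is not
documented; both modes are provided and the bounded window is the default
because it is the stricter reading of "contextual". 300 characters is
roughly a sentence-or-two radius in normalized prose.

## Supplementary-file handling

Triage is a total, idempotent labelling of the manifest: media MIME
classes (image/audio/video) are excluded first, then known source-code
extensions, then anything text-convertible (by MIME class `text`, a known
subtype, or a known extension) is mineable; everything else is excluded as
unconvertible. MIME declared on the file link is trusted over the filename
extension when they conflict. Extraction failures (no adapter, undecodable
or corrupt content) mark the single file `extraction_failed` and never
abort a corpus run. Decoding tries UTF-8 (with and without BOM) and falls
back to latin-1, which cannot fail; binary formats without a registered
adapter fail extraction cleanly. PDF/DOC/XLS converters are deliberately
interface points — an adapter is any `bytes -> str` callable keyed by
extension — rather than bundled dependencies.

The article body is the character data under the JATS `<body>` element,
including figure and table text, excluding any reference list: Reference
lists are dense in identifier-like strings (page ranges, years,
six-digit article ids) that are not data citations.

## Evaluation protocol

Scoring is at unique *(database, normalized accession)* per article —
publisher-supplied gold annotations are identifier-level, not span-level.
TP/FP/FN are summed over articles; precision, recall and F-score are
reported as percentages, half-up-rounded to 2 decimals (bankers' rounding
would flip some cells), with unrounded values retained internally. The
manual protocol is the operation *reassign k reviewed false positives to
true positives* (`fp -= k`, `tp += k`, FN unchanged), which can only raise
precision and recall (a tested invariant).

## Corpus statistics conventions

Body and supplementary totals are **mention** counts — every accepted span
counts once; corpus-scale supplementary totals run orders of magnitude
above the article counts, which only mention-level counting produces.
**Shared citations** are unique pairs occurring in both sections of the
same article, and the shared percentage is taken against the supplementary
mention total. Ratios with a zero denominator are reported as undefined,
never infinity. Top-fraction concentration ranks the articles that have at
least one supplementary citation of the database by their supplementary
mention count (ties broken by article id) and reports the share of
mentions held by the top `ceil(fraction · n)` articles. Yearly averages
are computed over articles that have mineable supplementary data, with an
optional per-database exclusion filter (e.g. to view body trends without
the dominant nucleotide-archive citations).

## The synthetic corpus

The generator emits the same on-disk layout the reader consumes
(`<id>.xml` + `<id>_files/`) and a ground-truth table of every planted
mention. Its purpose is to exercise the pipeline's mechanisms, and its
construction makes the intended outcome provable:

* accessions are sampled uniformly-ish from each grammar; planted cued
  mentions carry their cue immediately before the token, so the own-cue
  distance (≈7 characters) is always smaller than any other sentence's
  cue — cross-grammar collisions (ENA/UniProt, ENA/RefSNP) therefore
  resolve to the intended database;
* uncued mentions and decoys live in blocks separated from all cued text
  by more than `cue_window` characters of neutral filler, so a window-mode
  annotator can never license them; the filler prose is lowercase,
  digit-free and cue-free, so it can neither match a pattern nor license
  one;
* each article carries one guaranteed plain-text supplementary file plus
  extra files drawn from a format mix that includes media and source-code
  decoy files (the latter containing a planted accession that triage must
  screen out);
* per-article, per-database mention counts are Poisson with the configured
  means; a body mention is repeated in a supplementary file with
  probability `shared_prob`; an optional heavy-tail switch multiplies
  every k-th article's supplementary counts to emulate "data dump"
  articles.

Defaults (50 articles, years 1990–2014, body rate 0.3 and supplementary
rate 1.5 mentions/article/database, `cue_prob` 0.9, decoy rate 0.5,
`shared_prob` 0.1) give a small corpus with a supplementary:body ratio
of ~5, a visible minority of uncued mentions and decoys, and every triage
class represented. What the generator does **not** emulate: linguistic
realism, real PDF/DOC binaries, correlated accession lists, publisher
tagging idiosyncrasies, or real-world cue phrasing — so perfect recovery
on synthetic text demonstrates the mechanics of cue gating and overlap
resolution, not expected performance on real articles (the benchmark
table's 75–99% F-scores are the realistic reference there).

Test and acceptance runs use 400–500-article corpora (a few seconds of
runtime); rate-recovery checks compare observed per-database mention rates
to the configured Poisson means within three standard errors of the mean.

## Numerical and degenerate-input choices

* Precision is 100 when FP = 0 and TP > 0; all metrics are 0 when TP = 0
  with nonzero FP or FN; all-zero confusion counts are an error
  ("undefined metrics").
* Report rounding is decimal half-up (2 decimals; corpus percentages
  printed at the table's own precision).
* A database with zero supplementary citations has no concentration
  result (error), and a whole-corpus fraction of 1.0 returns exactly 100%.
* Unknown database identifiers raise a dedicated error everywhere;
  unknown cue modes and invalid generator configurations fail fast at
  construction.
* Validators never abort a run: a raising backend downgrades the affected
  annotations to `unvalidated` with a warning.

## Known limitations

* No sentence splitting: the cue window is purely character-based and can
  cross sentence or cell boundaries.
* No machine-learned disambiguation; a decoy token that happens to sit
  within the window of a genuine cue for its database will be annotated.
* The OMIM grammar (`[0-9]{6}`) remains the most false-positive-prone even
  with cue gating; its cue (`omim`) is the only defence.
* XLS (pre-2007 Excel), PDF and DOC require user-registered adapters;
  without one such files are counted `extraction_failed`.
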