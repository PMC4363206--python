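"""Corpus-level citation statistics: distributions, concentration,
breakdown and yearly averages."""

import math

import pytest

from suppcite import (
    Annotation,
    CitationStatsRow,
    Database,
    DocumentAnnotations,
    DocumentRecord,
    SuppFile,
    Triage,
    citation_distribution,
    corpus_breakdown,
    top_fraction_concentration,
    yearly_averages,
)
from suppcite.evaluation import round_half_up


def _ann(db: Database, acc: str, section: str) -> Annotation:
    return Annotation(
        db_id=db, surface=acc, start=0, end=len(acc), pattern_index=0,
        normalized_accession=acc.upper(), cue="x", cue_distance=1,
        section=section,
    )


def _doc_annotations(article_id, body_pairs, supp_pairs):
    da = DocumentAnnotations(article_id=article_id)
    da.body = [_ann(db, acc, "BODY") for db, acc in body_pairs]
    da.supp = {"s1.txt": [_ann(db, acc, "SUPP:s1.txt") for db, acc in supp_pairs]}
    return da


# Published distribution table: per-database supplementary and body mention
# counts with shared unique pairs; the derived columns (supp/body ratio and
# shared percentage) must recompute from the counts.
PUBLISHED_DISTRIBUTION = [
    # db, supp, body, shared, ratio, shared_pct
    (Database.ENSEMBL, 1_292_198, 1_152, 23, 1121.70, 0.002),
    (Database.REFSEQ, 2_540_260, 2_864, 178, 886.96, 0.007),
    (Database.INTERPRO, 564_956, 639, 77, 884.13, 0.014),
    (Database.UNIPROT, 2_972_519, 9_387, 540, 316.66, 0.018),
    (Database.PFAM, 924_624, 2_968, 435, 311.53, 0.047),
    (Database.REFSNP, 2_443_679, 31_061, 3_849, 78.67, 0.16),
    (Database.ENA, 3_390_319, 125_534, 4_167, 27.01, 0.12),
    (Database.PDBE, 197_850, 44_269, 2_805, 4.47, 1.42),
    (Database.ARRAYEXPRESS, 2_377, 1_565, 53, 1.52, 2.23),
    (Database.OMIM, 2_400, 2_779, 19, 0.86, 0.79),
]


@pytest.mark.parametrize(
    "db, supp, body, shared, ratio, shared_pct", PUBLISHED_DISTRIBUTION
)
def test_distribution_derived_columns_from_counts(db, supp, body, shared,
                                                  ratio, shared_pct):
    row = CitationStatsRow.from_counts(db, supp, body, shared)
    assert round_half_up(row.ratio, 2) == ratio
    ndigits = 3 if row.shared_pct < 0.05 else 2
    assert round_half_up(row.shared_pct, ndigits) == shared_pct
    # pre-rounding identity: ratio * body_count == supp_count exactly
    assert row.ratio * body == pytest.approx(supp, rel=1e-12)


def test_distribution_zero_body_count_ratio_undefined():
    row = CitationStatsRow.from_counts(Database.ENA, 10, 0, 0)
    assert row.ratio is None
    empty = CitationStatsRow.from_counts(Database.ENA, 0, 0, 0)
    assert empty.shared_pct is None


def test_citation_distribution_counts_mentions_and_shared_pairs():
    da1 = _doc_annotations(
        "a1",
        body_pairs=[(Database.UNIPROT, "P09372"), (Database.UNIPROT, "P09372"),
                    (Database.OMIM, "601665")],
        supp_pairs=[(Database.UNIPROT, "P09372"), (Database.UNIPROT, "Q12345")],
    )
    da2 = _doc_annotations(
        "a2",
        body_pairs=[(Database.OMIM, "100100")],
        supp_pairs=[(Database.OMIM, "100200")],
    )
    rows = {r.db_id: r for r in citation_distribution([da1, da2])}
    uni = rows[Database.UNIPROT]
    # two body mentions of P09372 both count; shared pairs count once
    assert (uni.supp_count, uni.body_count, uni.shared_count) == (2, 2, 1)
    omim = rows[Database.OMIM]
    assert (omim.supp_count, omim.body_count, omim.shared_count) == (1, 2, 0)
    # conservation over databases
    assert sum(r.supp_count for r in rows.values()) == 3
    assert sum(r.body_count for r in rows.values()) == 4
    # shared pairs cannot exceed either section's unique pairs
    for row in rows.values():
        assert row.shared_count <= min(row.supp_count, row.body_count)


def test_citation_distribution_empty_corpus():
    rows = citation_distribution([])
    assert len(rows) == 10
    assert all(r.supp_count == 0 and r.ratio is None for r in rows)


def _skewed_corpus():
    """20 articles: one with 81 supplementary citations, 19 with one each."""
    corpus = []
    for i in range(20):
        n = 81 if i == 0 else 1
        pairs = [(Database.REFSNP, f"RS1{i:02d}{j:03d}") for j in range(n)]
        corpus.append(_doc_annotations(f"a{i:02d}", [], pairs))
    return corpus


def test_concentration_hand_enumerated_skew():
    result = top_fraction_concentration(_skewed_corpus(), Database.REFSNP, 0.05)
    assert result.n_articles == 20
    assert result.n_top == 1
    assert result.pct_in_top == pytest.approx(81.0)


def test_concentration_whole_corpus_and_uniform_closed_form():
    corpus = _skewed_corpus()
    assert top_fraction_concentration(
        corpus, Database.REFSNP, 1.0
    ).pct_in_top == pytest.approx(100.0)

    uniform = [
        _doc_annotations(f"u{i}", [], [(Database.OMIM, f"10{i:04d}")])
        for i in range(40)
    ]
    result = top_fraction_concentration(uniform, Database.OMIM, 0.05)
    assert result.pct_in_top == pytest.approx(100.0 * math.ceil(0.05 * 40) / 40)


def test_concentration_monotone_in_fraction():
    corpus = _skewed_corpus()
    values = [
        top_fraction_concentration(corpus, Database.REFSNP, f).pct_in_top
        for f in (0.05, 0.1, 0.25, 0.5, 1.0)
    ]
    assert values == sorted(values)
    assert values[-1] == pytest.approx(100.0)


def test_concentration_errors():
    with pytest.raises(ValueError, match="no supplementary citations"):
        top_fraction_concentration(_skewed_corpus(), Database.ENA, 0.05)
    with pytest.raises(ValueError, match="fraction"):
        top_fraction_concentration(_skewed_corpus(), Database.REFSNP, 0.0)


def _record(article_id, year, n_mineable, n_other=0):
    manifest = [
        SuppFile(f"m{i}.txt", "text", "plain", triage=Triage.MINEABLE)
        for i in range(n_mineable)
    ] + [
        SuppFile(f"x{i}.png", "image", "png", triage=Triage.EXCLUDED_MEDIA)
        for i in range(n_other)
    ]
    return DocumentRecord(article_id, year, "", manifest)


def test_corpus_breakdown_counts_and_percentages():
    corpus = [
        (_record("a1", 2000, 2, 1),
         _doc_annotations("a1", [(Database.ENA, "AB123456")],
                          [(Database.ENA, "AB123456")])),
        (_record("a2", 2001, 1),
         _doc_annotations("a2", [], [(Database.OMIM, "100100")])),
        (_record("a3", 2002, 0, 1), _doc_annotations("a3", [], [])),
        (_record("a4", 2003, 0), DocumentAnnotations(article_id="a4")),
    ]
    # a3/a4 have no supp annotations: strip the fixture's default supp dict
    corpus[2][1].supp = {}
    corpus[3][1].supp = {}
    bd = corpus_breakdown(corpus)
    assert bd.n_articles_total == 4
    assert bd.n_with_mineable_supp == 2
    assert bd.n_body_cited == 1
    assert bd.n_both_body_and_supp == 1
    assert bd.n_files_total == 5
    assert bd.n_files_mineable == 3
    assert bd.n_supp_cited_files == 2
    assert bd.pct_with_mineable_supp == pytest.approx(50.0)
    assert bd.pct_supp_cited_files == pytest.approx(100 * 2 / 3)
    d = bd.to_dict()
    assert d["pct_both_body_and_supp"] == 25.0


def test_corpus_breakdown_empty_corpus_is_all_zero():
    bd = corpus_breakdown([])
    assert bd.n_articles_total == 0
    assert bd.pct_with_mineable_supp == 0.0


def test_yearly_averages_and_exclude_filter():
    corpus = [
        (_record("a1", 2005, 1),
         _doc_annotations("a1", [(Database.ENA, "AB123456"),
                                 (Database.ENA, "AB123457")],
                          [(Database.ENA, "AB123458")])),
        (_record("a2", 2005, 1),
         _doc_annotations("a2", [(Database.OMIM, "100100"),
                                 (Database.OMIM, "100200"),
                                 (Database.OMIM, "100300"),
                                 (Database.OMIM, "100400")], [])),
        # no mineable supp data: excluded from the yearly population
        (_record("a3", 2005, 0),
         _doc_annotations("a3", [(Database.ENA, "AB999999")], [])),
    ]
    corpus[1][1].supp = {}
    frame = yearly_averages(corpus)
    assert list(frame.index) == [2005]
    assert frame.loc[2005, "n_articles"] == 2
    assert frame.loc[2005, "mean_body"] == pytest.approx(3.0)  # (2+4)/2
    assert frame.loc[2005, "mean_supp"] == pytest.approx(0.5)

    no_ena = yearly_averages(corpus, exclude_db=[Database.ENA])
    assert no_ena.loc[2005, "mean_body"] == pytest.approx(2.0)  # (0+4)/2
    assert no_ena.loc[2005, "mean_supp"] == pytest.approx(0.0)
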