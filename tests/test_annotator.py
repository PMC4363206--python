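"""Candidate finding, cue gating, overlap resolution and document-level
annotation."""

import pytest

from suppcite import (
    AnnotatorConfig,
    Database,
    annotate_document,
    annotate_text,
    annotations_to_frame,
    apply_context_filter,
    conforms,
    find_candidates,
    load_document,
    normalize_text,
    resolve_overlaps,
    strip_cues,
)
from suppcite.annotator import ANNOTATION_COLUMNS, Candidate


def test_find_candidates_empty_text():
    assert find_candidates("") == []


def test_find_candidates_ambiguous_token_yields_both_databases():
    cands = find_candidates("accession P09372 from swissprot")
    found = {(c.db_id, c.surface) for c in cands}
    assert (Database.UNIPROT, "P09372") in found
    assert (Database.ENA, "P09372") in found


def test_find_candidates_single_ensembl_gene():
    cands = find_candidates("gene ENSG00000139618 here")
    assert [(c.db_id, c.surface) for c in cands] == [
        (Database.ENSEMBL, "ENSG00000139618")
    ]
    (c,) = cands
    assert "gene ENSG00000139618 here"[c.start:c.end] == c.surface


def test_find_candidates_requires_word_boundaries():
    # embedded in a longer alphanumeric token: no match
    assert find_candidates("xIPR000001") == []
    assert find_candidates("IPR0000012") == [] or all(
        c.db_id is not Database.INTERPRO for c in find_candidates("IPR0000012")
    )


def test_context_filter_keeps_cued_and_drops_cueless():
    text = "the swissprot entry P09372 was reported"
    cands = find_candidates(text)
    kept = apply_context_filter(cands, text)
    assert {(c.db_id, c.surface) for c in kept} == {(Database.UNIPROT, "P09372")}
    (c,) = kept
    assert c.cue == "swissprot"
    assert c.cue_distance == text.index("P09372") - (
        text.index("swissprot") + len("swissprot")
    )

    no_cue = "we observed 123456 in the cohort"
    assert apply_context_filter(find_candidates(no_cue), no_cue) == []


def test_context_filter_window_vs_section_mode():
    filler = "lorem ipsum " * 500  # ~6000 characters, cue-free
    text = "pdb " + filler + " 1ABC mentioned"
    cands = [c for c in find_candidates(text) if c.db_id is Database.PDBE]
    assert cands
    window = apply_context_filter(cands, text, config=AnnotatorConfig("window", 300))
    section = apply_context_filter(cands, text, config=AnnotatorConfig("section", 300))
    assert window == []
    assert len(section) == len(cands)


def test_context_filter_cue_inside_span_does_not_self_license():
    # "pfam" occurs only as the accession's own prefix
    text = "we scanned PFAM12345 domains"
    cands = [c for c in find_candidates(text) if c.db_id is Database.PFAM]
    assert cands
    assert apply_context_filter(cands, text) == []


def test_context_filter_unknown_mode_rejected():
    with pytest.raises(ValueError):
        AnnotatorConfig(cue_mode="paragraph")


def test_resolve_overlaps_prefers_nearest_cue_then_length_then_priority():
    a = Candidate(Database.UNIPROT, "P09372", 10, 16, 0, cue="swissprot", cue_distance=8)
    b = Candidate(Database.ENA, "P09372", 10, 16, 0, cue="genbank", cue_distance=200)
    assert resolve_overlaps([a, b]) == [a]
    assert resolve_overlaps([b, a]) == [a]
    # identity and disjoint candidates pass through
    assert resolve_overlaps([a]) == [a]
    c = Candidate(Database.OMIM, "123456", 40, 46, 0, cue="omim", cue_distance=3)
    assert resolve_overlaps([a, c]) == [a, c]
    # equal distance and span: higher registry priority (lower rank) wins
    d = Candidate(Database.UNIPROT, "P09372", 10, 16, 0, cue="uniprot", cue_distance=5)
    e = Candidate(Database.ENA, "P09372", 10, 16, 0, cue="embl", cue_distance=5)
    assert resolve_overlaps([d, e]) == [d]


def test_annotate_text_planted_accession_with_cue():
    anns = annotate_text("the interpro family record IPR004839 was matched")
    assert len(anns) == 1
    ann = anns[0]
    assert ann.db_id is Database.INTERPRO
    assert ann.normalized_accession == "IPR004839"
    assert ann.section == "BODY"


def test_annotate_text_cue_words_alone_yield_nothing():
    assert annotate_text("uniprot swissprot genbank pdb interpro omim") == []


def test_annotate_text_counts_cued_not_decoys():
    pad = "neutral filler words without meaning " * 12  # > 300 chars
    text = (
        "the uniprot entry P12345 was studied. the omim entry 601665 is known. "
        + pad
        + " decoy Q99999 and decoy 222222 appear with no context."
    )
    anns = annotate_text(text)
    assert {(a.db_id, a.normalized_accession) for a in anns} == {
        (Database.UNIPROT, "P12345"),
        (Database.OMIM, "601665"),
    }


def test_annotate_text_spans_sorted_nonoverlapping_and_conformant():
    text = (
        "genbank AB123456 near uniprot P09372 and ensembl ENSG00000139618 "
        "with snp rs5551212 and refseq NM_000546.5"
    )
    anns = annotate_text(text)
    assert len(anns) >= 4
    for first, second in zip(anns, anns[1:]):
        assert first.end <= second.start
    norm = normalize_text(text)
    for ann in anns:
        assert norm[ann.start:ann.end] == ann.surface
        assert conforms(ann.db_id, ann.surface)
    # deterministic
    assert annotate_text(text) == anns


def test_annotate_text_whitespace_normalization_gives_stable_offsets():
    anns1 = annotate_text("the pdb   entry\n\t 1ABC here")
    anns2 = annotate_text("the pdb entry 1ABC here")
    assert [(a.surface, a.start, a.end) for a in anns1] == [
        (a.surface, a.start, a.end) for a in anns2
    ]


def test_refseq_version_captured_and_stripped_in_normal_form():
    (ann,) = annotate_text("the refseq transcript NM_000546.5 was used")
    assert ann.surface == "NM_000546.5"
    assert ann.normalized_accession == "NM_000546"


def test_cue_stripping_silences_all_annotations(clean_corpus):
    corpus_dir, _config, _truth = clean_corpus
    doc = load_document(sorted(corpus_dir.glob("*.xml"))[0])
    assert annotate_text(doc.body_text)  # sanity: cued text annotates
    assert annotate_text(strip_cues(doc.body_text)) == []


def test_annotate_document_routes_sections(tmp_path, minimal_article_xml):
    xml_path = tmp_path / "PMC7777777.xml"
    xml_path.write_bytes(minimal_article_xml)
    supp_dir = tmp_path / "PMC7777777_files"
    supp_dir.mkdir()
    (supp_dir / "PMC7777777_s1.txt").write_text("pfam domain PF00001 reported")
    doc = load_document(xml_path)
    da = annotate_document(doc)
    assert [(a.db_id, a.normalized_accession) for a in da.body] == [
        (Database.UNIPROT, "P09372")
    ]
    assert list(da.supp) == ["PMC7777777_s1.txt"]
    (supp_ann,) = da.supp["PMC7777777_s1.txt"]
    assert supp_ann.db_id is Database.PFAM
    assert supp_ann.section == "SUPP:PMC7777777_s1.txt"
    # reference-list token was excluded from the body text
    assert all(a.normalized_accession != "IPR999999" for a in da.body)


def test_annotate_document_shared_pair_and_empty_body(tmp_path):
    xml = (
        '<?xml version="1.0"?>'
        '<article xmlns:xlink="http://www.w3.org/1999/xlink">'
        '<front><article-meta>'
        '<article-id pub-id-type="pmcid">PMC1</article-id>'
        "</article-meta></front>"
        "<body><p>the omim entry 601665 described</p>"
        '<supplementary-material mimetype="text" mime-subtype="plain" '
        'xlink:href="s1.txt"/></body></article>'
    )
    xml_path = tmp_path / "PMC1.xml"
    xml_path.write_text(xml)
    supp_dir = tmp_path / "PMC1_files"
    supp_dir.mkdir()
    (supp_dir / "s1.txt").write_text("omim record 601665 again")
    da = annotate_document(load_document(xml_path))
    assert da.shared_pairs == {(Database.OMIM, "601665")}

    # empty body, supp-only annotation
    xml2 = xml.replace("the omim entry 601665 described", "")
    (tmp_path / "PMC2").mkdir(exist_ok=True)
    xml_path2 = tmp_path / "PMC2.xml"
    xml_path2.write_text(xml2.replace("PMC1", "PMC2"))
    supp2 = tmp_path / "PMC2_files"
    supp2.mkdir()
    (supp2 / "s1.txt").write_text("pfam domain PF00001")
    da2 = annotate_document(load_document(xml_path2))
    assert da2.body == []
    assert len(da2.supp_annotations) == 1


def test_annotation_table_has_stable_column_order(clean_corpus):
    corpus_dir, _config, _truth = clean_corpus
    doc = load_document(sorted(corpus_dir.glob("*.xml"))[0])
    frame = annotations_to_frame(annotate_document(doc))
    assert list(frame.columns) == ANNOTATION_COLUMNS
    assert len(frame) > 0
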