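"""Generate a ground-truthed synthetic corpus and recover it end to end.

Every planted mention is cued and no decoys are planted, so the annotator
should reach precision = recall = 100% against the generator's ground
truth — this is the end-to-end sanity check of the whole pipeline
(XML parsing, triage, extraction, cue gating, overlap resolution).
"""

from tempfile import TemporaryDirectory

from suppcite import (
    GoldStandard,
    SynthConfig,
    align_to_gold,
    annotate_document,
    generate_corpus,
    read_corpus,
    score,
)

with TemporaryDirectory() as tmp:
    config = SynthConfig(
        n_articles=40, cue_prob=1.0, decoy_rate=0.0, shared_prob=0.2, seed=7
    )
    truth = generate_corpus(config, tmp)
    annotations = [annotate_document(doc) for doc in read_corpus(tmp)]

predicted = {
    da.article_id: {(a.db_id, a.normalized_accession)
                    for a in da.all_annotations()}
    for da in annotations
}
gold = GoldStandard(truth.unique_pairs_by_article())
counts = align_to_gold(predicted, gold)
metrics = score(counts).rounded()

print(f"planted mentions : {len(truth.mentions)}")
print(f"TP={counts.tp}  FP={counts.fp}  FN={counts.fn}")
print(
    f"precision={metrics.precision}%  recall={metrics.recall}%  "
    f"F={metrics.f_score}%"
)
print(
    "\nWith ideal cue placement the tool recovers every planted citation "
    "and invents none."
)
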