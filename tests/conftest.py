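import pytest

from suppcite import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def clean_corpus(tmp_path_factory):
    """Small corpus where every planted mention is cued and there are no
    decoys, so an ideal annotator recovers exactly the ground truth."""
    out = tmp_path_factory.mktemp("clean_corpus")
    config = SynthConfig(
        n_articles=30, cue_prob=1.0, decoy_rate=0.0, shared_prob=0.2, seed=101
    )
    truth = generate_corpus(config, out)
    return out, config, truth


@pytest.fixture(scope="session")
def noisy_corpus(tmp_path_factory):
    """Corpus with uncued mentions and pattern-conformant decoys."""
    out = tmp_path_factory.mktemp("noisy_corpus")
    config = SynthConfig(
        n_articles=30, cue_prob=0.7, decoy_rate=1.0, shared_prob=0.1, seed=202
    )
    truth = generate_corpus(config, out)
    return out, config, truth


MINIMAL_ARTICLE = """<?xml version="1.0" encoding="UTF-8"?>
<article xmlns:xlink="http://www.w3.org/1999/xlink">
  <front>
    <article-meta>
      <article-id pub-id-type="pmcid">PMC7777777</article-id>
      <pub-date><year>2007</year></pub-date>
    </article-meta>
  </front>
  <body>
    <sec><p>The uniprot entry P09372 was deposited.</p></sec>
    <sec>
      <supplementary-material mimetype="text" mime-subtype="plain"
        xlink:href="PMC7777777_s1.txt"/>
      <supplementary-material mimetype="video" mime-subtype="mp4"
        xlink:href="PMC7777777_s2.mp4"/>
    </sec>
  </body>
  <back>
    <ref-list><ref><mixed-citation>IPR999999 interpro</mixed-citation></ref></ref-list>
  </back>
</article>
"""


@pytest.fixture()
def minimal_article_xml():
    return MINIMAL_ARTICLE.encode()
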