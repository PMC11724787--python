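"""The generator itself: determinism, quotas, single-violation negatives,
embedding fixtures, and on-disk emission."""

import dataclasses

import numpy as np
import pytest

from copmine.annotation import validate_tree
from copmine.corpus_io import parse_fulltext_xml
from copmine.entity_filter import OrganLexicon
from copmine.matcher import match_copular_pattern
from copmine.synthetic import (
    NEGATIVE_TEMPLATES,
    _NEGATIVE_VIOLATION,
    GoldRecord,
    SyntheticSpec,
    _template_constraints,
    default_themes,
    generate_corpus,
    generate_embedding_fixture,
    read_gold,
    read_parses,
    write_corpus,
)
from copmine.embed_cluster import embed_expressions


SMALL = SyntheticSpec(
    n_articles=10, n_positives=20, n_negatives=20,
    distractor_rate=0.2, n_organ_free_articles=2, random_seed=7,
)


def _fingerprint(parses):
    return [
        (s.text, s.article_id, s.section_title,
         tuple((t.text, t.lemma, t.pos, t.dep_label, t.head_index)
               for t in s.tokens))
        for s in parses
    ]


def test_quotas_and_seed_determinism():
    articles, gold, parses = generate_corpus(SMALL)
    assert len(articles) == 10
    assert sum(g.is_positive for g in gold) == 20
    assert sum(g.template_id.startswith("neg_") for g in gold) == 20
    articles2, gold2, parses2 = generate_corpus(SMALL)
    assert _fingerprint(parses) == _fingerprint(parses2)
    assert gold == gold2


def test_every_sentence_ships_a_valid_tree():
    _, gold, parses = generate_corpus(SMALL)
    assert len(parses) == len(gold)
    assert all(validate_tree(s) for s in parses)


def test_positive_gold_carries_expected_string():
    _, gold, _ = generate_corpus(SMALL)
    for g in gold:
        assert g.is_positive == (g.expected_expression_text is not None)
        if g.is_positive:
            assert g.expected_expression_text.split()[0] in {"a", "an", "the"}


def test_gold_record_invariant_enforced():
    with pytest.raises(ValueError):
        GoldRecord("a", "s", "t", True, None, None, "pos_bare", "brain", "Intro")


def test_trailing_clause_expectation_excludes_the_clause():
    spec = SyntheticSpec(
        n_articles=5, n_positives=12, n_negatives=0,
        positive_templates=("pos_trailing_clause",),
        negative_templates=NEGATIVE_TEMPLATES,
        distractor_rate=0.0, n_organ_free_articles=0, random_seed=1,
    )
    _, gold, parses = generate_corpus(spec)
    for g in gold:
        assert "," in g.sentence_text and "analysis" in g.sentence_text
        assert "analysis" not in g.expected_expression_text
        assert "," not in g.expected_expression_text


def test_zero_distractor_rate_means_only_template_instances():
    spec = SyntheticSpec(
        n_articles=8, n_positives=15, n_negatives=15,
        distractor_rate=0.0, n_organ_free_articles=0, random_seed=2,
    )
    _, gold, _ = generate_corpus(spec)
    assert all(g.template_id != "distractor" for g in gold)
    assert len(gold) == 30


def test_infeasible_theme_quota_fails_before_generation():
    themes = tuple(
        dataclasses.replace(t, target_count=100) for t in default_themes()[:3]
    )
    with pytest.raises(ValueError, match="budget"):
        SyntheticSpec(n_positives=20, themes=themes)


def test_negatives_violate_exactly_their_declared_constraint():
    """Structural check: every negative instance fails its one declared
    template constraint while keeping the prerequisites intact — and,
    independently, the matcher finds nothing in it."""
    _, gold, parses = generate_corpus(SMALL)
    by_key = {(g.article_id, g.sentence_text): g for g in gold}
    lexicon = OrganLexicon()
    n_checked = 0
    for s in parses:
        g = by_key[(s.article_id, s.text)]
        if not g.template_id.startswith("neg_"):
            continue
        constraints = _template_constraints(s)
        assert constraints["organ_present"]
        assert constraints[_NEGATIVE_VIOLATION[g.template_id]] is False
        assert match_copular_pattern(s, lexicon) == []
        n_checked += 1
    assert n_checked == 20


def test_organ_free_articles_mention_no_organ():
    articles, gold, parses = generate_corpus(SMALL)
    lexicon = OrganLexicon()
    organ_free_ids = {a.article_id for a in articles[-2:]}
    for s in parses:
        if s.article_id in organ_free_ids:
            assert all(t.lemma not in lexicon for t in s.tokens)


def test_corpus_roundtrips_through_jats_files(tmp_path):
    articles, gold, parses = generate_corpus(SMALL)
    write_corpus(articles, gold, parses, tmp_path)
    reread = [
        parse_fulltext_xml(p.read_text(), source_name=p.name)
        for p in sorted((tmp_path / "articles").glob("*.xml"))
    ]
    assert len(reread) == len(articles)
    by_id = {a.article_id: a for a in articles}
    for article in reread:
        original = by_id[article.article_id]
        assert article.journal == original.journal
        assert article.year == original.year
        assert [(s.title, s.text) for s in article.sections] == \
            [(s.title, s.text) for s in original.sections]
    assert _fingerprint(read_parses(tmp_path / "parses.jsonl")) == \
        _fingerprint(parses)
    assert read_gold(tmp_path / "gold.jsonl") == gold


def test_embedding_fixture_counts_and_labels():
    texts, labels = generate_embedding_fixture(default_themes()[:5],
                                               per_theme=100, seed=3)
    assert len(texts) == 500
    assert sorted(set(labels)) == [0, 1, 2, 3, 4]
    texts2, labels2 = generate_embedding_fixture(default_themes()[:5],
                                                 per_theme=100, seed=3)
    assert texts == texts2 and labels == labels2


def test_single_theme_fixture_is_one_group():
    texts, labels = generate_embedding_fixture(default_themes()[:1],
                                               per_theme=60, seed=4)
    assert set(labels) == {0} and len(texts) == 60


def test_theme_centroids_separate_in_stub_embedding_space():
    themes = default_themes()
    texts, labels = generate_embedding_fixture(themes, per_theme=50, seed=5)
    labels = np.array(labels)
    vectors = embed_expressions(texts)
    centroids = np.array([
        vectors[labels == k].mean(axis=0) for k in range(len(themes))
    ])
    for k in range(len(themes)):
        intra = np.linalg.norm(vectors[labels == k] - centroids[k],
                               axis=1).mean()
        for j in range(len(themes)):
            if j != k:
                inter = np.linalg.norm(centroids[k] - centroids[j])
                assert inter > 0.5 * intra  # themes never collapse together


def test_overlapping_theme_lexicons_warn(caplog):
    themes = default_themes()[:1] * 2
    with caplog.at_level("WARNING"):
        generate_embedding_fixture(themes, per_theme=5, seed=1)
    assert any("share lexicon" in r.message for r in caplog.records)
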