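"""End-to-end orchestration: filter a corpus, match the copular template,
extract predicate phrases, and score the result against gold bookkeeping.

Extraction failures (a match whose copula has no rightward children) are
logged and dropped, never raised out of a corpus run — at corpus scale a
detected sentence that yields no extractable phrase is expected leakage
between the matching and extraction stages.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .annotation import BackendError, ParsedSentence, ParserBackend, annotate_text
from .corpus_io import Article, ExpressionRecord
from .entity_filter import OrganLexicon, filter_corpus
from .extractor import ExtractionError, TraversalConfig, extract_predicate
from .matcher import DEFAULT_DETERMINERS, CopularMatch, match_copular_pattern
from .synthetic import GoldRecord

logger = logging.getLogger(__name__)


@dataclass
class PipelineStats:
    n_articles_in: int = 0
    n_articles_kept: int = 0
    n_sentences: int = 0
    n_matched_sentences: int = 0
    n_matches: int = 0
    n_expressions: int = 0
    n_extraction_failures: int = 0


@dataclass
class PipelineResult:
    expressions: List[ExpressionRecord]
    #: (article_id, sentence_text) for every sentence with >= 1 match
    matched_sentences: List[Tuple[str, str]]
    stats: PipelineStats


def run_extraction(
    articles: Iterable[Article],
    backend: ParserBackend,
    lexicon: OrganLexicon = OrganLexicon(),
    determiners: frozenset = DEFAULT_DETERMINERS,
    traversal: TraversalConfig = TraversalConfig(),
    *,
    allow_subject_adjective: bool = True,
) -> PipelineResult:
    """Run prefilter -> matcher -> extractor over a corpus of articles."""
    stats = PipelineStats()
    articles = list(articles)
    stats.n_articles_in = len(articles)
    expressions: List[ExpressionRecord] = []
    matched_sentences: List[Tuple[str, str]] = []

    for article in filter_corpus(articles, lexicon, backend):
        stats.n_articles_kept += 1
        for section in article.sections:
            if not section.text.strip():
                continue
            try:
                sentences = annotate_text(section.text, backend)
            except BackendError as exc:
                logger.warning("skipping section %r of %s: %s",
                               section.title, article.article_id, exc)
                continue
            for sentence in sentences:
                stats.n_sentences += 1
                # provenance follows the article being processed, not
                # whatever the backend cached
                sentence = ParsedSentence(
                    tokens=sentence.tokens, text=sentence.text,
                    article_id=article.article_id,
                    section_title=section.title,
                )
                matches = match_copular_pattern(
                    sentence, lexicon, determiners,
                    allow_subject_adjective=allow_subject_adjective,
                )
                if matches:
                    stats.n_matched_sentences += 1
                    matched_sentences.append((article.article_id, sentence.text))
                for match in matches:
                    stats.n_matches += 1
                    try:
                        record = extract_predicate(
                            sentence, match, traversal, article=article
                        )
                    except ExtractionError as exc:
                        stats.n_extraction_failures += 1
                        logger.warning("dropping match: %s", exc)
                        continue
                    expressions.append(record)
                    stats.n_expressions += 1

    logger.info(
        "pipeline: %d/%d articles kept, %d sentences, %d matched, "
        "%d expressions (%d extraction failures)",
        stats.n_articles_kept, stats.n_articles_in, stats.n_sentences,
        stats.n_matched_sentences, stats.n_expressions,
        stats.n_extraction_failures,
    )
    return PipelineResult(expressions=expressions,
                          matched_sentences=matched_sentences, stats=stats)


# ---------------------------------------------------------------------------
# Evaluation against gold bookkeeping
# ---------------------------------------------------------------------------

def matcher_precision_recall(
    matched_sentences: Sequence[Tuple[str, str]],
    gold: Sequence[GoldRecord],
) -> Tuple[float, float]:
    """Sentence-level precision/recall of the matcher against gold plants.

    Sentences are identified by (article_id, sentence_text) multisets, which
    tolerates repeated texts across articles.
    """
    gold_pos = Counter(
        (g.article_id, g.sentence_text) for g in gold if g.is_positive
    )
    matched = Counter(matched_sentences)
    tp = sum(min(matched[k], gold_pos[k]) for k in matched)
    precision = tp / sum(matched.values()) if matched else 1.0
    recall = tp / sum(gold_pos.values()) if gold_pos else 1.0
    return precision, recall


def expression_recovery(
    expressions: Sequence[ExpressionRecord],
    gold: Sequence[GoldRecord],
) -> Tuple[float, int, int]:
    """Fraction of gold predicate strings recovered exactly.

    Compares (article_id, expression_text) multisets; returns
    (recovered_fraction, n_recovered, n_gold).
    """
    gold_expected = Counter(
        (g.article_id, g.expected_expression_text)
        for g in gold if g.is_positive
    )
    got = Counter((e.article_id, e.expression_text) for e in expressions)
    n_gold = sum(gold_expected.values())
    recovered = sum(min(got[k], gold_expected[k]) for k in gold_expected)
    return (recovered / n_gold if n_gold else 1.0), recovered, n_gold
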