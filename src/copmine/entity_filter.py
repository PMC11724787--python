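"""Organ-mention prefilter: reduce a corpus to articles naming a target organ.

Matching is token-lemma based and case-insensitive, so "Kidneys" matches via
the lemma "kidney" while "brainstem" (a single token with its own lemma) does
not.  The prefilter optimizes recall: acronym collisions such as "the BRAIN
initiative" are accepted as over-matches because the downstream copular
matcher disambiguates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .annotation import BackendError, ParserBackend, annotate_text
from .corpus_io import Article

logger = logging.getLogger(__name__)

#: The seven organ surface names surveyed.
DEFAULT_ORGANS = frozenset(
    {"brain", "lung", "pancreas", "stomach", "liver", "kidney", "heart"}
)


@dataclass(frozen=True)
class OrganLexicon:
    """Set of organ lemmas matched case-insensitively against token lemmas."""

    entries: frozenset[str] = DEFAULT_ORGANS

    def __post_init__(self):
        if not self.entries:
            raise ValueError("organ lexicon must be nonempty")
        bad = {e for e in self.entries if e != e.lower() or not e}
        if bad:
            raise ValueError(f"lexicon entries must be lowercase lemmas: {bad}")

    def __contains__(self, lemma: str) -> bool:
        return lemma.lower() in self.entries


def contains_organ_mention(
    article: Article, lexicon: OrganLexicon, backend: ParserBackend
) -> bool:
    """True iff any token in any section has its lemma in the lexicon."""
    if not article.sections:
        raise ValueError(f"article {article.article_id} has no sections")
    for section in article.sections:
        if not section.text.strip():
            continue
        try:
            sentences = annotate_text(section.text, backend)
        except BackendError as exc:
            logger.warning(
                "skipping unannotatable section %r of article %s: %s",
                section.title, article.article_id, exc,
            )
            continue
        for sentence in sentences:
            for token in sentence.tokens:
                if token.lemma in lexicon:
                    return True
    return False


def filter_corpus(
    articles: Iterable[Article],
    lexicon: OrganLexicon,
    backend: ParserBackend,
) -> Iterator[Article]:
    """Yield, in order, the articles that mention at least one target organ."""
    kept = dropped = 0
    for article in articles:
        if contains_organ_mention(article, lexicon, backend):
            kept += 1
            yield article
        else:
            dropped += 1
    logger.info("organ prefilter kept %d articles, dropped %d", kept, dropped)
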