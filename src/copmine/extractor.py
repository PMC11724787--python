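"""Predicate-phrase extraction by rightward dependency-tree traversal.

Given a matched "the organ is a ..." template, the goal is to recover the
complete predicate noun phrase — and nothing more.  Taking the whole rest of
the sentence over-collects: in "The brain is a complex system, and this is
the inspiration for our analysis" only "a complex system" describes the
organ.  The traversal therefore walks the dependency tree rightward from the
copula:

1. start from the copula's immediate rightward children (the predicate head
   and whatever else attaches to the right of "is");
2. scan those frontier tokens for a dependent bearing a followed label —
   nominal modifier, conjunct, or relative clause modifier, checked in that
   order of priority (leftmost wins within a label);
3. when one is found, collect it together with its own immediate rightward
   children, and repeat the scan from there.

The collected token with the greatest index bounds the phrase: the rendered
expression is the contiguous token span from the post-copular determiner
through that index, which naturally picks up left-attached material
(determiners, adjectives) inside the phrase while trailing clauses stay out.

Two guards keep the walk inside the predicate: punctuation tokens are never
collected (in a verb-headed tree the sentence-final period hangs off the
copula and would otherwise drag the span to the end of the sentence), and a
*verbal* conjunct is never followed, because a conjunct headed by a finite
verb is a new clause ("..., and this is the inspiration"), not a coordinated
noun phrase.  Relative-clause dependents are of course verbal and are
followed regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Set, Tuple

from .annotation import ParsedSentence, TokenAnnotation, VERBAL_POS, validate_tree
from .corpus_io import Article, ExpressionRecord
from .matcher import CopularMatch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraversalConfig:
    """Which dependency labels the traversal follows, and a depth safeguard.

    The label order is significant: it is the scan priority at each step.
    """

    follow_labels: Tuple[str, ...] = ("nmod", "conj", "relcl")
    max_iterations: int = 50


class ExtractionError(RuntimeError):
    """Raised when a match yields no extractable predicate tokens."""


def _followable(child: TokenAnnotation, frontier_tok: TokenAnnotation,
                label: str) -> bool:
    if child.dep_label != label or child.is_punct:
        return False
    if child.index <= frontier_tok.index:
        return False  # traversal is strictly rightward
    if label == "conj" and child.pos in VERBAL_POS:
        return False  # verbal conjunct = new clause, do not follow
    return True


def _pick_followed(sentence: ParsedSentence, frontier: List[TokenAnnotation],
                   config: TraversalConfig) -> Optional[TokenAnnotation]:
    """The single dependent followed from this frontier, or None.

    Labels are tried in configured priority order; within a label the
    leftmost candidate (smallest index) wins.
    """
    for label in config.follow_labels:
        candidates = [
            child
            for tok in frontier
            for child in sentence.children(tok.index)
            if _followable(child, tok, label)
        ]
        if candidates:
            return min(candidates, key=lambda t: t.index)
    return None


def collect_predicate_indices(
    sentence: ParsedSentence, match: CopularMatch, config: TraversalConfig
) -> Set[int]:
    """Indices gathered by the iterative frontier walk (excluding punctuation)."""
    frontier = sentence.rightward_children(match.copula_index)
    collected: Set[int] = {t.index for t in frontier}
    for _ in range(config.max_iterations):
        followed = _pick_followed(sentence, frontier, config)
        if followed is None:
            break
        frontier = sentence.rightward_children(followed.index)
        collected.add(followed.index)
        collected.update(t.index for t in frontier)
    return collected


def _render(sentence: ParsedSentence, match: CopularMatch,
            collected: Set[int]) -> str:
    """Contiguous span from the post-copular determiner to the last collected
    token, with any trailing punctuation stripped."""
    stop = max(collected)
    while stop > match.det2_index and sentence.tokens[stop].is_punct:
        stop -= 1
    return sentence.span_text(match.det2_index, stop)


def _to_record(sentence: ParsedSentence, match: CopularMatch, text: str,
               article: Optional[Article]) -> ExpressionRecord:
    adjective = (
        sentence.tokens[match.adjective_index].text.lower()
        if match.adjective_index is not None
        else None
    )
    return ExpressionRecord(
        expression_text=text,
        organ=match.organ,
        subject_adjective=adjective,
        sentence_text=sentence.text,
        article_id=article.article_id if article else sentence.article_id,
        journal=article.journal if article else "",
        year=article.year if article else None,
        section_title=sentence.section_title,
    )


def extract_predicate(
    sentence: ParsedSentence,
    match: CopularMatch,
    config: TraversalConfig = TraversalConfig(),
    *,
    article: Optional[Article] = None,
) -> ExpressionRecord:
    """Extract the predicate expression for one match.

    Raises :class:`ExtractionError` when the copula has no rightward
    non-punctuation children (nothing to extract) — corpus pipelines log and
    drop such matches rather than aborting.
    """
    if not validate_tree(sentence):
        raise ValueError(f"invalid tree for sentence {sentence.text!r}")
    collected = collect_predicate_indices(sentence, match, config)
    if not collected:
        raise ExtractionError(
            f"copula at index {match.copula_index} has no rightward children "
            f"in {sentence.text!r}"
        )
    return _to_record(sentence, match, _render(sentence, match, collected), article)


# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------

def _oracle_collect(sentence: ParsedSentence, head: int, depth: int,
                    config: TraversalConfig) -> Set[int]:
    """Recursive re-statement of the traversal, for cross-checking only."""
    kids = sentence.rightward_children(head)
    acc = {t.index for t in kids}
    if depth >= config.max_iterations:
        return acc
    best: Optional[TokenAnnotation] = None
    best_rank = len(config.follow_labels)
    for kid in kids:
        for child in sentence.children(kid.index):
            for rank, label in enumerate(config.follow_labels):
                if _followable(child, kid, label):
                    if rank < best_rank or (
                        best is not None
                        and rank == best_rank
                        and child.index < best.index
                    ):
                        best, best_rank = child, rank
    if best is not None:
        acc.add(best.index)
        acc |= _oracle_collect(sentence, best.index, depth + 1, config)
    return acc


def extract_predicate_oracle(
    sentence: ParsedSentence,
    match: CopularMatch,
    config: TraversalConfig = TraversalConfig(),
    *,
    article: Optional[Article] = None,
) -> ExpressionRecord:
    """Same contract as :func:`extract_predicate`, written as a direct
    recursive walk; exists solely for equivalence testing."""
    if not validate_tree(sentence):
        raise ValueError(f"invalid tree for sentence {sentence.text!r}")
    collected = _oracle_collect(sentence, match.copula_index, 0, config)
    if not collected:
        raise ExtractionError(
            f"copula at index {match.copula_index} has no rightward children "
            f"in {sentence.text!r}"
        )
    return _to_record(sentence, match, _render(sentence, match, collected), article)
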