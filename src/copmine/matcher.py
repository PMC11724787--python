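"""Detection of the copular template "[DET] [ADJ?] [ORGAN] is [DET] ...".

A match requires, on the surface, the exact token sequence

    determiner (the/a/an)  [optional adjective]  organ  "is"  determiner

and, in the dependency tree, that the organ token is the nominal subject of
the clause headed by that very copula.  The tree check is what rejects
sentences where an organ merely sits next to "is" without being the subject.
Similes ("the brain is like a computer") fail because the comparison marker
intervenes between the copula and the second determiner; negations and
modals fail for the same adjacency reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional

from .annotation import ParsedSentence, TokenAnnotation, validate_tree
from .entity_filter import OrganLexicon

#: Determiners accepted on both sides of the template.  "an" is included
#: because predicates such as "an energy demanding organ" require it.
DEFAULT_DETERMINERS = frozenset({"the", "a", "an"})

NSUBJ = "nsubj"


@dataclass(frozen=True)
class CopularMatch:
    """Token indices of one template occurrence inside a parsed sentence."""

    sentence: ParsedSentence
    det1_index: int
    adjective_index: Optional[int]
    organ_index: int
    copula_index: int
    det2_index: int
    organ: str

    def __post_init__(self):
        if not (self.det1_index < self.organ_index < self.copula_index
                < self.det2_index):
            raise ValueError("match indices out of order")
        if self.adjective_index is not None and not (
            self.det1_index < self.adjective_index < self.organ_index
        ):
            raise ValueError("adjective index outside det1..organ window")


def _is_determiner(token: TokenAnnotation, determiners: FrozenSet[str]) -> bool:
    return token.pos == "DET" and token.text.lower() in determiners


def match_copular_pattern(
    sentence: ParsedSentence,
    lexicon: OrganLexicon,
    determiners: FrozenSet[str] = DEFAULT_DETERMINERS,
    *,
    allow_subject_adjective: bool = True,
) -> List[CopularMatch]:
    """Return every non-overlapping template occurrence, left to right.

    The organ is matched on its (lowercase) lemma, the copula and determiners
    on lowercased surface text, so the matcher is insensitive to casing of the
    input text.  At most one adjectival token is allowed between the first
    determiner and the organ; disable with ``allow_subject_adjective=False``
    to require strict determiner-organ adjacency.
    """
    if not validate_tree(sentence):
        raise ValueError(f"invalid dependency tree for sentence {sentence.text!r}")
    tokens = sentence.tokens
    n = len(tokens)
    matches: List[CopularMatch] = []
    i = 0
    while i < n:
        tok = tokens[i]
        if tok.lemma in lexicon and tok.dep_label == NSUBJ:
            copula = i + 1
            if (
                copula < n
                and tokens[copula].text.lower() == "is"
                and tok.head_index == copula
            ):
                det1 = adjective = None
                if i >= 1 and _is_determiner(tokens[i - 1], determiners):
                    det1 = i - 1
                elif (
                    allow_subject_adjective
                    and i >= 2
                    and tokens[i - 1].pos == "ADJ"
                    and _is_determiner(tokens[i - 2], determiners)
                ):
                    det1, adjective = i - 2, i - 1
                det2 = copula + 1
                if det1 is not None and det2 < n and _is_determiner(
                    tokens[det2], determiners
                ):
                    matches.append(CopularMatch(
                        sentence=sentence,
                        det1_index=det1,
                        adjective_index=adjective,
                        organ_index=i,
                        copula_index=copula,
                        det2_index=det2,
                        organ=tok.lemma.lower(),
                    ))
                    i = det2 + 1  # non-overlapping: resume after the template
                    continue
        i += 1
    return matches
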