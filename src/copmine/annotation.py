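"""Linguistic annotation layer: tokens, dependency trees, and parser backends.

The matcher and extractor operate on :class:`ParsedSentence` objects carrying a
dependency tree in a fixed canonical scheme, so they are independent of any one
statistical parser.  The canonical scheme is verb-headed: the copular verb is
the head of its clause, the subject noun attaches to it with the nominal-subject
label, and the predicate noun attaches to it as an attribute complement.

Canonical dependency labels used throughout the package:

====================  =========================================================
label                 relation
====================  =========================================================
``nsubj``             nominal subject of a clause
``attr``              predicative (attribute) complement of a copular verb
``det``               determiner of a noun
``amod``              adjectival modifier
``nmod``              nominal modifier of a noun (typically via a preposition)
``case``              the preposition itself, attached to the modifier noun
``conj``              conjunct of a coordination
``cc``                coordinating word
``relcl``             relative clause modifier
``punct``             punctuation
``ROOT``              sentence root (head index is self-referential)
====================  =========================================================

Backends with a different native scheme (e.g. UD proper, where the predicate
noun heads the clause and the copula is a ``cop`` dependent) must map onto
this scheme before handing sentences to downstream stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Protocol, runtime_checkable

logger = logging.getLogger(__name__)

#: Part-of-speech tags treated as verbal when deciding whether a conjunct
#: opens a new clause rather than continuing a noun phrase.
VERBAL_POS = frozenset({"VERB", "AUX"})

#: Tags/labels identifying punctuation tokens.
PUNCT_POS = "PUNCT"
PUNCT_DEP = "punct"


@dataclass(frozen=True)
class TokenAnnotation:
    """One token of a parsed sentence.

    ``head_index`` points at the syntactic head within the same sentence and is
    self-referential for the root token.
    """

    index: int
    text: str
    lemma: str
    pos: str
    dep_label: str
    head_index: int

    @property
    def is_punct(self) -> bool:
        return self.pos == PUNCT_POS or self.dep_label == PUNCT_DEP


@dataclass
class ParsedSentence:
    """A sentence with its dependency tree and provenance."""

    tokens: List[TokenAnnotation]
    text: str
    article_id: str = ""
    section_title: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def children(self, index: int) -> List[TokenAnnotation]:
        """Dependents of the token at ``index``, in surface order."""
        return [
            t
            for t in self.tokens
            if t.head_index == index and t.index != index
        ]

    def rightward_children(
        self, index: int, *, include_punct: bool = False
    ) -> List[TokenAnnotation]:
        """Dependents of token ``index`` that occur to its right."""
        return [
            t
            for t in self.children(index)
            if t.index > index and (include_punct or not t.is_punct)
        ]

    def span_text(self, start: int, stop: int) -> str:
        """Detokenized text of tokens ``start..stop`` inclusive.

        Tokens are joined with single spaces except that closing punctuation
        attaches to the preceding token.
        """
        parts: List[str] = []
        for tok in self.tokens[start : stop + 1]:
            if parts and tok.text in _NO_SPACE_BEFORE:
                parts[-1] += tok.text
            else:
                parts.append(tok.text)
        return " ".join(parts)


_NO_SPACE_BEFORE = {",", ".", ";", ":", "!", "?", ")", "]"}


@runtime_checkable
class ParserBackend(Protocol):
    """Contract for anything that turns raw text into parsed sentences.

    Implementations must be deterministic: identical text in, identical
    annotation out.
    """

    name: str

    def annotate(self, text: str) -> List[ParsedSentence]: ...


class BackendError(RuntimeError):
    """Raised when a parser backend cannot annotate a span of text."""


def validate_tree(sentence: ParsedSentence) -> bool:
    """True iff the head links form a single rooted tree with valid indices.

    Checks: indices are 0..n-1 in order, exactly one self-referential root,
    every head index in range, and every token reachable from the root
    (which together rule out cycles and forests).
    """
    n = len(sentence.tokens)
    if n == 0:
        return False
    for i, tok in enumerate(sentence.tokens):
        if tok.index != i:
            return False
        if not (0 <= tok.head_index < n):
            return False
    roots = [t.index for t in sentence.tokens if t.head_index == t.index]
    if len(roots) != 1:
        return False
    # BFS from the root; all n tokens must be reached.
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for t in sentence.tokens:
        if t.head_index != t.index:
            children[t.head_index].append(t.index)
    seen = {roots[0]}
    stack = [roots[0]]
    while stack:
        for c in children[stack.pop()]:
            if c in seen:
                return False
            seen.add(c)
            stack.append(c)
    return len(seen) == n


def annotate_text(text: str, backend: ParserBackend) -> List[ParsedSentence]:
    """Segment and parse ``text`` with ``backend``, dropping invalid trees.

    Raises :class:`ValueError` on empty input and :class:`BackendError` if the
    backend fails; sentences whose head links do not form a valid tree are
    dropped with a logged warning rather than propagated downstream.
    """
    if not text or not text.strip():
        raise ValueError("annotate_text requires nonempty text")
    try:
        sentences = backend.annotate(text)
    except BackendError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise BackendError(
            f"backend {getattr(backend, 'name', backend)!r} failed on text "
            f"starting {text[:60]!r}: {exc}"
        ) from exc
    valid = []
    for s in sentences:
        if validate_tree(s):
            valid.append(s)
        else:
            logger.warning(
                "dropping sentence with invalid dependency tree: %r", s.text[:80]
            )
    return valid


class GoldTreeBackend:
    """Backend serving hand-specified gold parses keyed by sentence text.

    Used wherever parses are known in advance (synthetic corpora, fixtures):
    ``annotate`` segments the input by greedily matching known sentence texts
    left to right.  Unknown spans raise :class:`BackendError` so silent
    mis-segmentation cannot occur.
    """

    name = "gold"

    def __init__(self, sentences: Iterable[ParsedSentence]):
        self._by_text: dict[str, ParsedSentence] = {}
        for s in sentences:
            prev = self._by_text.get(s.text)
            if prev is not None and [t.head_index for t in prev.tokens] != [
                t.head_index for t in s.tokens
            ]:
                raise ValueError(
                    f"conflicting gold parses for identical text: {s.text!r}"
                )
            self._by_text.setdefault(s.text, s)
        # Index by a short prefix to keep greedy matching near-linear.
        self._by_prefix: dict[str, list[str]] = {}
        for text in self._by_text:
            self._by_prefix.setdefault(text[:12], []).append(text)
        for cands in self._by_prefix.values():
            cands.sort(key=len, reverse=True)  # longest match wins

    def annotate(self, text: str) -> List[ParsedSentence]:
        out: List[ParsedSentence] = []
        pos = 0
        n = len(text)
        while pos < n:
            while pos < n and text[pos] == " ":
                pos += 1
            if pos >= n:
                break
            for cand in self._by_prefix.get(text[pos : pos + 12], []):
                if text.startswith(cand, pos):
                    out.append(self._by_text[cand])
                    pos += len(cand)
                    break
            else:
                raise BackendError(
                    f"gold backend has no parse for text starting at "
                    f"{text[pos : pos + 60]!r}"
                )
        return out


class SpacyBackend:
    """Adapter for a spaCy/scispaCy pipeline, for real-corpus runs.

    Maps the parser's native labels onto the canonical scheme.  The spaCy
    dependency scheme (ClearNLP-derived) is already verb-headed with ``attr``
    complements, so the mapping is mostly renames.  Imported lazily so the
    package works without spaCy installed.
    """

    _LABEL_MAP = {
        "relcl": "relcl",
        "acl:relcl": "relcl",
        "nmod": "nmod",
        "prep": "nmod",  # spaCy attaches prepositional modifiers as prep/pobj
        "conj": "conj",
    }

    def __init__(self, model: str):
        try:
            import spacy  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise BackendError(
                f"spaCy is not installed; cannot load model {model!r}. "
                "Use the gold backend or install spacy+the model."
            ) from exc
        self._nlp = spacy.load(model)
        self.name = f"spacy:{model}"

    def annotate(self, text: str) -> List[ParsedSentence]:  # pragma: no cover
        doc = self._nlp(text)
        out = []
        for sent in doc.sents:
            offset = sent.start
            toks = [
                TokenAnnotation(
                    index=t.i - offset,
                    text=t.text,
                    lemma=t.lemma_.lower(),
                    pos=t.pos_,
                    dep_label=self._LABEL_MAP.get(t.dep_, t.dep_),
                    head_index=(t.i - offset if t.dep_ == "ROOT" else t.head.i - offset),
                )
                for t in sent
            ]
            out.append(ParsedSentence(tokens=toks, text=sent.text))
        return out


def load_backend(spec: str, **kwargs) -> ParserBackend:
    """Resolve a backend from a config key: ``"spacy:<model>"`` or ``"gold"``.

    The gold backend needs the parsed sentences passed as ``sentences=...``.
    """
    if spec == "gold":
        return GoldTreeBackend(kwargs["sentences"])
    if spec.startswith("spacy:"):
        return SpacyBackend(spec.split(":", 1)[1])
    raise ValueError(f"unknown parser backend {spec!r}")
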