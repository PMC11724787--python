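"""Synthetic corpus generator with gold dependency parses and bookkeeping.

Real full-text mining depends on a multi-million-article snapshot and a
pretrained statistical parser; neither is reproducible at desk scale.  This
module generates corpora in which every property the pipeline is supposed to
have can be checked exactly:

* positive sentences instantiate the copular template in six surface variants
  (bare predicate, adjectival subject, nominal-modifier chain, coordinated
  predicate, trailing conjoined clause, relative clause), each shipping a
  hand-specified gold dependency tree and the exact predicate string the
  extractor must recover;
* negative sentences each violate exactly one template constraint (simile
  marker, missing subject determiner, missing post-copular determiner,
  non-copular verb, organ as object), verified structurally at generation
  time by direct token inspection — not by running the matcher, which would
  make downstream precision/recall tests circular;
* distractor sentences mention no organ at all;
* article metadata is skewed the way large open-access corpora are skewed:
  Zipf-weighted journals, a majority of recent (>= 2020) publication years,
  and positives placed predominantly in Introduction sections;
* predicate phrases are drawn from disjoint per-theme lexicons so cluster
  recovery is measurable against planted theme labels.

Gold trees are emitted by construction, never by a statistical parser, so
parser noise cannot leak into test oracles.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .annotation import ParsedSentence, TokenAnnotation
from .corpus_io import Article, Section, SourceKind, article_to_jats
from .matcher import CopularMatch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tree construction helpers
# ---------------------------------------------------------------------------

def _sentence(rows: Sequence[Tuple], article_id: str = "",
              section_title: str = "") -> ParsedSentence:
    """Build a ParsedSentence from (text, pos, dep, head[, lemma]) rows."""
    tokens = []
    for i, row in enumerate(rows):
        text, pos, dep, head = row[:4]
        lemma = row[4] if len(row) > 4 else text.lower()
        tokens.append(TokenAnnotation(
            index=i, text=text, lemma=lemma, pos=pos,
            dep_label=dep, head_index=head,
        ))
    s = ParsedSentence(tokens=tokens, text="", article_id=article_id,
                       section_title=section_title)
    s.text = s.span_text(0, len(tokens) - 1)
    return s


# ---------------------------------------------------------------------------
# Themes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThemeSpec:
    """One planted semantic theme: disjoint lexicons for predicate content."""

    name: str
    modifiers: Tuple[str, ...]
    nouns: Tuple[str, ...]
    complements: Tuple[str, ...]  # objects of "of ..." / relative clauses
    verb: str = "involves"
    target_count: Optional[int] = None


def default_themes() -> Tuple[ThemeSpec, ...]:
    """Eight themes echoing recurring ways organs are characterized in the
    literature (energy demand, networks, computation, regulation, complexity,
    tissue composition, immune privilege, metastatic involvement), with
    pairwise-disjoint content lexicons."""
    return (
        ThemeSpec("energy", ("metabolic", "energetic", "expensive"),
                  ("consumer", "powerhouse", "engine"),
                  ("energy", "glucose", "oxygen"), "consumes"),
        ThemeSpec("network", ("distributed", "interconnected", "modular"),
                  ("network", "graph", "web"),
                  ("signals", "connections", "pathways"), "routes"),
        ThemeSpec("computation", ("computational", "predictive", "algorithmic"),
                  ("computer", "processor", "machine"),
                  ("information", "predictions", "inputs"), "computes"),
        ThemeSpec("regulation", ("homeostatic", "hormonal", "adaptive"),
                  ("regulator", "controller", "gatekeeper"),
                  ("stress", "hormones", "balance"), "regulates"),
        ThemeSpec("complexity", ("complex", "dynamic", "nonlinear"),
                  ("system", "structure", "entity"),
                  ("interactions", "dynamics", "feedback"), "exhibits"),
        ThemeSpec("tissue", ("lipid", "vascular", "cellular"),
                  ("reservoir", "depot", "matrix"),
                  ("lipids", "vessels", "cells"), "stores"),
        ThemeSpec("immunity", ("immune", "privileged", "protected"),
                  ("sanctuary", "fortress", "barrier"),
                  ("pathogens", "antibodies", "defenses"), "shields"),
        ThemeSpec("metastasis", ("frequent", "common", "vulnerable"),
                  ("site", "target", "destination"),
                  ("metastases", "tumors", "lesions"), "attracts"),
    )


# ---------------------------------------------------------------------------
# Sentence templates
# ---------------------------------------------------------------------------

POSITIVE_TEMPLATES = (
    "pos_bare",
    "pos_adj_subject",
    "pos_nmod_chain",
    "pos_coordination",
    "pos_trailing_clause",
    "pos_relative_clause",
)

NEGATIVE_TEMPLATES = (
    "neg_simile",
    "neg_no_det1",
    "neg_no_det2",
    "neg_noncopular",
    "neg_organ_object",
)

_SUBJECT_ADJECTIVES = ("human", "mammalian", "adult", "healthy")


def _instantiate_positive(template_id: str, organ: str, theme: ThemeSpec,
                          rng: random.Random) -> Tuple[ParsedSentence, str]:
    """Build one positive sentence; returns (sentence, expected predicate)."""
    mod = rng.choice(theme.modifiers)
    noun = rng.choice(theme.nouns)
    noun2 = rng.choice([n for n in theme.nouns if n != noun] or [noun])
    comp = rng.choice(theme.complements)

    if template_id == "pos_bare":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("is", "AUX", "ROOT", 2), ("a", "DET", "det", 4),
            (noun, "NOUN", "attr", 2), (".", "PUNCT", "punct", 2),
        ]
        expected = f"a {noun}"
    elif template_id == "pos_adj_subject":
        sadj = rng.choice(_SUBJECT_ADJECTIVES)
        rows = [
            ("The", "DET", "det", 2), (sadj, "ADJ", "amod", 2),
            (organ, "NOUN", "nsubj", 3), ("is", "AUX", "ROOT", 3),
            ("a", "DET", "det", 6), (mod, "ADJ", "amod", 6),
            (noun, "NOUN", "attr", 3), (".", "PUNCT", "punct", 3),
        ]
        expected = f"a {mod} {noun}"
    elif template_id == "pos_nmod_chain":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("is", "AUX", "ROOT", 2), ("the", "DET", "det", 5),
            (mod, "ADJ", "amod", 5), (noun, "NOUN", "attr", 2),
            ("of", "ADP", "case", 7), (comp, "NOUN", "nmod", 5),
            (".", "PUNCT", "punct", 2),
        ]
        expected = f"the {mod} {noun} of {comp}"
    elif template_id == "pos_coordination":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("is", "AUX", "ROOT", 2), ("a", "DET", "det", 4),
            (noun, "NOUN", "attr", 2), ("and", "CCONJ", "cc", 4),
            ("a", "DET", "det", 7), (noun2, "NOUN", "conj", 4),
            (".", "PUNCT", "punct", 2),
        ]
        expected = f"a {noun} and a {noun2}"
    elif template_id == "pos_trailing_clause":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("is", "AUX", "ROOT", 2), ("a", "DET", "det", 5),
            (mod, "ADJ", "amod", 5), (noun, "NOUN", "attr", 2),
            (",", "PUNCT", "punct", 9), ("and", "CCONJ", "cc", 9),
            ("this", "PRON", "nsubj", 9), ("is", "AUX", "conj", 5),
            ("the", "DET", "det", 11), (comp, "NOUN", "attr", 9),
            ("for", "ADP", "case", 14), ("the", "DET", "det", 14),
            ("analysis", "NOUN", "nmod", 11), (".", "PUNCT", "punct", 2),
        ]
        expected = f"a {mod} {noun}"
    elif template_id == "pos_relative_clause":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("is", "AUX", "ROOT", 2), ("an", "DET", "det", 4),
            ("organ", "NOUN", "attr", 2), ("that", "PRON", "nsubj", 6),
            (theme.verb, "VERB", "relcl", 4), (comp, "NOUN", "obj", 6),
            (".", "PUNCT", "punct", 2),
        ]
        expected = f"an organ that {theme.verb} {comp}"
    else:
        raise ValueError(f"unknown positive template {template_id!r}")
    return _sentence(rows), expected


def _instantiate_negative(template_id: str, organ: str, theme: ThemeSpec,
                          rng: random.Random) -> ParsedSentence:
    mod = rng.choice(theme.modifiers)
    noun = rng.choice(theme.nouns)
    if template_id == "neg_simile":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("is", "AUX", "ROOT", 2), ("like", "ADP", "case", 5),
            ("a", "DET", "det", 5), (noun, "NOUN", "nmod", 2),
            (".", "PUNCT", "punct", 2),
        ]
    elif template_id == "neg_no_det1":
        rows = [
            (organ.capitalize(), "NOUN", "nsubj", 1, organ),
            ("is", "AUX", "ROOT", 1), ("a", "DET", "det", 3),
            (noun, "NOUN", "attr", 1), (".", "PUNCT", "punct", 1),
        ]
    elif template_id == "neg_no_det2":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("is", "AUX", "ROOT", 2), ("remarkably", "ADV", "advmod", 4),
            (mod, "ADJ", "acomp", 2), (".", "PUNCT", "punct", 2),
        ]
    elif template_id == "neg_noncopular":
        rows = [
            ("The", "DET", "det", 1), (organ, "NOUN", "nsubj", 2),
            ("has", "VERB", "ROOT", 2, "have"), ("a", "DET", "det", 4),
            (noun, "NOUN", "obj", 2), (".", "PUNCT", "punct", 2),
        ]
    elif template_id == "neg_organ_object":
        rows = [
            ("We", "PRON", "nsubj", 1, "we"),
            ("studied", "VERB", "ROOT", 1, "study"),
            ("the", "DET", "det", 3), (organ, "NOUN", "obj", 1),
            ("carefully", "ADV", "advmod", 1), (".", "PUNCT", "punct", 1),
        ]
    else:
        raise ValueError(f"unknown negative template {template_id!r}")
    return _sentence(rows)


_DISTRACTOR_ROWS = (
    [("Samples", "NOUN", "nsubj", 2, "sample"), ("were", "AUX", "aux", 2),
     ("collected", "VERB", "ROOT", 2, "collect"), ("for", "ADP", "case", 4),
     ("analysis", "NOUN", "nmod", 2), (".", "PUNCT", "punct", 2)],
    [("These", "DET", "det", 1, "these"), ("results", "NOUN", "nsubj", 2, "result"),
     ("are", "AUX", "ROOT", 2, "be"), ("consistent", "ADJ", "acomp", 2),
     ("with", "ADP", "case", 6), ("previous", "ADJ", "amod", 6),
     ("work", "NOUN", "nmod", 3), (".", "PUNCT", "punct", 2)],
    [("Further", "ADJ", "amod", 1), ("research", "NOUN", "nsubj", 3),
     ("is", "AUX", "aux", 3), ("needed", "VERB", "ROOT", 3, "need"),
     ("in", "ADP", "case", 6), ("this", "DET", "det", 6, "this"),
     ("area", "NOUN", "nmod", 3), (".", "PUNCT", "punct", 3)],
)


def _distractor(rng: random.Random) -> ParsedSentence:
    return _sentence(rng.choice(_DISTRACTOR_ROWS))


# ---------------------------------------------------------------------------
# Structural single-violation verification (matcher-independent)
# ---------------------------------------------------------------------------

_DETERMINERS = {"the", "a", "an"}
_ORGAN_LEMMAS = {"brain", "lung", "pancreas", "stomach", "liver", "kidney",
                 "heart"}

#: Which template constraint each negative template is designed to break.
_NEGATIVE_VIOLATION = {
    "neg_simile": "det2_adjacent",
    "neg_no_det1": "det1_present",
    "neg_no_det2": "det2_adjacent",
    "neg_noncopular": "copula_is",
    "neg_organ_object": "organ_nsubj",
}


def _template_constraints(sentence: ParsedSentence) -> Dict[str, bool]:
    """Evaluate the template's constraints by direct token inspection.

    Independent of the matcher implementation on purpose: these checks keep
    generation-time validation from guaranteeing matcher test outcomes.
    """
    toks = sentence.tokens
    organ_positions = [t.index for t in toks if t.lemma in _ORGAN_LEMMAS]
    out = {
        "organ_present": bool(organ_positions),
        "organ_nsubj": False,
        "copula_is": False,
        "det1_present": False,
        "det2_adjacent": False,
    }
    for i in organ_positions:
        nsubj = toks[i].dep_label == "nsubj"
        copula = i + 1 < len(toks) and toks[i + 1].text.lower() == "is" \
            and toks[i].head_index == i + 1
        det1 = i >= 1 and toks[i - 1].text.lower() in _DETERMINERS
        det2 = i + 2 < len(toks) and toks[i + 2].text.lower() in _DETERMINERS
        out["organ_nsubj"] = out["organ_nsubj"] or nsubj
        out["copula_is"] = out["copula_is"] or (nsubj and copula)
        out["det1_present"] = out["det1_present"] or (nsubj and det1)
        out["det2_adjacent"] = out["det2_adjacent"] or (nsubj and copula and det2)
    return out


def _verify_negative(template_id: str, sentence: ParsedSentence) -> None:
    """Assert the negative instance violates exactly its declared constraint."""
    c = _template_constraints(sentence)
    violated = _NEGATIVE_VIOLATION[template_id]
    if c[violated]:
        raise AssertionError(
            f"{template_id}: constraint {violated!r} unexpectedly satisfied "
            f"in {sentence.text!r}"
        )
    # All constraints upstream of the violated one must still hold, so the
    # instance differs from a valid positive by that single constraint.
    order = ["organ_present", "organ_nsubj", "copula_is", "det1_present",
             "det2_adjacent"]
    for name in order[: order.index(violated)]:
        if not c[name]:
            raise AssertionError(
                f"{template_id}: prerequisite {name!r} not satisfied "
                f"in {sentence.text!r}"
            )


# ---------------------------------------------------------------------------
# Corpus specification and generation
# ---------------------------------------------------------------------------

DEFAULT_JOURNALS = (
    "PLoS ONE",
    "International Journal of Molecular Sciences",
    "Frontiers in Neuroscience",
    "Scientific Reports",
    "NeuroImage",
    "Cancers",
    "Journal of Physiology",
    "Brain and Behavior",
)

_POSITIVE_SECTION_WEIGHTS = (
    ("Introduction", 0.54),
    ("Discussion", 0.22),
    ("Abstract", 0.16),
    ("Results", 0.04),
    ("Methods", 0.04),
)

_OTHER_SECTIONS = ("Introduction", "Methods", "Results", "Discussion",
                   "Acknowledgements", "Supplementary notes")

_SECTION_ORDER = ("Abstract", "Introduction", "Methods", "Results",
                  "Discussion", "Acknowledgements", "Supplementary notes")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corpus.

    Defaults emulate the statistical structure of a large open-access corpus
    slice: Zipf-skewed journal representation, ~56% of dated articles from
    2020 onward, positives placed mostly in Introduction sections, and a
    planted-theme structure over predicate phrases.
    """

    n_articles: int = 200
    organs: Tuple[str, ...] = ("brain", "heart", "lung", "kidney", "liver",
                               "pancreas", "stomach")
    journals: Tuple[str, ...] = DEFAULT_JOURNALS
    year_range: Tuple[int, int] = (1995, 2023)
    frac_recent: float = 0.56  # share of dated articles with year >= 2020
    unknown_year_rate: float = 0.05
    themes: Tuple[ThemeSpec, ...] = field(default_factory=default_themes)
    positive_templates: Tuple[str, ...] = POSITIVE_TEMPLATES
    negative_templates: Tuple[str, ...] = NEGATIVE_TEMPLATES
    n_positives: int = 220
    n_negatives: int = 220
    distractor_rate: float = 0.25
    n_organ_free_articles: int = 20
    random_seed: int = 0

    def __post_init__(self):
        if not self.positive_templates or not self.negative_templates:
            raise ValueError("template lists must be nonempty")
        if not (0.0 <= self.distractor_rate < 1.0):
            raise ValueError("distractor_rate must be in [0, 1)")
        if not (0.0 <= self.frac_recent <= 1.0):
            raise ValueError("frac_recent must be a probability")
        explicit = [t.target_count for t in self.themes
                    if t.target_count is not None]
        if any(c < 1 for c in explicit):
            raise ValueError("theme target counts must be >= 1")
        if sum(explicit) > self.n_positives:
            raise ValueError(
                f"theme target counts sum to {sum(explicit)} but only "
                f"{self.n_positives} positive sentences are budgeted"
            )


@dataclass(frozen=True)
class GoldRecord:
    """Gold bookkeeping for one generated sentence."""

    article_id: str
    sentence_id: str
    sentence_text: str
    is_positive: bool
    expected_expression_text: Optional[str]
    theme: Optional[str]
    template_id: str
    organ: Optional[str]
    section_title: str

    def __post_init__(self):
        if self.is_positive != (self.expected_expression_text is not None):
            raise ValueError(
                "is_positive must coincide with expected_expression_text "
                "being present"
            )


def _theme_quotas(spec: SyntheticSpec) -> List[int]:
    quotas = [t.target_count for t in spec.themes]
    n_free = quotas.count(None)
    remaining = spec.n_positives - sum(q for q in quotas if q is not None)
    if n_free:
        base, extra = divmod(remaining, n_free)
        j = 0
        for i, q in enumerate(quotas):
            if q is None:
                quotas[i] = base + (1 if j < extra else 0)
                j += 1
    elif remaining:
        # explicit quotas under budget: cycle themes for the remainder
        for i in range(remaining):
            quotas[i % len(quotas)] += 1
    return quotas  # type: ignore[return-value]


def _sample_year(spec: SyntheticSpec, rng: random.Random) -> Optional[int]:
    if rng.random() < spec.unknown_year_rate:
        return None
    lo, hi = spec.year_range
    if hi >= 2020 > lo and rng.random() < spec.frac_recent:
        return rng.randint(2020, hi)
    return rng.randint(lo, min(hi, 2019) if hi >= 2020 > lo else hi)


def _weighted_section(rng: random.Random) -> str:
    r = rng.random()
    acc = 0.0
    for title, w in _POSITIVE_SECTION_WEIGHTS:
        acc += w
        if r < acc:
            return title
    return _POSITIVE_SECTION_WEIGHTS[-1][0]


def generate_corpus(
    spec: SyntheticSpec,
) -> Tuple[List[Article], List[GoldRecord], List[ParsedSentence]]:
    """Generate (articles, gold records, gold parses), deterministically.

    Every sentence — positive, negative, distractor — ships its gold tree in
    the returned parse list, with provenance set to its article and section.
    """
    rng = random.Random(spec.random_seed)
    quotas = _theme_quotas(spec)

    # --- sentence instances -------------------------------------------------
    # each entry: (sentence, is_positive, expected, theme, template_id, organ)
    planted: List[Tuple[ParsedSentence, bool, Optional[str], Optional[str],
                        str, Optional[str]]] = []
    for theme, quota in zip(spec.themes, quotas):
        for k in range(quota):
            template_id = spec.positive_templates[k % len(spec.positive_templates)]
            organ = rng.choice(spec.organs)
            sentence, expected = _instantiate_positive(template_id, organ,
                                                       theme, rng)
            planted.append((sentence, True, expected, theme.name,
                            template_id, organ))
    for k in range(spec.n_negatives):
        template_id = spec.negative_templates[k % len(spec.negative_templates)]
        organ = rng.choice(spec.organs)
        theme = rng.choice(spec.themes)
        sentence = _instantiate_negative(template_id, organ, theme, rng)
        _verify_negative(template_id, sentence)
        planted.append((sentence, False, None, None, template_id, organ))
    rng.shuffle(planted)

    n_planted = len(planted)
    if spec.distractor_rate > 0:
        n_distractors = round(
            spec.distractor_rate / (1 - spec.distractor_rate) * n_planted
        )
    else:
        n_distractors = 0
    for _ in range(n_distractors):
        planted.append((_distractor(rng), False, None, None, "distractor", None))

    # --- article assembly ---------------------------------------------------
    n_regular = spec.n_articles - spec.n_organ_free_articles
    if n_regular < 1 or len(planted) < n_regular:
        raise ValueError(
            f"{len(planted)} sentences cannot fill {n_regular} organ-bearing "
            f"articles; reduce n_articles or raise the sentence budget"
        )
    journal_weights = [1.0 / (i + 1) for i in range(len(spec.journals))]

    articles: List[Article] = []
    gold: List[GoldRecord] = []
    parses: List[ParsedSentence] = []
    sentence_counter = 0

    def new_article(idx: int) -> Article:
        return Article(
            article_id=f"synth{idx:05d}",
            journal=rng.choices(spec.journals, weights=journal_weights)[0],
            year=_sample_year(spec, rng),
            source_kind=SourceKind.synthetic,
            sections=[],
        )

    # assign planted sentences to regular articles: one each, rest random
    assignment: List[List[int]] = [[] for _ in range(n_regular)]
    order = list(range(len(planted)))
    rng.shuffle(order)
    for j, sent_idx in enumerate(order):
        target = j if j < n_regular else rng.randrange(n_regular)
        assignment[target].append(sent_idx)

    for a_idx in range(n_regular):
        article = new_article(a_idx)
        per_section: Dict[str, List[str]] = {}
        for sent_idx in sorted(assignment[a_idx]):
            sentence, is_pos, expected, theme_name, template_id, organ = \
                planted[sent_idx]
            section_title = (_weighted_section(rng) if is_pos
                             else rng.choice(_OTHER_SECTIONS))
            sid = f"s{sentence_counter:05d}"
            sentence_counter += 1
            placed = ParsedSentence(
                tokens=sentence.tokens, text=sentence.text,
                article_id=article.article_id, section_title=section_title,
            )
            parses.append(placed)
            per_section.setdefault(section_title, []).append(sentence.text)
            gold.append(GoldRecord(
                article_id=article.article_id, sentence_id=sid,
                sentence_text=sentence.text, is_positive=is_pos,
                expected_expression_text=expected, theme=theme_name,
                template_id=template_id, organ=organ,
                section_title=section_title,
            ))
        for title in _SECTION_ORDER:
            if title in per_section:
                article.sections.append(
                    Section(title=title, text=" ".join(per_section[title]))
                )
        articles.append(article)

    for k in range(spec.n_organ_free_articles):
        article = new_article(n_regular + k)
        texts = []
        for _ in range(rng.randint(1, 3)):
            sentence = _distractor(rng)
            sid = f"s{sentence_counter:05d}"
            sentence_counter += 1
            placed = ParsedSentence(
                tokens=sentence.tokens, text=sentence.text,
                article_id=article.article_id, section_title="Methods",
            )
            parses.append(placed)
            texts.append(sentence.text)
            gold.append(GoldRecord(
                article_id=article.article_id, sentence_id=sid,
                sentence_text=sentence.text, is_positive=False,
                expected_expression_text=None, theme=None,
                template_id="distractor", organ=None,
                section_title="Methods",
            ))
        article.sections.append(Section(title="Methods", text=" ".join(texts)))
        articles.append(article)

    return articles, gold, parses


# ---------------------------------------------------------------------------
# Embedding fixtures (planted themes for cluster-recovery tests)
# ---------------------------------------------------------------------------

def generate_embedding_fixture(
    themes: Sequence[ThemeSpec], per_theme: int, seed: int
) -> Tuple[List[str], List[int]]:
    """Phrase texts drawn from disjoint theme lexicons, plus gold theme labels.

    Warns (without failing) when theme lexicons overlap, since separation of
    the lexical embedding — and hence cluster recovery — is then not
    guaranteed.
    """
    for i, a in enumerate(themes):
        for b in themes[i + 1:]:
            shared = (set(a.modifiers) | set(a.nouns) | set(a.complements)) & \
                     (set(b.modifiers) | set(b.nouns) | set(b.complements))
            if shared:
                logger.warning(
                    "themes %s and %s share lexicon entries %s; cluster "
                    "recovery is not guaranteed", a.name, b.name, sorted(shared)
                )
    rng = random.Random(seed)
    texts: List[str] = []
    labels: List[int] = []
    forms = ("det_mod_noun", "det_mod_noun_of", "det_mod_and_mod_noun")
    for label, theme in enumerate(themes):
        for _ in range(per_theme):
            det = rng.choice(("a", "the"))
            mod = rng.choice(theme.modifiers)
            noun = rng.choice(theme.nouns)
            form = rng.choice(forms)
            if form == "det_mod_noun":
                text = f"{det} {mod} {noun}"
            elif form == "det_mod_noun_of":
                text = f"{det} {mod} {noun} of {rng.choice(theme.complements)}"
            else:
                mod2 = rng.choice([m for m in theme.modifiers if m != mod]
                                  or [mod])
                text = f"{det} {mod} and {mod2} {noun}"
            texts.append(text)
            labels.append(label)
    return texts, labels


# ---------------------------------------------------------------------------
# Fixture sentences with hand-checked trees
# ---------------------------------------------------------------------------

def worked_example() -> Tuple[ParsedSentence, CopularMatch, str]:
    """The canonical trailing-clause sentence, its match, and the expected
    predicate string ("a complex system")."""
    s = _sentence([
        ("The", "DET", "det", 1), ("brain", "NOUN", "nsubj", 2),
        ("is", "AUX", "ROOT", 2), ("a", "DET", "det", 5),
        ("complex", "ADJ", "amod", 5), ("system", "NOUN", "attr", 2),
        (",", "PUNCT", "punct", 9), ("and", "CCONJ", "cc", 9),
        ("this", "PRON", "nsubj", 9), ("is", "AUX", "conj", 5),
        ("the", "DET", "det", 11), ("inspiration", "NOUN", "attr", 9),
        ("for", "ADP", "case", 14), ("our", "DET", "det", 14),
        ("analysis", "NOUN", "nmod", 11), ("in", "ADP", "case", 17),
        ("the", "DET", "det", 17), ("manuscript", "NOUN", "nmod", 14),
        (".", "PUNCT", "punct", 2),
    ])
    match = CopularMatch(sentence=s, det1_index=0, adjective_index=None,
                         organ_index=1, copula_index=2, det2_index=3,
                         organ="brain")
    return s, match, "a complex system"


def fixture_sentences() -> List[Tuple[ParsedSentence, Optional[str]]]:
    """Hand-parsed sentences with their expected predicate strings
    (None = the template must not match)."""
    fixtures: List[Tuple[ParsedSentence, Optional[str]]] = []

    s, _, expected = worked_example()
    fixtures.append((s, expected))

    fixtures.append((_sentence([
        ("the", "DET", "det", 1), ("brain", "NOUN", "nsubj", 2),
        ("is", "AUX", "ROOT", 2), ("a", "DET", "det", 5),
        ("complex", "ADJ", "amod", 5), ("computer", "NOUN", "attr", 2),
        (".", "PUNCT", "punct", 2),
    ]), "a complex computer"))

    fixtures.append((_sentence([
        ("The", "DET", "det", 1), ("brain", "NOUN", "nsubj", 2),
        ("is", "AUX", "ROOT", 2), ("a", "DET", "det", 4),
        ("network", "NOUN", "attr", 2), (".", "PUNCT", "punct", 2),
    ]), "a network"))

    fixtures.append((_sentence([
        ("The", "DET", "det", 1), ("brain", "NOUN", "nsubj", 2),
        ("is", "AUX", "ROOT", 2), ("the", "DET", "det", 5),
        ("key", "ADJ", "amod", 5), ("regulator", "NOUN", "attr", 2),
        ("of", "ADP", "case", 7), ("stress", "NOUN", "nmod", 5),
        (".", "PUNCT", "punct", 2),
    ]), "the key regulator of stress"))

    fixtures.append((_sentence([
        ("the", "DET", "det", 1), ("heart", "NOUN", "nsubj", 2),
        ("is", "AUX", "ROOT", 2), ("a", "DET", "det", 5),
        ("muscular", "ADJ", "amod", 5), ("pump", "NOUN", "attr", 2),
        (".", "PUNCT", "punct", 2),
    ]), "a muscular pump"))

    fixtures.append((_sentence([
        ("The", "DET", "det", 2), ("human", "ADJ", "amod", 2),
        ("brain", "NOUN", "nsubj", 3), ("is", "AUX", "ROOT", 3),
        ("a", "DET", "det", 6), ("predictive", "ADJ", "amod", 6),
        ("organ", "NOUN", "attr", 3), (".", "PUNCT", "punct", 3),
    ]), "a predictive organ"))

    # simile: comparison marker between copula and determiner
    fixtures.append((_sentence([
        ("The", "DET", "det", 1), ("brain", "NOUN", "nsubj", 2),
        ("is", "AUX", "ROOT", 2), ("like", "ADP", "case", 5),
        ("a", "DET", "det", 5), ("computer", "NOUN", "nmod", 2),
        (".", "PUNCT", "punct", 2),
    ]), None))

    # no determiner before the subject
    fixtures.append((_sentence([
        ("Brain", "NOUN", "nsubj", 1, "brain"), ("is", "AUX", "ROOT", 1),
        ("a", "DET", "det", 4), ("region", "NOUN", "compound", 4),
        ("label", "NOUN", "attr", 1), (".", "PUNCT", "punct", 1),
    ]), None))

    # no determiner after the copula
    fixtures.append((_sentence([
        ("The", "DET", "det", 1), ("brain", "NOUN", "nsubj", 2),
        ("is", "AUX", "ROOT", 2), ("remarkably", "ADV", "advmod", 4),
        ("efficient", "ADJ", "acomp", 2), (".", "PUNCT", "punct", 2),
    ]), None))

    return fixtures


# ---------------------------------------------------------------------------
# Random valid trees for extractor equivalence testing
# ---------------------------------------------------------------------------

_RAND_NOUNS = ("system", "network", "organ", "regulator", "machine", "pump",
               "structure", "matrix", "hub", "engine")
_RAND_ADJS = ("complex", "dynamic", "muscular", "plastic", "adaptive",
              "metabolic", "predictive", "vascular")
_RAND_VERBS = ("contains", "supports", "regulates", "drives")


def _append_np(rows: List[list], rng: random.Random, head: int, dep: str,
               depth: int, with_det: bool = True) -> int:
    """Append a noun phrase to ``rows``; returns the index of its head noun.

    Recursively decorates the noun with nominal modifiers, (possibly verbal)
    conjuncts, or relative clauses, always to the right.
    """
    if with_det and rng.random() < 0.9:
        det_idx = len(rows)
        rows.append([rng.choice(("the", "a", "an")), "DET", "det", None])
    else:
        det_idx = None
    amods = []
    for _ in range(rng.randrange(3)):
        amods.append(len(rows))
        rows.append([rng.choice(_RAND_ADJS), "ADJ", "amod", None])
    noun_idx = len(rows)
    rows.append([rng.choice(_RAND_NOUNS), "NOUN", dep, head])
    if det_idx is not None:
        rows[det_idx][3] = noun_idx
    for a in amods:
        rows[a][3] = noun_idx

    if depth >= 3:
        return noun_idx
    decoration = rng.random()
    if decoration < 0.30:  # nominal modifier: "of <np>"
        case_idx = len(rows)
        rows.append(["of", "ADP", "case", None])
        child = _append_np(rows, rng, noun_idx, "nmod", depth + 1,
                           with_det=rng.random() < 0.5)
        rows[case_idx][3] = child
    elif decoration < 0.50:  # nominal conjunct: "and <np>"
        cc_idx = len(rows)
        rows.append(["and", "CCONJ", "cc", None])
        child = _append_np(rows, rng, noun_idx, "conj", depth + 1,
                           with_det=rng.random() < 0.7)
        rows[cc_idx][3] = child
    elif decoration < 0.60:  # verbal conjunct: a trailing clause
        rows.append([",", "PUNCT", "punct", None])
        punct_idx = len(rows) - 1
        rows.append(["and", "CCONJ", "cc", None])
        cc_idx = len(rows) - 1
        rows.append(["it", "PRON", "nsubj", None])
        pron_idx = len(rows) - 1
        verb_idx = len(rows)
        rows.append(["is", "AUX", "conj", noun_idx])
        rows[punct_idx][3] = verb_idx
        rows[cc_idx][3] = verb_idx
        rows[pron_idx][3] = verb_idx
        _append_np(rows, rng, verb_idx, "attr", depth + 1)
    elif decoration < 0.80:  # relative clause: "that <verb> <np>"
        pron_idx = len(rows)
        rows.append(["that", "PRON", "nsubj", None])
        verb_idx = len(rows)
        rows.append([rng.choice(_RAND_VERBS), "VERB", "relcl", noun_idx])
        rows[pron_idx][3] = verb_idx
        _append_np(rows, rng, verb_idx, "obj", depth + 1,
                   with_det=rng.random() < 0.5)
    return noun_idx


def random_match_tree(rng: random.Random) -> Tuple[ParsedSentence, CopularMatch]:
    """One random valid copular sentence tree plus its match object."""
    organ = rng.choice(("brain", "heart", "lung", "kidney", "liver",
                        "pancreas", "stomach"))
    rows: List[list] = [
        ["The", "DET", "det", 1],
        [organ, "NOUN", "nsubj", 2],
        ["is", "AUX", "ROOT", 2],
    ]
    # the top-level predicate always starts with a determiner at index 3
    det_idx = len(rows)
    rows.append([rng.choice(("the", "a", "an")), "DET", "det", None])
    amods = []
    for _ in range(rng.randrange(3)):
        amods.append(len(rows))
        rows.append([rng.choice(_RAND_ADJS), "ADJ", "amod", None])
    noun_idx = len(rows)
    rows.append([rng.choice(_RAND_NOUNS), "NOUN", "attr", 2])
    rows[det_idx][3] = noun_idx
    for a in amods:
        rows[a][3] = noun_idx
    decoration = rng.random()
    if decoration < 0.35:
        case_idx = len(rows)
        rows.append(["of", "ADP", "case", None])
        child = _append_np(rows, rng, noun_idx, "nmod", 1,
                           with_det=rng.random() < 0.5)
        rows[case_idx][3] = child
    elif decoration < 0.60:
        cc_idx = len(rows)
        rows.append(["and", "CCONJ", "cc", None])
        child = _append_np(rows, rng, noun_idx, "conj", 1)
        rows[cc_idx][3] = child
    elif decoration < 0.75:
        rows.append([",", "PUNCT", "punct", None])
        punct_idx = len(rows) - 1
        rows.append(["and", "CCONJ", "cc", None])
        cc_idx = len(rows) - 1
        rows.append(["this", "PRON", "nsubj", None])
        pron_idx = len(rows) - 1
        verb_idx = len(rows)
        rows.append(["is", "AUX", "conj", noun_idx])
        rows[punct_idx][3] = verb_idx
        rows[cc_idx][3] = verb_idx
        rows[pron_idx][3] = verb_idx
        _append_np(rows, rng, verb_idx, "attr", 1)
    elif decoration < 0.90:
        pron_idx = len(rows)
        rows.append(["that", "PRON", "nsubj", None])
        verb_idx = len(rows)
        rows.append([rng.choice(_RAND_VERBS), "VERB", "relcl", noun_idx])
        rows[pron_idx][3] = verb_idx
        _append_np(rows, rng, verb_idx, "obj", 1, with_det=rng.random() < 0.5)
    rows.append([".", "PUNCT", "punct", 2])
    sentence = _sentence([tuple(r) for r in rows])
    match = CopularMatch(sentence=sentence, det1_index=0, adjective_index=None,
                         organ_index=1, copula_index=2, det2_index=3,
                         organ=organ)
    return sentence, match


# ---------------------------------------------------------------------------
# On-disk emission (JATS XML + gold JSONL), exercised by the analysis scripts
# ---------------------------------------------------------------------------

def write_corpus(articles: Sequence[Article], gold: Sequence[GoldRecord],
                 parses: Sequence[ParsedSentence], outdir: Path | str) -> None:
    outdir = Path(outdir)
    (outdir / "articles").mkdir(parents=True, exist_ok=True)
    for article in articles:
        path = outdir / "articles" / f"{article.article_id}.xml"
        path.write_text(article_to_jats(article), encoding="utf-8")
    with (outdir / "gold.jsonl").open("w", encoding="utf-8") as fh:
        for g in gold:
            fh.write(json.dumps(g.__dict__, ensure_ascii=False) + "\n")
    write_parses(parses, outdir / "parses.jsonl")


def write_parses(parses: Sequence[ParsedSentence], path: Path | str) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in parses:
            fh.write(json.dumps({
                "text": s.text,
                "article_id": s.article_id,
                "section_title": s.section_title,
                "tokens": [
                    {"i": t.index, "text": t.text, "lemma": t.lemma,
                     "pos": t.pos, "dep": t.dep_label, "head": t.head_index}
                    for t in s.tokens
                ],
            }, ensure_ascii=False) + "\n")


def read_parses(path: Path | str) -> List[ParsedSentence]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(ParsedSentence(
                tokens=[TokenAnnotation(
                    index=t["i"], text=t["text"], lemma=t["lemma"],
                    pos=t["pos"], dep_label=t["dep"], head_index=t["head"],
                ) for t in d["tokens"]],
                text=d["text"],
                article_id=d.get("article_id", ""),
                section_title=d.get("section_title", ""),
            ))
    return out


def read_gold(path: Path | str) -> List[GoldRecord]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(GoldRecord(**json.loads(line)))
    return out
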