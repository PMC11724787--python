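# Methods

`copmine` implements a literature-mining pipeline for *copular definitional
expressions*: sentences of the form "the ⟨organ⟩ is a/the ⟨noun phrase⟩",
where a copular verb links an organ (brain, heart, lung, kidney, liver,
pancreas, stomach) to a predicate that defines or characterizes it.  Such
expressions carry the metaphors, analogies and essential-property claims
scientists attach to organs ("the brain is a complex system", "the heart is
a muscular pump").  The pipeline detects them, extracts the complete
predicate noun phrase, embeds and clusters the phrases into semantic groups,
and tabulates their distribution over journals, section types and years.

## Pipeline model and assumptions

**Organ prefilter.**  Articles are first reduced to those containing at
least one token whose *lemma* is an organ name, case-insensitively.  Lemma
matching (not substring search) means "kidneys" matches via the lemma
"kidney" while "brainstem" — a single token with its own lemma — does not.
The filter optimizes recall; acronym collisions ("the BRAIN initiative")
are accepted as over-matches because the copular matcher downstream
disambiguates.  Synonyms ("cerebrum", "renal") are deliberately out of
scope: the survey is of the surface organ names.  All sections of an
article are searched, titles and abstracts included.

**Copular template.**  A match requires the surface sequence

    determiner (the/a/an) · [optional adjective] · organ · "is" · determiner

*and* the dependency-tree condition that the organ token is the nominal
subject (`nsubj`) of the clause headed by that copula.  Consequences of the
template:

* Similes are excluded structurally: in "the brain is like a computer" the
  comparison marker intervenes between the copula and the determiner.
  Negations and modals ("is not a", "may be a") fail the same adjacency
  test.  This is intended — similes assert similarity, not identity.
* The copula is "is" exactly, not "are"/"was", so plural subjects ("the
  lungs are…") are not captured.  The determiner set includes "an" (with a
  flag to disable it) because predicates such as "an energy demanding organ"
  require it.
* At most one adjectival token may sit between the determiner and the organ
  ("the human brain is…"), for all organs uniformly; a flag
  (`allow_subject_adjective`) turns this off.
* Matching is insensitive to casing of the surface text: the organ is
  matched on its lowercase lemma, copula and determiners on lowercased
  token text.

**Canonical dependency scheme.**  The matcher and extractor operate on a
fixed verb-headed label inventory (`nsubj`, `attr`, `det`, `amod`, `nmod`,
`case`, `conj`, `cc`, `relcl`, `punct`), documented in
`copmine.annotation`.  Any parser backend must map its native scheme onto
this one, which decouples the algorithm from any particular statistical
parser.  Tests never require a pretrained model: gold trees are emitted by
the synthetic generator by construction.  A lazy spaCy adapter is provided
for real-corpus runs.

**Predicate extraction.**  Given a match, the full predicate noun phrase is
recovered by a rightward traversal of the dependency tree:

1. initialize the frontier to the copula's immediate rightward children;
2. scan the frontier tokens for a dependent bearing a followed label —
   nominal modifier, conjunct, or relative-clause modifier, in that priority
   order (leftmost wins within a label);
3. if found, collect that token and its immediate rightward children, and
   repeat the scan from there; stop when no followed label remains or an
   iteration cap (default 50) is reached.

The rendered expression is the contiguous token span from the post-copular
determiner through the highest collected index, which picks up left-attached
material (determiners, adjectives) inside the phrase while trailing clauses
stay out; trailing punctuation is stripped.  Two guards are part of the
algorithm's definition here and are the package's own design choices:

* **Punctuation is never collected.**  In a verb-headed tree the
  sentence-final period hangs off the copula; collecting it would drag the
  rendered span to the end of the sentence.
* **Verbal conjuncts are not followed.**  A conjunct headed by a finite verb
  opens a new clause ("…, and this is the inspiration for our analysis"),
  not a coordinated noun phrase; following it would re-import exactly the
  irrelevant material the traversal exists to exclude.  Relative-clause
  dependents are verbal by nature and are followed regardless.

With these rules, "The brain is a complex system, and this is the
inspiration for our analysis in the manuscript" yields exactly "a complex
system", and "The brain is the key regulator of stress" follows the
nominal-modifier chain to yield the full "the key regulator of stress".

A structurally independent recursive implementation
(`extract_predicate_oracle`) ships alongside the frontier-loop
implementation solely for equivalence testing; the two are compared
string-for-string on every fixture and on ≥1,000 seeded random trees.

A match whose copula has no rightward non-punctuation children raises an
extraction failure; corpus pipelines log and drop it rather than abort,
modelling the expected leakage between detection and extraction at corpus
scale.

## Embedding, reduction, clustering

Expressions are embedded as vectors, reduced to two dimensions with UMAP,
and the *planar coordinates* are clustered with HDBSCAN.  Clustering the
2-D coordinates rather than the full embedding is a deliberate inherited
methodological choice and a known caveat: the reduction can distort
density, so cluster boundaries are properties of the reduced space.

Parameters that matter (defaults in parentheses):

| parameter | default | meaning |
|---|---|---|
| embedding dimension | 64 (stub) / 768 (transformer) | vector width |
| UMAP `n_neighbors` | 15 | neighborhood size of the k-NN graph |
| UMAP `min_dist` | 0 | lets same-meaning points collapse together |
| UMAP seed | explicit | reductions are reproducible by default |
| HDBSCAN `min_cluster_size` | 50 | smallest admissible cluster |
| `allow_single_cluster` | True | a lone dense group is one cluster, not noise |
| `cluster_selection_epsilon` | 0.3 | floor below which density splits are ignored |

Two embedding backends satisfy one contract.  The
`pretrained_transformer` backend targets a 768-dimensional
sentence-transformer trained on scientific semantic-similarity tasks; it is
loaded lazily and raises an explicit error when the library or weights are
unavailable — it is never substituted silently.  The
`deterministic_lexical_stub` backend, used by all tests and desk-scale
runs, is a hashed bag-of-tokens embedding defined bit-exactly: each
lowercased alphanumeric token adds ±1 (sign and slot from the MD5 digest of
the token) at index `md5(token) mod d`, each character trigram of tokens
longer than three characters adds ±0.3 at `md5("##"+gram) mod d`, and the
sum is L2-normalized.  It separates phrases by lexical overlap, which is
exactly what the disjoint-lexicon synthetic themes exercise.

Numerical choices for clustering: scikit-learn's HDBSCAN with
excess-of-mass selection discards the root of the cluster hierarchy, so a
dataset forming one coherent group would come back as pure noise;
`allow_single_cluster=True` restores it, and a small selection epsilon
(0.3) stops the root's fringe being eroded to noise.  Epsilon is expressed
in units of the reduced plane, where `min_dist=0` collapses within-group
distances toward zero and inter-group gaps are of order 1–10, so 0.3 never
merges distinct groups.  On small point sets (tens of points) the epsilon
floor can interact with single-cluster selection so that *no* candidate
survives; `density_cluster` then deterministically re-selects without the
floor.  Fewer points than `min_cluster_size` yield all-noise with a
warning.

Cluster triage is human: the package surfaces per-cluster sizes and
keyword lists (within-cluster term frequency weighted by smoothed inverse
document frequency, function words excluded, ties alphabetical) and applies
explicit merge instructions (`merge_clusters`), but it does not decide
which clusters are semantically coherent or what they mean.

## The synthetic corpus

The generator (`copmine.synthetic`) emulates the statistical structure of a
large open-access corpus slice so that every pipeline property is checkable
against planted truth:

* **Positives** instantiate the template in six variants: bare predicate,
  adjectival subject, nominal-modifier chain, coordinated predicate,
  trailing conjoined clause, relative clause.  Each carries a
  hand-specified gold tree and the exact predicate string to be recovered.
* **Negatives** each violate exactly one constraint (simile marker, missing
  subject determiner, missing post-copular determiner, non-copular verb,
  organ as object), verified at generation time by direct token inspection
  — deliberately *not* by running the matcher, so matcher tests stay
  non-circular.
* **Distractors** mention no organ.
* **Metadata skew**: Zipf-weighted journals, ~56% of dated articles ≥2020,
  5% unknown years, positives placed 54% in Introduction / 22% in
  Discussion / 16% in Abstract sections.
* **Themes**: predicate content words come from eight pairwise-disjoint
  lexicons (energy, network, computation, regulation, complexity, tissue,
  immunity, metastasis), so clustering recovery is measurable with the
  adjusted Rand index against planted labels.

Default study conditions: 200 articles, 220 positives, 220 negatives,
distractor rate 0.25, 20 organ-free articles, all driven by a single seed.
Embedding fixtures use 100 phrases per theme, matching the canonical
minimum cluster size of 50 with a 2× margin.

What the generator does *not* emulate — and therefore what passing tests do
not show about real corpora: statistical-parser errors, free grammatical
variation beyond the templates, plural copulas, OCR noise, section-title
diversity beyond a short list, and the long tail of JATS dialect drift.
Exactness results (precision/recall 1.0, exact string recovery) are
statements about the algorithmic contract on correct parses, not about
end-to-end accuracy on noisy text.

## Degenerate inputs and tie-breaks

* Sentences whose head links do not form a single rooted tree are dropped
  at ingestion with a warning.
* Overlapping template occurrences are resolved left to right,
  non-overlapping; scanning resumes after each match's second determiner.
* In the traversal, label priority is nominal modifier > conjunct >
  relative clause at every step; ties within a label go to the leftmost
  candidate.
* Section-title normalization is case-insensitive substring containment
  with first-hit priority in the canonical list (Abstract, Introduction,
  Results, Discussion, Methods, Conclusion) — "Results and Discussion"
  therefore maps to "Results"; everything else is "nonstandard".  The list
  is configurable.
* Year binning splits at 2020 with the boundary year in the upper bin;
  unknown years are excluded from year tables (their exclusion is this
  package's choice — no convention exists for them).

## Problem sizes

Desk-scale runs and the test suite use the default 200-article corpus
(~630 sentences), 1,000–2,000 random trees for the equivalence property,
and 300–800 points per clustering fixture.  These sizes are chosen so the
whole suite and the acceptance script each complete in well under half an
hour on one CPU while leaving every measured property at its asymptote
(all acceptance quantities sit at 1.0; the cluster ARI stays ≥0.98 across
seeds).

## Known limitations

* The traversal follows one dependent per step; a predicate with two
  parallel nominal modifiers keeps only the chain through the first.  The
  span rendering usually recovers the rest when indices are contiguous.
* Keyword lists are lexical; they support, and cannot replace, human
  labelling of cluster meaning, and the cross-organ overlap table is a
  keyword proxy for what is, in the underlying methodology, a judgment
  about meaning.
* The interface-level CLI is the set of numbered drivers under
  `analysis/`; the library functions are the stable API.
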