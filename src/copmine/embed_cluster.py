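"""Phrase embedding, planar reduction, density clustering, merging, keywords.

The pipeline mirrors standard practice for grouping short phrases by meaning:
embed each phrase as a vector, reduce to two dimensions with UMAP
(n_neighbors=15, min_dist=0 by default), then cluster the planar coordinates
with HDBSCAN (minimum cluster size 50 by default), labelling low-density
points as noise (-1).  Clustering operates on the 2-D coordinates, not the
full embedding — a deliberate methodological choice inherited by this
pipeline and flagged as a caveat in the package docs, since the reduction
can distort density.

Two embedding backends exist behind one contract:

* ``pretrained_transformer`` — a sentence-transformer trained on scientific
  semantic-similarity tasks (768-d).  Loaded lazily; if the library or the
  weights are unavailable an explicit error is raised telling the caller to
  fall back to the stub.  Never substituted silently.
* ``deterministic_lexical_stub`` — a download-free hashed bag-of-tokens
  embedding used by tests and desk-scale runs.  Documented bit-exactly below
  so oracle examples are stable.

Stub definition (dimension d, default 64): for each whitespace-separated,
lowercased, punctuation-stripped token, add a unit contribution at index
``md5(token) mod d`` with sign given by the next hash bit; additionally each
character trigram of the token contributes with weight 0.3 (sub-word
smoothing, so morphologically related tokens correlate).  The summed vector
is L2-normalized.  MD5 is used purely as a stable hash.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus_io import ExpressionRecord

logger = logging.getLogger(__name__)

NOISE_LABEL = -1


@dataclass(frozen=True)
class EmbeddingConfig:
    backend: str = "deterministic_lexical_stub"  # or "pretrained_transformer"
    dimension: int = 64  # 768 for the transformer backend
    subword_weight: float = 0.3
    transformer_model: str = "pritamdeka/S-Scibert-snli-multinli-stsb"

    def __post_init__(self):
        if self.dimension <= 0:
            raise ValueError("embedding dimension must be positive")


@dataclass(frozen=True)
class ReductionConfig:
    n_neighbors: int = 15
    min_dist: float = 0.0
    n_components: int = 2
    random_seed: int = 0

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be nonnegative")
        if self.n_components != 2:
            raise ValueError("this pipeline reduces to exactly 2 dimensions")


@dataclass(frozen=True)
class ClusterConfig:
    """Density-clustering parameters.

    ``allow_single_cluster`` lets a dataset that forms one coherent dense
    group come back as one cluster instead of all noise (the excess-of-mass
    selection otherwise discards the tree root).  On its own that selection
    still erodes a lone group's fringe into noise, so
    ``cluster_selection_epsilon`` sets a small distance floor below which
    density splits are ignored; 0.3 is small relative to the inter-group
    gaps the planar reduction produces (min_dist=0 collapses within-group
    distances toward zero) and so never merges distinct groups.
    """

    min_cluster_size: int = 50
    allow_single_cluster: bool = True
    cluster_selection_epsilon: float = 0.3

    def __post_init__(self):
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.cluster_selection_epsilon < 0:
            raise ValueError("cluster_selection_epsilon must be nonnegative")


@dataclass
class ClusterResult:
    """Planar coordinates and cluster labels for one set of expressions."""

    coordinates: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,), int; -1 = noise
    min_cluster_size: int
    merged_from: Optional[Dict[int, Tuple[int, ...]]] = None

    def __post_init__(self):
        if len(self.coordinates) != len(self.labels):
            raise ValueError("coordinates and labels must align")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {NOISE_LABEL})

    @property
    def noise_count(self) -> int:
        return int(np.sum(self.labels == NOISE_LABEL))

    def cluster_sizes(self) -> Dict[int, int]:
        sizes = Counter(int(l) for l in self.labels if l != NOISE_LABEL)
        return dict(sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0])))


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _hash_slot(key: str, dimension: int) -> Tuple[int, float]:
    digest = hashlib.md5(key.encode("utf-8")).digest()
    index = int.from_bytes(digest[:8], "big") % dimension
    sign = 1.0 if digest[8] & 1 else -1.0
    return index, sign


def _stub_vector(text: str, config: EmbeddingConfig) -> np.ndarray:
    vec = np.zeros(config.dimension, dtype=np.float64)
    for token in _TOKEN_RE.findall(text.lower()):
        idx, sign = _hash_slot(token, config.dimension)
        vec[idx] += sign
        if config.subword_weight and len(token) > 3:
            for i in range(len(token) - 2):
                gram = token[i : i + 3]
                idx, sign = _hash_slot("##" + gram, config.dimension)
                vec[idx] += sign * config.subword_weight
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def embed_expressions(
    texts: Sequence[str], config: EmbeddingConfig = EmbeddingConfig()
) -> np.ndarray:
    """One embedding row per text; identical texts yield identical rows."""
    if len(texts) == 0:
        raise ValueError("no texts to embed")
    for i, t in enumerate(texts):
        if not t or not t.strip():
            raise ValueError(f"text at position {i} is empty")
    if config.backend == "deterministic_lexical_stub":
        return np.vstack([_stub_vector(t, config) for t in texts])
    if config.backend == "pretrained_transformer":
        try:
            from sentence_transformers import SentenceTransformer  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "the pretrained_transformer embedding backend requires the "
                "sentence-transformers library and downloaded weights for "
                f"{config.transformer_model!r}; install them or switch the "
                "EmbeddingConfig backend to 'deterministic_lexical_stub'"
            ) from exc
        model = SentenceTransformer(config.transformer_model)  # pragma: no cover
        return np.asarray(model.encode(list(texts)))  # pragma: no cover
    raise ValueError(f"unknown embedding backend {config.backend!r}")


# ---------------------------------------------------------------------------
# Reduction and clustering
# ---------------------------------------------------------------------------

def reduce_to_plane(
    vectors: np.ndarray, config: ReductionConfig = ReductionConfig()
) -> np.ndarray:
    """UMAP the embedding matrix down to 2-D, reproducibly for a fixed seed."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2:
        raise ValueError("expected a 2-D embedding matrix")
    minimum = config.n_neighbors + 1
    if vectors.shape[0] < minimum:
        raise ValueError(
            f"reduction needs at least n_neighbors+1 = {minimum} rows, "
            f"got {vectors.shape[0]}"
        )
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        n_components=config.n_components,
        random_state=config.random_seed,
    )
    return np.asarray(reducer.fit_transform(vectors), dtype=np.float64)


def density_cluster(
    coordinates: np.ndarray, config: ClusterConfig = ClusterConfig()
) -> ClusterResult:
    """HDBSCAN over planar coordinates; points in no dense group get -1.

    Fewer points than ``min_cluster_size`` cannot form any cluster, so the
    result is all noise with a logged warning.
    """
    coordinates = np.asarray(coordinates, dtype=np.float64)
    n = coordinates.shape[0]
    if n < config.min_cluster_size:
        logger.warning(
            "only %d points for min_cluster_size=%d: labelling all as noise",
            n, config.min_cluster_size,
        )
        labels = np.full(n, NOISE_LABEL, dtype=int)
    else:
        from sklearn.cluster import HDBSCAN

        labels = HDBSCAN(
            min_cluster_size=config.min_cluster_size,
            allow_single_cluster=config.allow_single_cluster,
            cluster_selection_epsilon=config.cluster_selection_epsilon,
            copy=True,
        ).fit_predict(coordinates).astype(int)
        if (
            config.allow_single_cluster
            and config.cluster_selection_epsilon > 0
            and not (labels != NOISE_LABEL).any()
        ):
            # The epsilon floor can interact badly with single-cluster
            # selection on small point sets, discarding every candidate
            # cluster.  A configuration that allows a single cluster should
            # not return none when a denser-than-noise group exists, so
            # re-select without the floor.
            logger.info(
                "epsilon-filtered selection found no cluster among %d "
                "points; re-selecting without the epsilon floor", n
            )
            labels = HDBSCAN(
                min_cluster_size=config.min_cluster_size,
                allow_single_cluster=True,
                copy=True,
            ).fit_predict(coordinates).astype(int)
    result = ClusterResult(
        coordinates=coordinates,
        labels=labels,
        min_cluster_size=config.min_cluster_size,
    )
    logger.info("found %d clusters, %d noise points of %d",
                result.n_clusters, result.noise_count, n)
    return result


def merge_clusters(
    result: ClusterResult, merge_groups: Sequence[Set[int]]
) -> ClusterResult:
    """Manually merge cluster labels; each group collapses to its smallest label.

    Noise (-1) is not mergeable; groups must be disjoint and reference only
    existing labels.  Expression count and identity are untouched.
    """
    existing = set(result.labels.tolist())
    seen: Set[int] = set()
    for group in merge_groups:
        for label in group:
            if label == NOISE_LABEL:
                raise ValueError("the noise label -1 cannot be merged")
            if label not in existing:
                raise ValueError(f"unknown cluster label {label}")
            if label in seen:
                raise ValueError(f"label {label} appears in more than one group")
            seen.add(label)
    labels = result.labels.copy()
    merged_from = dict(result.merged_from or {})
    for group in merge_groups:
        if len(group) < 2:
            continue
        target = min(group)
        for label in group:
            labels[result.labels == label] = target
        merged_from[target] = tuple(sorted(group))
    return ClusterResult(
        coordinates=result.coordinates,
        labels=labels,
        min_cluster_size=result.min_cluster_size,
        merged_from=merged_from or None,
    )


# ---------------------------------------------------------------------------
# Keyword labelling aid
# ---------------------------------------------------------------------------

#: Function words excluded from keyword rankings.
KEYWORD_STOPWORDS = frozenset(
    {"a", "an", "the", "of", "and", "or", "that", "which", "is", "are",
     "for", "in", "to", "with", "its"}
)


def cluster_keywords(
    expressions: Sequence[ExpressionRecord] | Sequence[str],
    result: ClusterResult,
    top_k: int = 5,
) -> Dict[int, List[str]]:
    """Top tokens per cluster, ranked by within-cluster frequency weighted
    against corpus-wide document frequency (smoothed tf-idf); an aid for the
    manual labelling step, not a replacement for it.

    Deterministic: ties break alphabetically.
    """
    texts = [
        e.expression_text if isinstance(e, ExpressionRecord) else e
        for e in expressions
    ]
    if len(texts) != len(result.labels):
        raise ValueError("expressions and cluster labels must align")
    doc_freq: Counter = Counter()
    tokenized: List[List[str]] = []
    for text in texts:
        toks = [t for t in _TOKEN_RE.findall(text.lower())
                if t not in KEYWORD_STOPWORDS]
        tokenized.append(toks)
        doc_freq.update(set(toks))
    n_docs = len(texts)
    out: Dict[int, List[str]] = {}
    for label in sorted(set(result.labels.tolist()) - {NOISE_LABEL}):
        tf: Counter = Counter()
        for toks, lab in zip(tokenized, result.labels):
            if lab == label:
                tf.update(toks)
        scored = sorted(
            tf.items(),
            key=lambda kv: (
                -kv[1] * (math.log((1 + n_docs) / (1 + doc_freq[kv[0]])) + 1.0),
                kv[0],
            ),
        )
        out[int(label)] = [tok for tok, _ in scored[:top_k]]
    return out
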