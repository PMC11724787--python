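"""Stub embeddings, planar reduction, density clustering, merging, keywords."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from copmine.embed_cluster import (
    NOISE_LABEL,
    ClusterConfig,
    ClusterResult,
    EmbeddingConfig,
    ReductionConfig,
    cluster_keywords,
    density_cluster,
    embed_expressions,
    merge_clusters,
    reduce_to_plane,
)
from copmine.synthetic import default_themes, generate_embedding_fixture


# --- embedding --------------------------------------------------------------

def test_identical_texts_embed_identically():
    vecs = embed_expressions(["a complex system", "a network",
                              "a complex system"])
    assert np.array_equal(vecs[0], vecs[2])
    assert not np.array_equal(vecs[0], vecs[1])
    assert np.allclose(np.linalg.norm(vecs, axis=1), 1.0)


def test_lexical_overlap_orders_similarity():
    a, b, c = embed_expressions([
        "a complex network", "a complex system", "a lipid rich organ",
    ])
    assert a @ b > a @ c  # shared 'complex' beats no shared content word


def test_empty_inputs_are_rejected():
    with pytest.raises(ValueError):
        embed_expressions([])
    with pytest.raises(ValueError, match="position 1"):
        embed_expressions(["fine", "  "])


def test_transformer_backend_errors_instead_of_silently_substituting():
    config = EmbeddingConfig(backend="pretrained_transformer", dimension=768)
    with pytest.raises(RuntimeError, match="deterministic_lexical_stub"):
        embed_expressions(["a complex system"], config)


# --- reduction --------------------------------------------------------------

@pytest.fixture(scope="module")
def three_blob_fixture():
    texts, labels = generate_embedding_fixture(default_themes()[:3],
                                               per_theme=100, seed=3)
    vectors = embed_expressions(texts)
    coords = reduce_to_plane(vectors, ReductionConfig(random_seed=11))
    return np.array(labels), vectors, coords


def test_blob_centroids_separate_beyond_spread(three_blob_fixture):
    labels, _, coords = three_blob_fixture
    centroids = np.array([coords[labels == k].mean(axis=0) for k in range(3)])
    spreads = [
        np.linalg.norm(coords[labels == k] - centroids[k], axis=1).mean()
        for k in range(3)
    ]
    for i in range(3):
        for j in range(i + 1, 3):
            gap = np.linalg.norm(centroids[i] - centroids[j])
            assert gap > max(spreads[i], spreads[j])


def test_reduction_is_seed_deterministic(three_blob_fixture):
    _, vectors, coords = three_blob_fixture
    again = reduce_to_plane(vectors, ReductionConfig(random_seed=11))
    assert np.array_equal(coords, again)


def test_reduction_rejects_too_few_rows():
    with pytest.raises(ValueError, match="16"):
        reduce_to_plane(np.zeros((10, 8)), ReductionConfig(n_neighbors=15))


# --- clustering -------------------------------------------------------------

def _blobs(rng, centers, n_each, spread=0.05):
    pts = np.vstack([
        rng.normal(loc=c, scale=spread, size=(n_each, 2)) for c in centers
    ])
    gold = np.repeat(np.arange(len(centers)), n_each)
    return pts, gold


def test_planted_blobs_are_recovered():
    rng = np.random.default_rng(1)
    coords, gold = _blobs(rng, [(0, 0), (3, 0), (0, 3), (3, 3), (6, 1.5)], 100)
    result = density_cluster(coords, ClusterConfig(min_cluster_size=50))
    assert result.n_clusters == 5
    assert adjusted_rand_score(gold, result.labels) >= 0.9
    # every real cluster honors the minimum size
    assert all(v >= 50 for v in result.cluster_sizes().values())


def test_single_tight_blob_is_one_cluster():
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(200, 2), scale=0.1)
    result = density_cluster(coords, ClusterConfig(min_cluster_size=50))
    assert result.n_clusters == 1
    assert result.noise_count <= 0.05 * 200


def test_uniform_scatter_is_mostly_noise():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 100, size=(400, 2))
    result = density_cluster(coords, ClusterConfig(min_cluster_size=50))
    assert result.noise_count >= 0.5 * 400


def test_fewer_points_than_min_cluster_size_is_all_noise():
    coords = np.zeros((10, 2))
    result = density_cluster(coords, ClusterConfig(min_cluster_size=50))
    assert result.n_clusters == 0 and result.noise_count == 10


def test_noise_grows_monotonically_with_min_cluster_size():
    rng = np.random.default_rng(4)
    coords, _ = _blobs(rng, [(0, 0), (4, 0), (0, 4)], 60, spread=0.3)
    noise = [
        density_cluster(coords, ClusterConfig(min_cluster_size=m)).noise_count
        for m in (10, 30, 61)
    ]
    assert noise == sorted(noise)


# --- merging ----------------------------------------------------------------

@pytest.fixture()
def five_cluster_result():
    labels = np.repeat([0, 1, 2, 3, 4], 10)
    labels[:3] = NOISE_LABEL
    return ClusterResult(coordinates=np.zeros((50, 2)), labels=labels,
                         min_cluster_size=5)


def test_merge_conserves_counts(five_cluster_result):
    before = five_cluster_result
    merged = merge_clusters(before, [{2, 3}])
    assert merged.n_clusters == before.n_clusters - 1
    assert len(merged.labels) == len(before.labels)
    n_2 = int(np.sum(before.labels == 2))
    n_3 = int(np.sum(before.labels == 3))
    assert int(np.sum(merged.labels == 2)) == n_2 + n_3
    assert merged.merged_from == {2: (2, 3)}
    assert merged.noise_count == before.noise_count


def test_empty_merge_is_identity(five_cluster_result):
    merged = merge_clusters(five_cluster_result, [])
    assert np.array_equal(merged.labels, five_cluster_result.labels)


def test_merge_rejects_noise_unknown_and_overlap(five_cluster_result):
    with pytest.raises(ValueError, match="noise"):
        merge_clusters(five_cluster_result, [{NOISE_LABEL, 0}])
    with pytest.raises(ValueError, match="unknown"):
        merge_clusters(five_cluster_result, [{0, 99}])
    with pytest.raises(ValueError, match="more than one"):
        merge_clusters(five_cluster_result, [{0, 1}, {1, 2}])


# --- keyword aid ------------------------------------------------------------

def test_dominant_token_ranks_first():
    texts = ["an energy demanding organ", "an energy hungry organ",
             "the energy budget", "a quiet interlude", "a quiet pause"]
    labels = np.array([0, 0, 0, 1, 1])
    result = ClusterResult(np.zeros((5, 2)), labels, min_cluster_size=2)
    keywords = cluster_keywords(texts, result, top_k=3)
    assert keywords[0][0] == "energy"
    assert "quiet" in keywords[1][:2]


def test_disjoint_vocabularies_give_disjoint_keywords():
    texts = ["alpha beta gamma"] * 5 + ["delta epsilon zeta"] * 5
    labels = np.array([0] * 5 + [1] * 5)
    result = ClusterResult(np.zeros((10, 2)), labels, min_cluster_size=2)
    keywords = cluster_keywords(texts, result, top_k=3)
    assert set(keywords[0]).isdisjoint(keywords[1])


def test_theme_nouns_surface_in_their_clusters_keywords():
    themes = default_themes()[:4]
    texts, labels = generate_embedding_fixture(themes, per_theme=30, seed=9)
    labels = np.array(labels)
    result = ClusterResult(np.zeros((len(texts), 2)), labels,
                           min_cluster_size=10)
    keywords = cluster_keywords(texts, result, top_k=3)
    for k, theme in enumerate(themes):
        assert set(keywords[k]) & (set(theme.nouns) | set(theme.modifiers))
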