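"""Embed the extracted predicate phrases, reduce to two dimensions, cluster,
and pull keyword labels — pooled across organs and again per organ.

The pooled run uses a smaller minimum cluster size than the canonical 50
because the desk-scale corpus yields a few hundred expressions, not
thousands; the per-organ runs adjust it further down (mirroring how the
minimum cluster size is adapted per organ whenever the expression set
shrinks).  Organs with fewer expressions than the reducer's neighborhood
size are reported as unclustered.

Reads results/expressions.tsv (from 02_extract_expressions.py); writes
results/cluster_labels.tsv, results/cluster_summary.json and
results/per_organ_keywords.json.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

from copmine import (
    ClusterConfig,
    ReductionConfig,
    cluster_keywords,
    density_cluster,
    embed_expressions,
    read_expressions,
    reduce_to_plane,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--min-cluster-size", type=int, default=20)
    parser.add_argument("--per-organ-min-cluster-size", type=int, default=5)
    parser.add_argument("--per-organ-n-neighbors", type=int, default=8,
                        help="smaller UMAP neighborhood for the tens-sized "
                             "per-organ expression sets")
    args = parser.parse_args()

    results = ROOT / "results"
    records = read_expressions(results / "expressions.tsv")
    texts = [r.expression_text for r in records]
    reduction = ReductionConfig(random_seed=args.seed)

    # pooled clustering over every extracted expression
    coords = reduce_to_plane(embed_expressions(texts), reduction)
    pooled = density_cluster(
        coords, ClusterConfig(min_cluster_size=args.min_cluster_size)
    )
    keywords = cluster_keywords(records, pooled, top_k=5)

    with (results / "cluster_labels.tsv").open("w", encoding="utf-8") as fh:
        fh.write("expression_text\torgan\tx\ty\tcluster\n")
        for r, (x, y), label in zip(records, coords, pooled.labels):
            fh.write(f"{r.expression_text}\t{r.organ}\t{x:.6f}\t{y:.6f}\t"
                     f"{int(label)}\n")

    print(f"pooled: {len(records)} expressions -> {pooled.n_clusters} "
          f"clusters, {pooled.noise_count} noise points")
    for label, size in pooled.cluster_sizes().items():
        print(f"  cluster {label:>2} (N={size:>3}): "
              + ", ".join(keywords[label]))

    # per-organ clustering with an adjusted minimum cluster size
    per_organ_keywords = {}
    per_organ_counts = Counter(r.organ for r in records)
    organ_reduction = ReductionConfig(
        n_neighbors=args.per_organ_n_neighbors, random_seed=args.seed
    )
    for organ in sorted(per_organ_counts):
        organ_records = [r for r in records if r.organ == organ]
        if len(organ_records) < organ_reduction.n_neighbors + 1:
            print(f"{organ}: only {len(organ_records)} expressions — "
                  f"too few to cluster")
            continue
        organ_coords = reduce_to_plane(
            embed_expressions([r.expression_text for r in organ_records]),
            organ_reduction,
        )
        organ_clusters = density_cluster(
            organ_coords,
            ClusterConfig(min_cluster_size=args.per_organ_min_cluster_size),
        )
        per_organ_keywords[organ] = cluster_keywords(
            organ_records, organ_clusters, top_k=5
        )
        print(f"{organ}: {len(organ_records)} expressions -> "
              f"{organ_clusters.n_clusters} clusters "
              f"({organ_clusters.noise_count} noise)")

    (results / "cluster_summary.json").write_text(json.dumps({
        "n_expressions": len(records),
        "pooled_n_clusters": pooled.n_clusters,
        "pooled_noise": pooled.noise_count,
        "pooled_cluster_sizes": pooled.cluster_sizes(),
        "pooled_keywords": keywords,
        "min_cluster_size": args.min_cluster_size,
        "per_organ_min_cluster_size": args.per_organ_min_cluster_size,
    }, indent=2) + "\n", encoding="utf-8")
    (results / "per_organ_keywords.json").write_text(
        json.dumps(per_organ_keywords, indent=2) + "\n", encoding="utf-8")


if __name__ == "__main__":
    main()
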