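"""Summarize the extracted expressions: frequency tables by journal,
normalized section type, year bin (< 2020 vs >= 2020) and organ, plus the
cross-organ overlap of cluster themes.

Reads results/expressions.tsv and results/per_organ_keywords.json; writes
results/table_by_*.tsv and results/cross_organ_overlap.tsv.
"""

import argparse
import json
from pathlib import Path

from copmine import cross_organ_overlap, read_expressions, tabulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    results = ROOT / "results"
    records = read_expressions(results / "expressions.tsv")

    for by in ("journal", "section", "year_bin", "organ"):
        table = tabulate(records, by=by)
        path = results / f"table_by_{by}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.1f")
        top = table.iloc[0]
        print(f"by {by}: {len(table)} rows; largest share {top[by]!r} "
              f"(N={top['count']}, {top['percent']:.0f}%) -> {path.name}")

    keywords = json.loads(
        (results / "per_organ_keywords.json").read_text(encoding="utf-8")
    )
    per_organ = {
        organ: {int(label): kws for label, kws in clusters.items()}
        for organ, clusters in keywords.items()
    }
    if len(per_organ) >= 2:
        overlap = cross_organ_overlap(per_organ)
        overlap.assign(organs=overlap["organs"].map(", ".join)).to_csv(
            results / "cross_organ_overlap.tsv", sep="\t", index=False)
        shared = overlap[overlap["n_organs"] >= 2]
        print(f"\n{len(shared)} keyword themes shared by >= 2 organs; "
              f"most widespread:")
        for _, row in shared.head(5).iterrows():
            print(f"  {row['theme']!r}: {', '.join(row['organs'])}")
    else:
        print("fewer than 2 organs clustered; no overlap table")


if __name__ == "__main__":
    main()
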