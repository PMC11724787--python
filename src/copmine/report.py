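"""Descriptive summaries: counts per cluster/journal/section/year bin/organ,
plus cross-organ overlap of cluster themes.

Section titles in full-text XML are free text ("1. Introduction", "Materials
and Methods", ...); they are normalized by case-insensitive substring
containment of a canonical name, first hit in list order winning, with
everything else mapped to "nonstandard".  Years are binned at 2020, the
boundary year falling in the upper bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd

from .corpus_io import ExpressionRecord
from .embed_cluster import NOISE_LABEL, ClusterResult

#: Canonical section names, in matching priority order.  "Results" precedes
#: "Discussion" so a combined "Results and Discussion" maps to "Results".
DEFAULT_STANDARD_TITLES = (
    "Abstract",
    "Introduction",
    "Results",
    "Discussion",
    "Methods",
    "Conclusion",
)

NONSTANDARD = "nonstandard"

YEAR_BIN_BOUNDARY = 2020
YEAR_BIN_LOW = f"< {YEAR_BIN_BOUNDARY}"
YEAR_BIN_HIGH = f">= {YEAR_BIN_BOUNDARY}"


@dataclass(frozen=True)
class SectionTypeMap:
    standard_titles: Tuple[str, ...] = DEFAULT_STANDARD_TITLES

    def __post_init__(self):
        lowered = [t.lower() for t in self.standard_titles]
        if len(set(lowered)) != len(lowered):
            raise ValueError("canonical section names must be unique")


def normalize_section(title: str, section_map: SectionTypeMap = SectionTypeMap()) -> str:
    """Canonical section name by substring containment, else "nonstandard"."""
    lowered = title.lower()
    for canonical in section_map.standard_titles:
        if canonical.lower() in lowered:
            return canonical
    return NONSTANDARD


_TABULATE_KEYS = ("cluster", "journal", "section", "year_bin", "organ")


def tabulate(
    records: Sequence[ExpressionRecord],
    by: str,
    labels: ClusterResult | None = None,
    section_map: SectionTypeMap = SectionTypeMap(),
) -> pd.DataFrame:
    """Frequency table of expressions along one dimension.

    Returns a DataFrame with columns ``[by, "count", "percent"]`` sorted by
    descending count (ties alphabetical).  Eligibility: for ``year_bin``,
    records with unknown year are excluded; for ``cluster``, noise points are
    excluded; counts always sum to the number of eligible records.
    """
    if by not in _TABULATE_KEYS:
        raise ValueError(f"unknown tabulation key {by!r}; choose from {_TABULATE_KEYS}")
    keys: List[str] = []
    if by == "cluster":
        if labels is None:
            raise ValueError("tabulate(by='cluster') needs a ClusterResult")
        if len(labels.labels) != len(records):
            raise ValueError(
                f"{len(records)} records but {len(labels.labels)} cluster labels"
            )
        keys = [str(int(l)) for l in labels.labels if l != NOISE_LABEL]
    elif by == "journal":
        keys = [r.journal for r in records]
    elif by == "section":
        keys = [normalize_section(r.section_title, section_map) for r in records]
    elif by == "year_bin":
        keys = [
            YEAR_BIN_HIGH if r.year >= YEAR_BIN_BOUNDARY else YEAR_BIN_LOW
            for r in records
            if r.year is not None
        ]
    elif by == "organ":
        keys = [r.organ for r in records]

    counts = pd.Series(keys, dtype="object").value_counts()
    total = int(counts.sum())
    table = pd.DataFrame({
        by: counts.index,
        "count": counts.to_numpy(),
    })
    table = table.sort_values(
        ["count", by], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["percent"] = (
        100.0 * table["count"] / total if total else 0.0
    )
    return table


def cross_organ_overlap(
    per_organ: Dict[str, Dict[int, List[str]]],
) -> pd.DataFrame:
    """Which organs share which cluster themes.

    ``per_organ`` maps organ -> per-cluster keyword lists (as produced by
    :func:`copmine.embed_cluster.cluster_keywords` after per-organ
    clustering).  A theme token maps to every organ having at least one
    cluster whose keyword list contains it.  Returns a DataFrame with columns
    ``["theme", "organs", "n_organs"]`` sorted by descending organ count then
    theme; an organ with no clusters appears in no row.
    """
    if len(per_organ) < 2:
        raise ValueError("cross-organ overlap needs at least 2 organs")
    theme_to_organs: Dict[str, Set[str]] = {}
    for organ, keywords in per_organ.items():
        for kws in keywords.values():
            for kw in kws:
                theme_to_organs.setdefault(kw, set()).add(organ)
    rows = [
        {"theme": theme, "organs": tuple(sorted(organs)), "n_organs": len(organs)}
        for theme, organs in theme_to_organs.items()
    ]
    return (
        pd.DataFrame(rows, columns=["theme", "organs", "n_organs"])
        .sort_values(["n_organs", "theme"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
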