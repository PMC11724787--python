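"""Section normalization, frequency tables, cross-organ theme overlap."""

from collections import Counter

import numpy as np
import pytest

from copmine.corpus_io import ExpressionRecord
from copmine.embed_cluster import ClusterResult
from copmine.report import (
    NONSTANDARD,
    SectionTypeMap,
    cross_organ_overlap,
    normalize_section,
    tabulate,
)


def _record(journal="J1", year=2021, section="Introduction", organ="brain"):
    return ExpressionRecord(
        expression_text="a network", organ=organ, subject_adjective=None,
        sentence_text="The brain is a network.", article_id="a",
        journal=journal, year=year, section_title=section,
    )


@pytest.mark.parametrize(
    "title, expected",
    [
        ("1. Introduction", "Introduction"),
        ("Materials and Methods", "Methods"),
        ("METHODS", "Methods"),
        ("Results and Discussion", "Results"),  # first hit in priority order
        ("Acknowledgements", NONSTANDARD),
        ("", NONSTANDARD),
        ("Graphical abstract", "Abstract"),
    ],
)
def test_normalize_section(title, expected):
    assert normalize_section(title) == expected


def test_normalize_section_idempotent_and_case_insensitive():
    for title in ["1. InTrOdUcTiOn", "discussion", "Supplementary", ""]:
        once = normalize_section(title)
        assert normalize_section(once) == once
        assert normalize_section(title.upper()) == once


def test_journal_table_arithmetic():
    records = [_record("J1")] * 7 + [_record("J2")] * 3
    table = tabulate(records, by="journal")
    assert list(table["journal"]) == ["J1", "J2"]
    assert list(table["count"]) == [7, 3]
    assert list(table["percent"]) == [70.0, 30.0]


def test_year_bin_boundary_falls_in_upper_bin():
    records = [_record(year=2019), _record(year=2020), _record(year=2023),
               _record(year=None)]
    table = tabulate(records, by="year_bin").set_index("year_bin")
    assert table.loc[">= 2020", "count"] == 2
    assert table.loc["< 2020", "count"] == 1
    assert table["count"].sum() == 3  # the unknown-year record is ineligible


def test_tables_conserve_counts_on_the_synthetic_corpus(corpus, pipeline_result):
    records = pipeline_result.expressions
    for by in ("journal", "section", "organ"):
        table = tabulate(records, by=by)
        assert table["count"].sum() == len(records)
        assert abs(table["percent"].sum() - 100.0) < 1e-9
    dated = [r for r in records if r.year is not None]
    assert tabulate(records, by="year_bin")["count"].sum() == len(dated)


def test_journal_table_matches_gold_bookkeeping(corpus, pipeline_result):
    """Planted per-journal quotas resurface exactly in the tabulation."""
    _, _, gold, _ = corpus
    positive_keys = {(g.article_id, g.sentence_text) for g in gold
                     if g.is_positive}
    expected = Counter(
        e.journal for e in pipeline_result.expressions
        if (e.article_id, e.sentence_text) in positive_keys
    )
    table = tabulate(pipeline_result.expressions, by="journal")
    assert dict(zip(table["journal"], table["count"])) == dict(expected)


def test_cluster_table_excludes_noise():
    records = [_record() for _ in range(6)]
    labels = ClusterResult(np.zeros((6, 2)), np.array([0, 0, 1, 1, 1, -1]),
                           min_cluster_size=2)
    table = tabulate(records, by="cluster", labels=labels)
    assert table["count"].sum() == 5
    with pytest.raises(ValueError):
        tabulate(records[:3], by="cluster", labels=labels)


def test_overlap_maps_shared_theme_to_both_organs():
    per_organ = {
        "brain": {0: ["complex", "network"], 1: ["prediction", "machine"]},
        "heart": {0: ["complex", "pump"]},
    }
    table = cross_organ_overlap(per_organ)
    by_theme = dict(zip(table["theme"], table["organs"]))
    assert by_theme["complex"] == ("brain", "heart")
    assert by_theme["prediction"] == ("brain",)
    assert by_theme["pump"] == ("heart",)


def test_organ_with_no_clusters_appears_in_no_row():
    per_organ = {
        "brain": {0: ["complex"]},
        "stomach": {},  # all noise
    }
    table = cross_organ_overlap(per_organ)
    assert all("stomach" not in organs for organs in table["organs"])


def test_overlap_needs_two_organs():
    with pytest.raises(ValueError):
        cross_organ_overlap({"brain": {0: ["complex"]}})


def test_planted_shared_and_unique_themes_recovered():
    per_organ = {
        "brain": {0: ["dynamic"], 1: ["computer"]},
        "heart": {0: ["dynamic"], 1: ["pump"]},
        "liver": {0: ["dynamic"], 1: ["filter"]},
    }
    table = cross_organ_overlap(per_organ).set_index("theme")
    assert table.loc["dynamic", "n_organs"] == 3
    for unique in ("computer", "pump", "filter"):
        assert table.loc[unique, "n_organs"] == 1
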