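"""Article XML/abstract parsing and expression-table round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from copmine.corpus_io import (
    UNKNOWN_JOURNAL,
    Article,
    ExpressionRecord,
    ParseError,
    Section,
    SourceKind,
    article_to_jats,
    parse_abstract_file,
    parse_abstract_record,
    parse_fulltext_xml,
    read_expressions,
    read_expressions_jsonl,
    write_expressions,
    write_expressions_jsonl,
)

MINIMAL = """<article>
  <front><journal-meta><journal-title>J1</journal-title></journal-meta>
    <article-meta><article-id>A1</article-id>
      <pub-date pub-type="epub"><year>2021</year></pub-date>
    </article-meta></front>
  <body><sec><title>Introduction</title><p>Some text.</p></sec></body>
</article>"""

NESTED = """<article><front><journal-meta><journal-title>J2</journal-title>
</journal-meta></front><body>
<sec><title>Results</title><p>outer text</p>
  <sec><title>Subsection A</title><p>inner A</p></sec>
  <sec><title>Subsection B</title><p>inner B</p></sec>
</sec>
<sec><title>Discussion</title><p>closing</p></sec>
</body></article>"""


def test_minimal_single_section():
    article = parse_fulltext_xml(MINIMAL)
    assert article.journal == "J1"
    assert article.year == 2021
    assert [s.title for s in article.sections] == ["Introduction"]
    assert article.sections[0].text == "Some text."


def test_nested_sections_flatten_in_document_order():
    # hand-enumerated walk of the element tree: Results, Subsection A,
    # Subsection B, Discussion — parents before children, document order
    article = parse_fulltext_xml(NESTED)
    assert [s.title for s in article.sections] == [
        "Results", "Subsection A", "Subsection B", "Discussion",
    ]
    # a parent's own text excludes its nested subsections' text
    assert article.sections[0].text == "outer text"


def test_missing_journal_title_gives_unknown_sentinel():
    xml = "<article><body><sec><title>T</title><p>x</p></sec></body></article>"
    assert parse_fulltext_xml(xml).journal == UNKNOWN_JOURNAL


def test_missing_body_yields_empty_sections():
    xml = "<article><front><journal-meta><journal-title>J</journal-title></journal-meta></front></article>"
    assert parse_fulltext_xml(xml).sections == []


def test_malformed_xml_names_the_file():
    with pytest.raises(ParseError, match="badfile.xml"):
        parse_fulltext_xml("<article><unclosed>", source_name="badfile.xml")


def test_parsing_is_deterministic():
    a = parse_fulltext_xml(NESTED)
    b = parse_fulltext_xml(NESTED)
    assert [(s.title, s.text) for s in a.sections] == \
        [(s.title, s.text) for s in b.sections]


def test_jats_writer_roundtrips_through_parser():
    article = Article(
        article_id="X9", journal="Journal of Testing", year=2018,
        source_kind=SourceKind.synthetic,
        sections=[Section("Abstract", "The brain is a network."),
                  Section("Introduction", "More text here.")],
    )
    back = parse_fulltext_xml(article_to_jats(article))
    assert back.journal == article.journal and back.year == article.year
    assert [(s.title, s.text) for s in back.sections] == \
        [(s.title, s.text) for s in article.sections]


# --- abstract records -------------------------------------------------------

RECORD = """PMID- 123456
JT  - J1
DP  - 2021 Mar
AB  - The brain is a network.
      It spans two lines.
"""


def test_abstract_record_maps_fields():
    article = parse_abstract_record(RECORD)
    assert article.journal == "J1" and article.year == 2021
    assert article.source_kind == SourceKind.abstract_record
    assert [s.title for s in article.sections] == ["Abstract"]
    assert "spans two lines" in article.sections[0].text


def test_abstract_record_without_text_is_skipped():
    assert parse_abstract_record("PMID- 1\nJT  - J1\nDP  - 2020\n") is None


def test_abstract_batch_count_conservation():
    batch = RECORD + "\n\nPMID- 2\nJT  - J2\nDP  - 1999\n\n" + \
        RECORD.replace("123456", "777")
    articles = parse_abstract_file(batch)
    assert len(articles) == 2  # 3 records, 1 without abstract
    assert [a.article_id for a in articles] == ["123456", "777"]


# --- expression tables ------------------------------------------------------

def _record(i=0, **kw):
    base = dict(
        expression_text=f"a complex system {i}",
        organ="brain",
        subject_adjective="human" if i % 3 == 0 else None,
        sentence_text=f"The human brain is a complex system {i}.",
        article_id=f"a{i}",
        journal=["PLoS ONE", "NeuroImage", "J ünïcode"][i % 3],
        year=[2021, 1999, None][i % 3],
        section_title="Introduction",
    )
    base.update(kw)
    return ExpressionRecord(**base)


def test_empty_table_roundtrip(tmp_path):
    path = tmp_path / "empty.tsv"
    write_expressions([], path)
    assert read_expressions(path) == []


def test_special_characters_roundtrip(tmp_path):
    record = _record(expression_text='a "complex, dynamic" system — ünïcode')
    path = tmp_path / "one.tsv"
    write_expressions([record], path)
    assert read_expressions(path) == [record]


def test_500_records_roundtrip_tsv_and_jsonl(tmp_path):
    records = [_record(i) for i in range(500)]
    tsv, jsonl = tmp_path / "t.tsv", tmp_path / "t.jsonl"
    write_expressions(records, tsv)
    write_expressions_jsonl(records, jsonl)
    assert read_expressions(tsv) == records
    assert read_expressions_jsonl(jsonl) == records


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.builds(
            ExpressionRecord,
            expression_text=st.text(
                alphabet=st.characters(blacklist_categories=("Cs",),
                                       blacklist_characters="\r"),
                min_size=1),
            organ=st.sampled_from(["brain", "heart", "kidney"]),
            subject_adjective=st.none() | st.text(min_size=1, max_size=8,
                                                  alphabet="abcdefg"),
            sentence_text=st.text(max_size=40,
                                  alphabet="abc \t,\"'é"),
            article_id=st.text(min_size=1, max_size=6, alphabet="ax1"),
            journal=st.sampled_from(["J1", "J2"]),
            year=st.none() | st.integers(1900, 2030),
            section_title=st.sampled_from(["Intro", "Results"]),
        ),
        max_size=8,
    )
)
def test_roundtrip_property(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("rt") / "x.tsv"
    write_expressions(records, path)
    assert read_expressions(path) == records


def test_malformed_row_reports_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    write_expressions([_record(0)], path)
    with path.open("a", encoding="utf-8") as fh:
        fh.write("only\tthree\tfields\n")
    with pytest.raises(ParseError, match="line 3"):
        read_expressions(path)
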