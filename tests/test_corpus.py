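"""Embedded word list, published counts, response-table IO."""

import pytest

from dswspell import corpus
from dswspell.corpus import CorpusValidationError


def test_lexicon_size_and_ids():
    lex = corpus.load_lexicon()
    assert sorted(lex) == list(range(1, 61))


def test_syllable_spans_cover_units():
    for w in corpus.load_lexicon().values():
        stops = [b for _, b in w.syllables]
        starts = [a for a, _ in w.syllables]
        assert starts[0] == 0
        assert stops[-1] == len(w.graphemes())
        assert starts[1:] == stops[:-1]
        assert 0 <= w.stress_index < len(w.syllables)


def test_verify_integrity():
    assert corpus.verify_integrity()


def test_word_counts_sums():
    df = corpus.word_counts()
    assert len(df) == 60
    assert ((df["gd_correct"] + df["gd_incorrect"]) == 30).all()
    assert ((df["gwd_correct"] + df["gwd_incorrect"]) == 30).all()
    assert int(df["gd_incorrect"].sum()) == 849
    assert int(df["gwd_incorrect"].sum()) == 128


def test_grade_totals_consistent_with_counts():
    gt = corpus.grade_totals()
    assert int(gt["n_students"].sum()) == 60  # 30 per group
    df = corpus.word_counts()
    for g, col in (("GD", "gd_incorrect"), ("GWD", "gwd_incorrect")):
        assert int(gt.loc[gt["group"] == g, "total_incorrect"].sum()) == \
            int(df[col].sum())


def test_checksum_stable():
    assert corpus.corpus_checksum() == corpus.corpus_checksum()
    assert len(corpus.corpus_checksum()) == 64


def test_gold_records_reference_real_words():
    lex = corpus.load_lexicon()
    for rec in corpus.gold_records():
        assert rec.word_id in lex
        assert rec.labels or rec.ambiguous is not None


def _write(tmp_path, text):
    p = tmp_path / "responses.csv"
    p.write_text(text, encoding="utf-8")
    return p


HEADER = "student_id,group,grade,word_id,response\n"


def test_read_responses_roundtrip(tmp_path):
    p = _write(tmp_path, HEADER + "s1,GD,3,1,muito\ns1,GD,3,2,cuando\n")
    df = corpus.read_responses(p)
    assert list(df.columns) == list(corpus.RESPONSE_COLUMNS)
    assert len(df) == 2 and df.loc[1, "response"] == "cuando"


def test_read_responses_missing_column(tmp_path):
    p = _write(tmp_path, "student_id,group,grade,word_id\ns1,GD,3,1\n")
    with pytest.raises(CorpusValidationError, match="missing column"):
        corpus.read_responses(p)


@pytest.mark.parametrize("row,fragment", [
    ("s1,XX,3,1,muito", "group"),
    ("s1,GD,9,1,muito", "grade"),
    ("s1,GD,3,99,muito", "word_id"),
    (",GD,3,1,muito", "student_id"),
])
def test_read_responses_bad_rows(tmp_path, row, fragment):
    p = _write(tmp_path, HEADER + row + "\n")
    with pytest.raises(CorpusValidationError, match="line 2") as exc:
        corpus.read_responses(p)
    assert fragment in str(exc.value)


def test_write_then_read(tmp_path):
    import pandas as pd
    df = pd.DataFrame([("s1", "GWD", 4, 5, "carro")],
                      columns=list(corpus.RESPONSE_COLUMNS))
    p = tmp_path / "out.csv"
    corpus.write_responses(df, p)
    back = corpus.read_responses(p)
    assert back.equals(df)
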