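"""Semiological classification of misspelled responses."""

import pytest

from dswspell import corpus
from dswspell.classifier import (
    ARBITRARY,
    CATEGORIES,
    NATURAL,
    ClassifierConfig,
    classify,
)
from dswspell.orthography import InvalidResponseError


@pytest.fixture(scope="module")
def lex():
    return corpus.load_lexicon()


def test_category_inventory():
    assert set(NATURAL) == {"RPG", "OIL", "ASS", "USW"}
    assert set(ARBITRARY) == {"IPG_1", "IPG_2", "AAW"}
    assert set(CATEGORIES) == set(NATURAL) | set(ARBITRARY) | {"OTHER"}


def test_correct_response(lex):
    c = classify(corpus.word_by_form("casa"), "Casa ")
    assert c.correct and c.labels == ()


def test_blank_raises(lex):
    with pytest.raises(InvalidResponseError):
        classify(corpus.word_by_form("casa"), "   ")


def test_non_alphabetic_is_other(lex):
    c = classify(corpus.word_by_form("casa"), "c4sa")
    assert c.labels == ("OTHER",)


def test_lexical_other_forms(lex):
    for target, response in (("tenho", "temum"), ("almoço", "almoção"),
                             ("futebol", "futball")):
        c = classify(corpus.word_by_form(target), response)
        assert c.labels == ("OTHER",), (target, response)


def test_other_suppresses_everything(lex):
    """OTHER is exclusive: no other label may co-occur with it."""
    for rec in corpus.gold_records():
        c = classify(lex[rec.word_id], rec.form)
        if "OTHER" in c.labels:
            assert c.labels == ("OTHER",), rec.form


def test_low_similarity_is_other(lex):
    c = classify(corpus.word_by_form("tenho"), "xilofone")
    assert c.labels == ("OTHER",)


def test_similarity_threshold_configurable(lex):
    # with the threshold disabled, a distant-but-alignable form is labeled
    cfg = ClassifierConfig(similarity_threshold=0.0,
                           other_forms=frozenset())
    c = classify(corpus.word_by_form("tenho"), "temum", cfg)
    assert c.labels and c.labels != ("OTHER",)


def test_curated_examples_containment(lex):
    """Every published per-category example receives (at least) its
    published label."""
    missed = []
    for wid, form, cat in corpus.curated_examples():
        c = classify(lex[wid], form)
        if cat not in c.labels:
            missed.append((form, cat, c.labels))
    assert not missed, missed


def test_gold_containment_unambiguous(lex):
    """On the annotated fixture subset whose published labels follow the
    published rules, predicted labels must contain the annotation."""
    records = corpus.gold_records(include_ambiguous=False)
    missed = []
    for rec in records:
        c = classify(lex[rec.word_id], rec.form)
        if not set(rec.labels) <= set(c.labels):
            missed.append((rec.form, rec.labels, c.labels))
    assert not missed, missed[:10]


CASE_TABLE = [
    # canonical single-category cases, one per category
    ("casa", "caza", {"IPG_2"}),        # intervocalic s/z: lexically opaque
    ("guerra", "gerra", {"IPG_1"}),     # velar digraph rule before <e>
    ("tempo", "tembo", {"RPG"}),        # homorganic swap changes the reading
    ("tempo", "tepo", {"OIL"}),         # nasal coda letter omitted
    ("porque", "proque", {"ASS"}),      # adjacent transposition
    ("de repente", "derepente", {"USW"}),  # hyposegmentation
    ("embaixo", "em baixo", {"USW"}),   # hypersegmentation
    ("também", "tambem", {"AAW"}),      # acute accent dropped
    ("homem", "omem", {"IPG_2"}),       # silent initial <h>
    ("então", "entao", {"IPG_1"}),      # nasalization tilde dropped
    ("disse", "dise", {"IPG_1"}),       # past-tense <ss> slot
]


@pytest.mark.parametrize("target,response,expected", CASE_TABLE)
def test_canonical_cases(target, response, expected, lex):
    c = classify(corpus.word_by_form(target), response)
    assert expected <= set(c.labels), (target, response, c.labels)


def test_natural_and_arbitrary_partition(lex):
    """Every emitted label on gold data belongs to the taxonomy."""
    for rec in corpus.gold_records():
        c = classify(lex[rec.word_id], rec.form)
        assert set(c.labels) <= set(CATEGORIES)
        assert not c.correct
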