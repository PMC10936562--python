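"""Unit-level alignment: edit scripts, similarity, boundary mapping."""

from functools import lru_cache

import pytest

from dswspell import corpus
from dswspell.alignment import align, apply_script, boundary_diff, units_equivalent
from dswspell.orthography import normalize_form, segment_graphemes
from dswspell.classifier import classify


def _align(target_form, response):
    word = corpus.word_by_form(target_form)
    return word, align(word.graphemes(), segment_graphemes(normalize_form(response)), word)


def test_conseguiu_cosegiu_script():
    _, script = _align("conseguiu", "cosegiu")
    ops = [(op.op, op.t_units, op.r_units) for op in script.ops]
    assert ops == [
        ("match", ("c",), ("c",)),
        ("match", ("o",), ("o",)),
        ("del", ("n",), ()),
        ("match", ("s",), ("s",)),
        ("match", ("e",), ("e",)),
        ("sub", ("gu",), ("g",)),
        ("match", ("i",), ("i",)),
        ("match", ("u",), ("u",)),
    ]
    assert script.cost == pytest.approx(1.5)  # del 1 + sound-preserving sub 0.5


def test_single_deletion():
    _, script = _align("embaixo", "ebaixo")
    nontrivial = [op for op in script.ops if op.op != "match"]
    assert len(nontrivial) == 1
    assert nontrivial[0].op == "del" and nontrivial[0].t_units == ("m",)


def test_single_transposition():
    _, script = _align("porque", "proque")
    nontrivial = [op for op in script.ops if op.op != "match"]
    assert len(nontrivial) == 1
    op = nontrivial[0]
    assert op.op == "transpose"
    assert op.t_units == ("o", "r") and op.r_units == ("r", "o")
    assert script.cost == pytest.approx(1.0)


def test_similarity_gate_examples():
    _, s1 = _align("tenho", "temum")
    assert s1.similarity < 0.5
    _, s2 = _align("almoço", "almoção")
    assert s2.similarity >= 0.5


def test_similarity_identical():
    _, script = _align("casa", "casa")
    assert script.cost == 0.0 and script.similarity == 1.0


def test_boundary_join():
    word = corpus.word_by_form("de repente")
    ops = boundary_diff(word.graphemes(),
                        segment_graphemes("derepente"), word_meta=word)
    assert [op.op for op in ops] == ["join"]


def test_boundary_split():
    word = corpus.word_by_form("embaixo")
    ops = boundary_diff(word.graphemes(),
                        segment_graphemes(normalize_form("em baixo")),
                        word_meta=word)
    assert [op.op for op in ops] == ["split"]


def test_boundary_none():
    word = corpus.word_by_form("casa")
    ops = boundary_diff(word.graphemes(), segment_graphemes("caza"),
                        word_meta=word)
    assert ops == ()


def _gold_pairs():
    lex = corpus.load_lexicon()
    for rec in corpus.gold_records():
        yield lex[rec.word_id], rec.form


def test_apply_script_reproduces_response():
    """Replaying the edit script over the target units must yield the
    response units, for every annotated misspelled form."""
    for word, form in _gold_pairs():
        try:
            r_gs = segment_graphemes(normalize_form(form))
        except Exception:
            continue
        script = align(word.graphemes(), r_gs, word)
        assert apply_script(script) == script.r_units, (word.form, form)


def test_length_bookkeeping():
    """matches + subs + dels + 2*transpositions == |target units| and the
    symmetric identity for the response."""
    for word, form in _gold_pairs():
        try:
            r_gs = segment_graphemes(normalize_form(form))
        except Exception:
            continue
        script = align(word.graphemes(), r_gs, word)
        kinds = [op.op for op in script.ops]
        m, s = kinds.count("match"), kinds.count("sub")
        d, i, tr = kinds.count("del"), kinds.count("ins"), kinds.count("transpose")
        assert m + s + d + 2 * tr == len(script.t_units)
        assert m + s + i + 2 * tr == len(script.r_units)


def _oracle_cost(t, r, equiv):
    """Independent exhaustive-recursion reference for the DP cost."""
    @lru_cache(maxsize=None)
    def f(i, j):
        if i == len(t) and j == len(r):
            return 0.0
        best = float("inf")
        if i < len(t):
            best = min(best, 1.0 + f(i + 1, j))
        if j < len(r):
            best = min(best, 1.0 + f(i, j + 1))
        if i < len(t) and j < len(r):
            c = 0.0 if t[i] == r[j] else (0.5 if equiv(i, j) else 1.0)
            best = min(best, c + f(i + 1, j + 1))
        if (i + 1 < len(t) and j + 1 < len(r) and t[i] == r[j + 1]
                and t[i + 1] == r[j] and t[i] != t[i + 1]):
            best = min(best, 1.0 + f(i + 2, j + 2))
        return best
    return f(0, 0)


def test_dp_cost_matches_recursive_oracle():
    from dswspell.orthography import _stress_nucleus_heuristic
    for word, form in _gold_pairs():
        try:
            r_gs = segment_graphemes(normalize_form(form))
        except Exception:
            continue
        script = align(word.graphemes(), r_gs, word)
        t, r = script.t_units, script.r_units
        t_nuc = word.stressed_nucleus()
        r_nuc = _stress_nucleus_heuristic(r)
        cost = _oracle_cost(
            t, r, lambda i, j: units_equivalent(t, i, r, j, word, t_nuc, r_nuc))
        assert script.cost == pytest.approx(cost), (word.form, form)
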