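"""Grapheme segmentation and grapheme-to-phoneme reading."""

import pytest
from hypothesis import given, settings, strategies as st

from dswspell import corpus
from dswspell.orthography import (
    InvalidResponseError,
    NonAlphabeticError,
    g2p,
    normalize_form,
    segment_graphemes,
    strip_accents,
)

SEG_CASES = {
    "guerra": ["gu", "e", "rr", "a"],
    "quando": ["qu", "a", "n", "d", "o"],
    "escola": ["e", "s", "c", "o", "l", "a"],   # <sc> before <o>: two units
    "chuva": ["ch", "u", "v", "a"],
    "tenho": ["t", "e", "nh", "o"],
    "assim": ["a", "ss", "i", "m"],
    "exemplo": ["e", "x", "e", "m", "p", "l", "o"],
    "em cima": ["e", "m", "c", "i", "m", "a"],
    "conseguiu": ["c", "o", "n", "s", "e", "gu", "i", "u"],
}


@pytest.mark.parametrize("form,units", sorted(SEG_CASES.items()))
def test_segmentation(form, units):
    gs = segment_graphemes(normalize_form(form))
    assert list(gs.surfaces()) == units


def test_multiword_spaces():
    gs = segment_graphemes(normalize_form("em cima"))
    assert gs.spaces == frozenset({2})  # boundary before unit index 2


def test_normalize_lowercases_and_strips():
    assert normalize_form("  Casa ") == "casa"


def test_blank_raises():
    with pytest.raises(InvalidResponseError):
        normalize_form("   ")


def test_non_alphabetic_raises():
    with pytest.raises(NonAlphabeticError):
        segment_graphemes("c4sa")


G2P_CASES = {
    "tenho": ["t", "e", "J", "u"],          # <nh> one unit; final o raised
    "guerra": ["g", "e", "R", "a"],         # digraphs read as one phoneme
    "quando": ["kw", "a", "N", "d", "u"],   # nasal coda archiphoneme
    "escola": ["e", "S", "k", "o", "l", "a"],  # coda sibilant archiphoneme
    "exemplo": ["e", "z", "e", "N", "p", "l", "u"],  # lexical <x> = /z/
    "homem": ["o", "m", "e", "N"],          # silent initial <h>
    "feliz": ["f", "e", "l", "i", "S"],
    "almoço": ["a", "w", "m", "o", "s", "u"],  # coda <l> vocalized
    "então": ["e", "N", "t", "aN", "w"],    # tilde vowel is one symbol
    "embaixo": ["e", "N", "b", "a", "j", "X", "u"],  # glide after vowel
}


@pytest.mark.parametrize("form,phonemes", sorted(G2P_CASES.items()))
def test_g2p(form, phonemes):
    word = corpus.word_by_form(form)
    assert list(g2p(word.graphemes(), word).symbols) == phonemes


def test_g2p_length_bound():
    """Every word yields at least one phoneme per non-silent unit and never
    more phonemes than units."""
    for word in corpus.load_lexicon().values():
        units = word.graphemes().surfaces()
        ph = g2p(word.graphemes(), word).symbols
        assert 1 <= len(ph) <= len(units)


_letters = st.text(alphabet="abcdefghijlmnopqrstuvxzçãõáéíóúâêô",
                   min_size=1, max_size=12)


@settings(max_examples=100, derandomize=True)
@given(_letters)
def test_normalize_idempotent(s):
    n = normalize_form(s)
    assert normalize_form(n) == n


@settings(max_examples=100, derandomize=True)
@given(_letters)
def test_segmentation_roundtrip(s):
    """Concatenating the unit surfaces reproduces the normalized string."""
    n = normalize_form(s)
    gs = segment_graphemes(n)
    assert "".join(gs.surfaces()) == n


@settings(max_examples=100, derandomize=True)
@given(_letters)
def test_strip_accents_idempotent(s):
    assert strip_accents(strip_accents(s)) == strip_accents(s)
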