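"""Seed-deterministic synthetic dictation corpora.

Since the study's raw per-student corpus is not published, this module
generates one: per-word error probabilities are taken from the published
per-word counts, error categories are drawn from the published per-group
category mix, and each category is realized by a category-consistent
corruption operator (an edit that the classifier's own rules assign to that
category by construction).  Every operator validates its output by
re-segmentation, so single-error forms round-trip through the classifier.

Operators (one per category):

* RPG   — swap a grapheme with a homorganic partner (p/b, t/d, f/v, c/g, x/j)
* OIL   — delete one unit, or insert an <i>
* ASS   — transpose two adjacent distinct units
* USW   — join a multiword target, or split a word at a syllable boundary
* AAW   — strip an acute/circumflex accent
* IPG_1 — violate a contextual/morphological rule without changing the sound
* IPG_2 — pick a different grapheme for a lexically opaque slot
* OTHER — emit a listed lexicalized intrusion

Applicability varies by word; ``corrupt`` raises
:class:`OperatorNotApplicableError` when a category has no site on a word.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import corpus
from .classifier import CATEGORIES
from .orthography import (
    _ACUTE_CIRC,
    TargetWord,
    _is_vowel,
    normalize_form,
    segment_graphemes,
)

__all__ = [
    "OperatorNotApplicableError",
    "SimulationProfile",
    "default_profile",
    "applicable_categories",
    "corrupt",
    "simulate_dataset",
    "OTHER_FORMS",
]


class OperatorNotApplicableError(ValueError):
    """The requested category has no applicable site on this word."""


# word_id -> lexicalized intrusion
OTHER_FORMS = {15: "futball", 47: "temum", 26: "almoção"}

_HOMORGANIC = {"p": "b", "b": "p", "t": "d", "d": "t",
               "f": "v", "v": "f", "c": "g", "g": "c",
               "x": "j", "j": "x"}
_SIBILANT_TARGETS = {"s", "ss", "ç", "c", "z"}


@dataclass(frozen=True)
class SimulationProfile:
    """Generation parameters; ``default_profile()`` derives them from the
    embedded study tables."""

    word_error_rates: dict  # group -> {word_id: probability}
    category_mix: dict      # group -> {category: weight}
    group_sizes: dict       # grade -> students per group
    multi_error_rate: float = 0.25

    def validate(self) -> None:
        for g, rates in self.word_error_rates.items():
            for wid, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"rate for word {wid} in {g} not in [0,1]")
        for g, mix in self.category_mix.items():
            if any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
                raise ValueError(f"invalid category mix for {g}")
            unknown = set(mix) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"unknown categories {sorted(unknown)}")
        if not 0.0 <= self.multi_error_rate <= 1.0:
            raise ValueError("multi_error_rate not in [0,1]")


def default_profile() -> SimulationProfile:
    counts = corpus.word_counts()
    rates = {
        "GD": dict(zip(counts["word_id"], counts["gd_incorrect"] / 30.0)),
        "GWD": dict(zip(counts["word_id"], counts["gwd_incorrect"] / 30.0)),
    }
    mix = {g: dict(v) for g, v in corpus.distinct_form_counts().items()}
    return SimulationProfile(word_error_rates=rates, category_mix=mix,
                             group_sizes=corpus.group_sizes(),
                             multi_error_rate=0.25)


# ---------------------------------------------------------------------------
# Site enumeration.  A site is (kind, payload):
#   ("sub", (pos, replacement)) | ("del", pos) | ("ins", (pos, letter))
#   ("swap", pos)  — swap units pos, pos+1
#   ("join", None) | ("split", pos) | ("lexical", form)
# ---------------------------------------------------------------------------


def _units_and_spaces(word: TargetWord):
    gs = word.graphemes()
    return list(gs.surfaces()), set(gs.spaces)


def _render(units: Sequence[str], spaces) -> str:
    out = []
    for i, u in enumerate(units):
        if i in spaces:
            out.append(" ")
        out.append(u)
    return "".join(out)


def _token_spans(n_units: int, spaces) -> list[tuple[int, int]]:
    cuts = sorted(spaces)
    starts = [0] + cuts
    stops = cuts + [n_units]
    return list(zip(starts, stops))


def _apply_site(word: TargetWord, kind: str, payload):
    units, spaces = _units_and_spaces(word)
    if kind == "sub":
        pos, repl = payload
        units[pos] = repl
    elif kind == "del":
        pos = payload
        del units[pos]
        spaces = {s if s <= pos else s - 1 for s in spaces}
    elif kind == "ins":
        pos, letter = payload
        units.insert(pos, letter)
        spaces = {s if s < pos else s + 1 for s in spaces}
    elif kind == "swap":
        pos = payload
        units[pos], units[pos + 1] = units[pos + 1], units[pos]
    elif kind == "join":
        spaces = set()
    elif kind == "split":
        spaces = set(spaces) | {payload}
    elif kind == "lexical":
        return payload
    else:  # pragma: no cover
        raise ValueError(kind)
    return _render(units, spaces)


def _expected_units(word: TargetWord, kind: str, payload) -> Optional[list[str]]:
    units, _ = _units_and_spaces(word)
    if kind == "sub":
        pos, repl = payload
        units[pos] = repl
    elif kind == "del":
        del units[payload]
    elif kind == "ins":
        pos, letter = payload
        units.insert(pos, letter)
    elif kind == "swap":
        pos = payload
        units[pos], units[pos + 1] = units[pos + 1], units[pos]
    else:
        return None
    return units


def _site_valid(word: TargetWord, kind: str, payload) -> bool:
    """Re-segment the corrupted text and require the intended unit edit —
    edits that merge or shatter digraphs are rejected."""
    text = _apply_site(word, kind, payload)
    norm = normalize_form(text)
    if norm == normalize_form(word.form):
        return False
    try:
        gs = segment_graphemes(norm)
    except Exception:
        return False
    expected = _expected_units(word, kind, payload)
    if expected is not None and list(gs.surfaces()) != expected:
        return False
    return True


def _front(units: Sequence[str], i: int) -> bool:
    from .orthography import strip_accents
    nxt = units[i + 1] if i + 1 < len(units) else None
    return _is_vowel(nxt) and strip_accents(nxt)[0] in "ei"


def _coda(units: Sequence[str], i: int) -> bool:
    nxt = units[i + 1] if i + 1 < len(units) else None
    return nxt is None or not _is_vowel(nxt)


def _sites_RPG(word: TargetWord) -> list:
    units, _ = _units_and_spaces(word)
    out = []
    for i, u in enumerate(units):
        repl = _HOMORGANIC.get(u)
        if repl is None:
            continue
        if _site_valid(word, "sub", (i, repl)):
            out.append(("sub", (i, repl)))
    return out


def _sites_OIL(word: TargetWord) -> list:
    units, spaces = _units_and_spaces(word)
    spans = _token_spans(len(units), spaces)
    out = []
    for i, u in enumerate(units):
        if i == 0 and u == "h":
            continue  # silent-h omission is an IPG_2 pattern, not OIL
        if any(b - a == 1 and a == i for a, b in spans):
            continue  # deleting a whole token is a segmentation change
        if _site_valid(word, "del", i):
            out.append(("del", i))
    for pos in range(len(units) + 1):
        if _site_valid(word, "ins", (pos, "i")):
            out.append(("ins", (pos, "i")))
    return out


def _sites_ASS(word: TargetWord) -> list:
    units, spaces = _units_and_spaces(word)
    out = []
    for i in range(len(units) - 1):
        if units[i] == units[i + 1]:
            continue
        if i + 1 in spaces:
            continue  # keep transpositions within a token
        if _site_valid(word, "swap", i):
            out.append(("swap", i))
    return out


def _sites_USW(word: TargetWord) -> list:
    units, spaces = _units_and_spaces(word)
    if word.multiword:
        return [("join", None)]
    out = []
    for start, _ in word.syllables[1:]:
        if 0 < start < len(units):
            out.append(("split", start))
    return out


def _sites_AAW(word: TargetWord) -> list:
    units, _ = _units_and_spaces(word)
    out = []
    for i, u in enumerate(units):
        if u in _ACUTE_CIRC and _site_valid(word, "sub", (i, _ACUTE_CIRC[u])):
            out.append(("sub", (i, _ACUTE_CIRC[u])))
    return out


def _sites_IPG_1(word: TargetWord) -> list:
    units, _ = _units_and_spaces(word)
    n = len(units)
    nucleus = word.stressed_nucleus()
    out = []
    for i, u in enumerate(units):
        last = i == n - 1
        prev = units[i - 1] if i > 0 else None
        # internal nasal coda letter swapped
        if u in ("m", "n") and not last and _coda(units, i):
            out.append(("sub", (i, "n" if u == "m" else "m")))
        # <rr> simplified / intervocalic <r> doubled
        if u == "rr":
            out.append(("sub", (i, "r")))
        if u == "r" and _is_vowel(prev) and not last and _is_vowel(units[i + 1]):
            out.append(("sub", (i, "rr")))
        # velar digraph reduced before a front vowel
        if u in ("gu", "qu") and _front(units, i):
            out.append(("sub", (i, u[0])))
        # tilde (nasalization mark) dropped
        if u in ("ã", "õ"):
            out.append(("sub", (i, {"ã": "a", "õ": "o"}[u])))
        # paroxytone final vowel raised in spelling
        if last and word.stress_kind == "paroxytone" and u in ("e", "o") \
                and prev is not None and not _is_vowel(prev):
            out.append(("sub", (i, "i" if u == "e" else "u")))
        # simple-past final <u> respelled
        if last and word.verb_past and u == "u" and _is_vowel(prev):
            out.append(("sub", (i, "l")))
            out.append(("sub", (i, "o")))
        # lexical /z/ spelled <x> replaced by <z>/<s>
        if u == "x" and word.x_reads == "z":
            out.append(("sub", (i, "z")))
            out.append(("sub", (i, "s")))
    # morphological slot rules (past-tense <ss>)
    for idx, _rid in word.slot_rules:
        for repl in ("ç", "c", "s"):
            out.append(("sub", (idx, repl)))
    return [s for s in out if _site_valid(word, *s)]


def _sites_IPG_2(word: TargetWord) -> list:
    units, _ = _units_and_spaces(word)
    n = len(units)
    nucleus = word.stressed_nucleus()
    slot_positions = {idx for idx, _ in word.slot_rules}
    out = []
    for i, u in enumerate(units):
        if i in slot_positions:
            continue  # governed by a morphological rule: IPG_1 territory
        last = i == n - 1
        prev = units[i - 1] if i > 0 else None
        nxt = units[i + 1] if i + 1 < n else None
        intervocalic = _is_vowel(prev) and _is_vowel(nxt)
        front = _front(units, i)
        # sibilant respellings that keep the sound
        if u == "ç":
            out.append(("sub", (i, "s")))
            out.append(("sub", (i, "ss")))
        elif u == "ss":
            out.append(("sub", (i, "ç" if not front else "c")))
            out.append(("sub", (i, "s")))
        elif u == "c" and front:
            out.append(("sub", (i, "s")))
            out.append(("sub", (i, "ss")))
        elif u == "s" and intervocalic:
            out.append(("sub", (i, "z")))
        elif u == "s" and _is_vowel(nxt) and not _is_vowel(prev):
            out.append(("sub", (i, "c" if front else "ç")))
        elif u == "z" and last:
            out.append(("sub", (i, "s")))
        # <g>/<j> before a front vowel
        if u == "g" and front:
            out.append(("sub", (i, "j")))
        if u == "j" and front:
            out.append(("sub", (i, "g")))
        # word-final nasal letter
        if last and u in ("m", "n"):
            out.append(("sub", (i, "n" if u == "m" else "m")))
        # pretonic e/i and o/u
        if i < nucleus and u in ("e", "i", "o", "u") and not _is_vowel(prev):
            swap = {"e": "i", "i": "e", "o": "u", "u": "o"}[u]
            out.append(("sub", (i, swap)))
        # final /w/ letter in non-verbs
        if last and not word.verb_past and u == "l" and _is_vowel(prev):
            out.append(("sub", (i, "u")))
            out.append(("sub", (i, "o")))
        # internal coda /w/
        if not last and u in ("l", "u") and _is_vowel(prev) \
                and nxt is not None and not _is_vowel(nxt):
            out.append(("sub", (i, "u" if u == "l" else "l")))
        # silent initial <h>
        if i == 0 and u == "h":
            out.append(("del", 0))
    return [s for s in out if _site_valid(word, *s)]


def _sites_OTHER(word: TargetWord) -> list:
    form = OTHER_FORMS.get(word.word_id)
    return [("lexical", form)] if form else []


_SITE_FNS = {"RPG": _sites_RPG, "OIL": _sites_OIL, "ASS": _sites_ASS,
             "USW": _sites_USW, "AAW": _sites_AAW, "IPG_1": _sites_IPG_1,
             "IPG_2": _sites_IPG_2, "OTHER": _sites_OTHER}

_SITE_CACHE: dict[tuple[int, str], list] = {}


def _sites(word: TargetWord, category: str) -> list:
    key = (word.word_id, category)
    if key not in _SITE_CACHE:
        try:
            fn = _SITE_FNS[category]
        except KeyError:
            raise ValueError(f"unknown category {category!r}") from None
        _SITE_CACHE[key] = fn(word)
    return _SITE_CACHE[key]


def applicable_categories(word: TargetWord) -> list[str]:
    return [c for c in CATEGORIES if _sites(word, c)]


def corrupt(word: TargetWord, category: str,
            rng: Optional[np.random.Generator] = None) -> str:
    """One category-consistent misspelling of ``word`` (seed-deterministic
    given ``rng``)."""
    rng = rng or np.random.default_rng()
    sites = _sites(word, category)
    if not sites:
        raise OperatorNotApplicableError(
            f"category {category} has no site on {word.form!r}")
    kind, payload = sites[int(rng.integers(len(sites)))]
    return normalize_form(_apply_site(word, kind, payload))


def _positions(kind: str, payload) -> tuple[int, ...]:
    if kind == "sub":
        return (payload[0],)
    if kind == "del":
        return (payload,)
    if kind == "ins":
        return (payload[0],)
    if kind == "swap":
        return (payload, payload + 1)
    if kind == "split":
        return (payload,)
    return ()


def _compose(word: TargetWord, first: tuple, second: tuple) -> Optional[str]:
    """Apply two sites jointly when they are positionally independent."""
    (k1, p1), (k2, p2) = first, second
    if "lexical" in (k1, k2) or {k1, k2} == {"join", "split"}:
        return None
    pos1, pos2 = _positions(k1, p1), _positions(k2, p2)
    if pos1 and pos2 and min(abs(a - b) for a in pos1 for b in pos2) < 2:
        return None
    units, spaces = _units_and_spaces(word)
    for kind, payload in sorted(
            [first, second],
            key=lambda s: -(max(_positions(*s)) if _positions(*s) else -1)):
        if kind == "sub":
            units[payload[0]] = payload[1]
        elif kind == "del":
            del units[payload]
            spaces = {s if s <= payload else s - 1 for s in spaces}
        elif kind == "ins":
            units.insert(payload[0], payload[1])
            spaces = {s if s < payload[0] else s + 1 for s in spaces}
        elif kind == "swap":
            units[payload], units[payload + 1] = \
                units[payload + 1], units[payload]
        elif kind == "join":
            spaces = set()
        elif kind == "split":
            spaces = set(spaces) | {payload}
    text = _render(units, spaces)
    norm = normalize_form(text)
    if norm == normalize_form(word.form):
        return None
    try:
        segment_graphemes(norm)
    except Exception:
        return None
    return norm


def _calibrated_weights(profile: SimulationProfile, group: str,
                        lex: dict) -> dict:
    """Per-category sampling weights such that the EXPECTED drawn category
    mix over the whole corpus equals the profile mix.

    A naive per-word renormalization over applicable categories inflates
    broadly applicable categories (insertions/omissions fit every word) at
    the expense of narrowly applicable ones (accent errors fit few).  This
    corrects for that with iterative proportional fitting over the
    word-by-category applicability matrix, weighted by each word's error
    rate."""
    mix = profile.category_mix[group]
    rates = profile.word_error_rates[group]
    cats = [c for c in CATEGORIES if mix.get(c, 0) > 0]
    target = np.array([mix[c] for c in cats], dtype=float)
    target /= target.sum()
    rows, wts = [], []
    for wid, rate in rates.items():
        if rate <= 0 or wid not in lex:
            continue
        row = np.array([1.0 if _sites(lex[wid], c) else 0.0 for c in cats])
        if row.sum() == 0:
            continue
        rows.append(row)
        wts.append(rate)
    A = np.array(rows)
    w = np.array(wts)
    lam = np.ones(len(cats))
    for _ in range(500):
        q = A * (target * lam)
        q /= q.sum(axis=1, keepdims=True)
        achieved = (w[:, None] * q).sum(axis=0)
        achieved /= achieved.sum()
        lam *= target / np.maximum(achieved, 1e-12)
    return dict(zip(cats, target * lam))


def _draw_category(rng, weights: dict, allowed: Sequence[str]) -> Optional[str]:
    cats = [c for c in allowed if weights.get(c, 0) > 0]
    if not cats:
        return None
    w = np.array([weights[c] for c in cats], dtype=float)
    return cats[int(rng.choice(len(cats), p=w / w.sum()))]


def simulate_dataset(profile: Optional[SimulationProfile] = None,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate the full design: both groups, grades 3–6, 60 words each.

    Returns a response table (``student_id, group, grade, word_id,
    response``) plus generation annotations (``is_error``,
    ``true_categories``).
    """
    profile = profile or default_profile()
    profile.validate()
    rng = np.random.default_rng(seed)
    lex = corpus.load_lexicon()
    rows = []
    for group in corpus.GROUPS:
        rates = profile.word_error_rates[group]
        weights = _calibrated_weights(profile, group, lex)
        counter = 0
        for grade in corpus.GRADES:
            for _ in range(profile.group_sizes[grade]):
                counter += 1
                sid = f"{group}{grade}-{counter:02d}"
                for wid in sorted(lex):
                    word = lex[wid]
                    target = normalize_form(word.form)
                    p = rates.get(wid, 0.0)
                    if rng.random() >= p:
                        rows.append((sid, group, grade, wid, target,
                                     False, ""))
                        continue
                    allowed = applicable_categories(word)
                    cat = _draw_category(rng, weights, allowed)
                    if cat is None:  # no operator fits: emit an OIL form
                        cat = "OIL"
                    sites = _sites(word, cat)
                    first = sites[int(rng.integers(len(sites)))]
                    response = normalize_form(_apply_site(word, *first))
                    cats = [cat]
                    if cat != "OTHER" and len(word.graphemes()) >= 5 \
                            and rng.random() < profile.multi_error_rate:
                        cat2 = _draw_category(
                            rng, weights,
                            [c for c in allowed if c not in ("OTHER", cat)])
                        if cat2 is not None:
                            sites2 = _sites(word, cat2)
                            order = rng.permutation(len(sites2))
                            for k in order:
                                combined = _compose(word, first, sites2[int(k)])
                                if combined is not None:
                                    response = combined
                                    cats.append(cat2)
                                    break
                    rows.append((sid, group, grade, wid, response,
                                 True, "|".join(cats)))
    return pd.DataFrame(
        rows, columns=["student_id", "group", "grade", "word_id",
                       "response", "is_error", "true_categories"])
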