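"""Semiological classification of spelling errors.

A written response to a dictation target is mapped to a set of error
categories:

Natural-spelling errors (failures of phoneme–grapheme conversion itself):

* ``RPG``  — substitution that changes the word's reading
* ``OIL``  — omission or insertion of letters
* ``ASS``  — alteration of syllable structure (adjacent transposition, or a
  deletion/insertion pair moving an equivalent letter to another syllable)
* ``USW``  — unconventional word segmentation (joins and splits)

Arbitrary-spelling errors (the sound is preserved but an orthographic
convention is violated):

* ``IPG_1`` — the violated rule is contextual or morphological (a rule the
  writer could have applied)
* ``IPG_2`` — the conventional spelling is lexically opaque
* ``AAW``  — accentuation alteration (acute/circumflex added, lost or moved)

``OTHER`` marks unclassifiable productions (non-alphabetic content, forms too
distant from the target, or lexicalized intrusions) and suppresses all other
labels.

The decision procedure is a fixed precedence cascade over the aligned edit
script; every labeled edit is kept on the result so decisions are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .orthography import (
    DIGRAPHS,
    VOWELS,
    SIBILANT_UNITS,
    SIBILANT_PHONEMES,
    GraphemeString,
    TargetWord,
    NonAlphabeticError,
    _is_vowel,
    _stress_nucleus_heuristic,
    base_letters,
    normalize_form,
    phoneme_of_unit,
    segment_graphemes,
    strip_accents,
)
from .alignment import (
    EditOp,
    EditScript,
    SEMIVOWEL_LETTERS,
    VELAR_UNITS,
    align,
    boundary_diff,
)

__all__ = [
    "CATEGORIES",
    "NATURAL",
    "ARBITRARY",
    "CATEGORY_CLASS",
    "ClassifierConfig",
    "LabeledEdit",
    "Classification",
    "classify",
    "DEFAULT_CONFIG",
]

NATURAL = ("RPG", "OIL", "ASS", "USW")
ARBITRARY = ("IPG_1", "IPG_2", "AAW")
CATEGORIES = NATURAL + ARBITRARY + ("OTHER",)
CATEGORY_CLASS = {**{c: "natural" for c in NATURAL},
                  **{c: "arbitrary" for c in ARBITRARY},
                  "OTHER": "other"}

_VOICELESS_VELARS = frozenset({"c", "q", "qu"})
_VOICED_VELARS = frozenset({"g", "gu"})
_NASALS = frozenset({"m", "n"})
_RHOTICS = frozenset({"r", "rr"})

# Letter-equivalence classes for the syllable-restructuring (migration)
# pairing: a deleted letter re-inserted elsewhere as itself, as the other
# member of its class, counts as a displacement rather than two independent
# letter errors.
_MIGRATION_CLASSES = (SEMIVOWEL_LETTERS, _NASALS,
                      frozenset({"s", "ss", "c", "ç", "z", "x", "sc", "sç",
                                 "xc", "xs"}))


@dataclass(frozen=True)
class ClassifierConfig:
    """Knobs of the decision procedure (defaults follow the study)."""

    similarity_threshold: float = 0.5
    # lexicalized intrusions that are unclassifiable by rule
    other_forms: frozenset = frozenset({"almoção", "temum", "futball"})
    # enable the deletion/insertion migration pairing for ASS
    migration_pairing: bool = True


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class LabeledEdit:
    edit: EditOp
    label: Optional[str]
    reason: str = ""


@dataclass(frozen=True)
class Classification:
    target: TargetWord
    response: str  # normalized written form
    correct: bool
    labels: tuple[str, ...]  # sorted per CATEGORIES order
    edits: tuple[LabeledEdit, ...] = ()
    script: Optional[EditScript] = None
    similarity: float = 1.0

    @property
    def natural_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l in NATURAL)

    @property
    def arbitrary_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l in ARBITRARY)

    @property
    def is_other(self) -> bool:
        return self.labels == ("OTHER",)


def _sort_labels(labels) -> tuple[str, ...]:
    return tuple(sorted(set(labels), key=CATEGORIES.index))


def _is_digraph_release(t_unit: str, r_unit: str) -> Optional[str]:
    """If the sub keeps one letter of a target digraph, return the released
    (dropped) letter."""
    if t_unit in DIGRAPHS and len(r_unit) == 1 and r_unit in t_unit \
            and t_unit[0] != t_unit[1]:
        return t_unit[0] if r_unit == t_unit[1] else t_unit[1]
    return None


def _same_migration_class(a: str, b: str) -> bool:
    if a == b:
        return True
    return any(a in cls and b in cls for cls in _MIGRATION_CLASSES)


def _coda(surfaces: Sequence[str], i: int) -> bool:
    nxt = surfaces[i + 1] if i + 1 < len(surfaces) else None
    return nxt is None or not _is_vowel(nxt)


def label_substitution(t: Sequence[str], i: int,
                       r: Sequence[str], j: int,
                       word_meta: TargetWord,
                       t_nuc: int, r_nuc: Optional[int]) -> tuple[str, str]:
    """Category of one unit substitution (target unit ``i`` → response unit
    ``j``), by fixed precedence.  Returns (label, reason)."""
    tu, ru = t[i], r[j]
    t_last = i == len(t) - 1
    r_last = j == len(r) - 1
    t_prev = t[i - 1] if i > 0 else None
    t_next = t[i + 1] if i + 1 < len(t) else None

    pt = phoneme_of_unit(t, i, word_meta, stress_nucleus=t_nuc)
    pr = phoneme_of_unit(r, j, word_meta, stress_nucleus=r_nuc)
    equivalent = pt == pr

    # 1. accent-only difference: acute/circumflex -> AAW
    if base_letters(tu) == base_letters(ru):
        return "AAW", "acute/circumflex accent altered"
    # 2. tilde difference: nasalization is rule-marked
    if strip_accents(tu) == strip_accents(ru):
        return "IPG_1", "tilde (nasalization mark) altered"
    # 3. morphological slot rule (e.g. past-tense <ss>)
    for idx, rid in word_meta.slot_rules:
        if idx == i and tu != ru:
            return "IPG_1", f"morphological rule {rid} violated"
    # 4. <x> / <ch> both reading /S/: position-conditioned
    if {tu, ru} == {"x", "ch"} and pt == pr == "X":
        after_diphthong = i >= 2 and _is_vowel(t_prev) and _is_vowel(t[i - 2])
        after_initial_en = i == 2 and t[0] == "e" and t[1] == "n"
        if after_diphthong or after_initial_en:
            return "IPG_1", "/S/ after diphthong or initial <en> must be <x>"
        return "IPG_2", "the choice <x>/<ch> is lexically opaque here"
    # 5. target <x> reading /z/ swapped for another sibilant letter
    if tu == "x" and word_meta.x_reads == "z" and ru in SIBILANT_UNITS \
            and pr in SIBILANT_PHONEMES:
        return "IPG_1", "intervocalic /z/ of this word must be <x>"
    # 6. sibilant family: sound class preserved, grapheme choice is lexical
    if tu in SIBILANT_UNITS and pt in SIBILANT_PHONEMES \
            and ru in SIBILANT_UNITS and pr in SIBILANT_PHONEMES:
        return "IPG_2", "sibilant grapheme choice is lexically opaque"
    # 7. <g> / <j> for /Z/: contextual before a,o,u; lexical before e,i
    if {tu, ru} == {"g", "j"}:
        front = _is_vowel(t_next) and strip_accents(t_next)[0] in "ei"
        if front:
            return "IPG_2", "<g>/<j> before <e>,<i> is lexically opaque"
        return "IPG_1", "/Z/ before <a>,<o>,<u> is written <j>"
    # 8. velar family: digraph misuse is contextual, voicing change is sound
    if tu in VELAR_UNITS and ru in VELAR_UNITS:
        same_voicing = ({tu, ru} <= _VOICELESS_VELARS
                        or {tu, ru} <= _VOICED_VELARS)
        if same_voicing:
            return "IPG_1", "velar digraph rule (<qu>/<gu> before <e>,<i>)"
        return "RPG", "velar voicing changed"
    # 9. <r> / <rr>
    if tu in _RHOTICS and ru in _RHOTICS:
        return "IPG_1", "intervocalic /R/ requires the digraph <rr>"
    # 10. nasal coda letter choice
    if tu in _NASALS and ru in _NASALS and _coda(t, i):
        if t_last:
            return "IPG_2", "word-final nasal letter is lexically opaque"
        if t_next in ("p", "b"):
            return "IPG_1", "nasal coda before <p>,<b> must be <m>"
        return "IPG_1", "internal nasal coda before other consonants is <n>"
    # 11. word-final <m> written as <i> (nasal diphthong respelled)
    if t_last and r_last and tu in _NASALS and ru == "i":
        return "IPG_2", "word-final nasal respelled as <i>"
    # 12. final semivowel /w/: <l>, <u>, <o> choices
    if t_last and r_last and tu in SEMIVOWEL_LETTERS \
            and ru in SEMIVOWEL_LETTERS and _is_vowel(t_prev):
        if word_meta.verb_past:
            return "IPG_1", "simple-past final /w/ is the morpheme <u>"
        return "IPG_2", "final /w/ letter is lexically opaque"
    # 13. internal coda /w/: <l> / <u>
    if not t_last and tu in ("l", "u") and ru in ("l", "u") \
            and _is_vowel(t_prev) and not _is_vowel(t_next):
        return "IPG_2", "internal coda /w/ letter is lexically opaque"
    # 14. word-final vowel raising pairs e/i, o/u
    if t_last and r_last and ({tu, ru} == {"e", "i"} or {tu, ru} == {"o", "u"}):
        if word_meta.stress_kind == "paroxytone":
            return "IPG_1", "paroxytone final /i/,/u/ are written <e>,<o>"
        return "IPG_2", "final unstressed vowel letter is lexically opaque"
    # 15. pretonic vowel pairs e/i, o/u
    if i < t_nuc and ({tu, ru} == {"e", "i"} or {tu, ru} == {"o", "u"}):
        return "IPG_2", "pretonic vowel spelling is lexically opaque"
    # 16. residual sound-preserving substitution (same reading, and stressed
    # on neither or both sides — a stress shift changes the word's sound)
    if equivalent and (i == t_nuc) == (j == r_nuc):
        return "IPG_2", "sound preserved; conventional grapheme is opaque"
    # 17. the reading changed
    return "RPG", "substitution changes the word's reading"


def substitution_sound_preserving(t: Sequence[str], i: int,
                                  r: Sequence[str], j: int,
                                  word_meta: TargetWord,
                                  t_nuc: int, r_nuc: Optional[int]) -> bool:
    """Whether the cascade assigns this substitution an arbitrary-class
    label (IPG_1/IPG_2/AAW) — i.e. the word still reads the same.  Used by
    the aligner as its phonological-equivalence cost discount."""
    lab, _ = label_substitution(t, i, r, j, word_meta, t_nuc, r_nuc)
    return lab in ARBITRARY


def classify(target: TargetWord, response: str,
             config: ClassifierConfig = DEFAULT_CONFIG) -> Classification:
    """Classify one written response against its dictation target.

    Raises :class:`~dswspell.orthography.InvalidResponseError` for blank
    responses.  Non-alphabetic content yields ``OTHER``.
    """
    norm = normalize_form(response)
    target_norm = normalize_form(target.form)
    if norm == target_norm:
        return Classification(target, norm, True, ())

    try:
        r_gs = segment_graphemes(norm)
    except NonAlphabeticError:
        return Classification(target, norm, False, ("OTHER",), (), None, 0.0)

    if norm in config.other_forms:
        return Classification(target, norm, False, ("OTHER",), (), None, 0.0)

    t_gs = target.graphemes()
    script = align(t_gs, r_gs, target)
    if script.similarity < config.similarity_threshold:
        return Classification(target, norm, False, ("OTHER",), (), script,
                              script.similarity)

    t = script.t_units
    r = script.r_units
    t_nuc = target.stressed_nucleus()
    r_nuc = _stress_nucleus_heuristic(r)

    labeled: list[LabeledEdit] = []
    labels: set[str] = set()

    # first pass: label unit edits
    for op in script.ops:
        if op.op == "match":
            continue
        if op.op == "transpose":
            labeled.append(LabeledEdit(op, "ASS", "adjacent units transposed"))
        elif op.op == "sub":
            lab, why = label_substitution(t, op.t_start, r, op.r_start,
                                          target, t_nuc, r_nuc)
            labeled.append(LabeledEdit(op, lab, why))
        elif op.op == "del":
            if op.t_start == 0 and op.t_units[0] == "h":
                labeled.append(LabeledEdit(
                    op, "IPG_2", "silent initial <h> is lexically opaque"))
            else:
                labeled.append(LabeledEdit(op, "OIL", "letter omitted"))
        elif op.op == "ins":
            labeled.append(LabeledEdit(op, "OIL", "letter inserted"))

    # second pass: migration pairing — a deletion (or the letter released by
    # a digraph-reducing substitution) paired with an insertion of an
    # equivalent letter elsewhere is a syllable-structure alteration
    if config.migration_pairing:
        sources: list[tuple[int, str]] = []  # (labeled index, letter)
        for k, le in enumerate(labeled):
            if le.edit.op == "del" and le.label == "OIL":
                sources.append((k, le.edit.t_units[0]))
            elif le.edit.op == "sub":
                released = _is_digraph_release(le.edit.t_units[0],
                                               le.edit.r_units[0])
                if released is not None:
                    sources.append((k, released))
        consumed: set[int] = set()
        for k, le in enumerate(labeled):
            if le.edit.op != "ins":
                continue
            letter = le.edit.r_units[0]
            for sk, src_letter in sources:
                if sk in consumed or sk == k:
                    continue
                if _same_migration_class(src_letter, letter):
                    labeled[k] = LabeledEdit(le.edit, "ASS",
                                             "letter displaced across syllables")
                    labeled[sk] = LabeledEdit(labeled[sk].edit, None,
                                              "displacement source")
                    consumed.add(sk)
                    break

    # third pass: word-segmentation layer
    for bop in boundary_diff(t_gs, r_gs, script, target):
        labeled.append(LabeledEdit(bop, "USW",
                                   "token boundary joined" if bop.op == "join"
                                   else "token boundary split"))

    labels = {le.label for le in labeled if le.label is not None}
    return Classification(target, norm, False, _sort_labels(labels),
                          tuple(labeled), script, script.similarity)
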