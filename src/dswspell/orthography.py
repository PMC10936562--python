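"""Brazilian Portuguese grapheme inventory, normalization and a rule-based
grapheme-to-phoneme (G2P) layer.

The G2P table is a broad, reading-direction transcription: it is exactly rich
enough to decide whether two spellings of a dictation target sound the same
(e.g. <agenti> preserves the reading of "a gente" while <comeco> does not
preserve "começou").  Dialect conventions follow Brazilian Portuguese with
final unstressed vowel raising (e → /i/, o → /u/), nasal codas neutralized to
the archiphoneme /N/ and the word-final sibilant neutralized to /S/.

Phoneme symbols are plain strings; nasal vowels are single symbols ("aN",
"oN") so that every non-silent grapheme unit maps to exactly one symbol.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "DIGRAPHS",
    "GraphemeUnit",
    "GraphemeString",
    "PhonemeString",
    "TargetWord",
    "OrthoRule",
    "RuleClass",
    "InvalidResponseError",
    "NonAlphabeticError",
    "normalize_form",
    "segment_graphemes",
    "g2p",
    "phoneme_of_unit",
    "phonologically_equivalent",
    "lookup_rules",
    "strip_accents",
    "base_letters",
]

# Digraphs are single functional units: <rr> and <ss> double letters, the
# consonant digraphs <ch lh nh>, the velar digraphs <qu gu> and the rarer
# sibilant clusters that spell /s/.
DIGRAPHS = ("rr", "ss", "ch", "lh", "nh", "qu", "gu", "sc", "sç", "xc", "xs")

VOWELS = set("aeiouáéíóúâêôàãõ")
_ACUTE_CIRC = {"á": "a", "é": "e", "í": "i", "ó": "o", "ú": "u",
               "â": "a", "ê": "e", "ô": "o", "à": "a"}
_TILDE = {"ã": "a", "õ": "o"}
ALPHABET = set("abcdefghijklmnopqrstuvwxyzç") | set(_ACUTE_CIRC) | set(_TILDE)

SIBILANT_UNITS = {"s", "ss", "c", "ç", "sc", "sç", "xc", "xs", "z", "x"}
SIBILANT_PHONEMES = {"s", "z", "S"}


class InvalidResponseError(ValueError):
    """Blank or whitespace-only written form."""


class NonAlphabeticError(ValueError):
    """Written form contains characters outside the Portuguese alphabet."""


class RuleClass(str, Enum):
    CONTEXTUAL = "contextual"
    MORPHOLOGICAL = "morphological"
    LEXICAL = "lexical"


@dataclass(frozen=True)
class GraphemeUnit:
    surface: str
    kind: str  # "simple" | "digraph"
    index: int

    def __post_init__(self):
        assert self.kind == ("digraph" if self.surface in DIGRAPHS else "simple")


@dataclass(frozen=True)
class GraphemeString:
    units: tuple[GraphemeUnit, ...]
    spaces: frozenset[int] = frozenset()  # boundary AFTER unit index i-1, i.e. before unit i

    def surfaces(self) -> tuple[str, ...]:
        return tuple(u.surface for u in self.units)

    def to_text(self) -> str:
        out = []
        for i, u in enumerate(self.units):
            if i in self.spaces:
                out.append(" ")
            out.append(u.surface)
        return "".join(out)

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class PhonemeString:
    symbols: tuple[str, ...]

    def __eq__(self, other):
        return isinstance(other, PhonemeString) and self.symbols == other.symbols

    def __hash__(self):
        return hash(self.symbols)


@dataclass(frozen=True)
class OrthoRule:
    rule_id: str
    rule_class: RuleClass
    licensed_graphemes: frozenset[str]
    description: str = ""


@dataclass(frozen=True)
class TargetWord:
    """One Dyslexic Sight Words lexicon entry.

    ``syllables`` are spans over grapheme-unit indices of the despaced unit
    sequence; ``stress_index`` is the 0-based index of the stressed syllable.
    ``stress_kind`` is oxytone / paroxytone / proparoxytone.
    """

    word_id: int
    form: str
    gloss: str
    syllables: tuple[tuple[int, int], ...]  # (start, stop) half-open unit spans
    stress_index: int
    multiword: bool = False
    verb_past: bool = False  # simple-past form: final /w/ is the morpheme <u>
    verb_infinitive: bool = False
    x_reads: Optional[str] = None  # lexical override for <x> ("z")
    slot_rules: tuple[tuple[int, str], ...] = ()  # (unit index, rule_id)

    @property
    def stress_kind(self) -> str:
        last = len(self.syllables) - 1
        if self.stress_index == last:
            return "oxytone"
        if self.stress_index == last - 1:
            return "paroxytone"
        return "proparoxytone"

    def graphemes(self) -> GraphemeString:
        return segment_graphemes(normalize_form(self.form))

    def stressed_nucleus(self) -> int:
        """Unit index of the stressed syllable's vowel nucleus."""
        start, stop = self.syllables[self.stress_index]
        units = self.graphemes().surfaces()
        span = [i for i in range(start, stop) if units[i] in VOWELS or units[i] in _TILDE]
        # nucleus = the accented vowel if present, else the first vowel
        for i in span:
            if units[i] in _ACUTE_CIRC or units[i] in _TILDE:
                return i
        # falling diphthong: nucleus is the first vowel unless the syllable is
        # a rising one like "iu" where stress data places it on the first too
        return span[0] if span else start

    def syllable_of(self, unit_index: int) -> int:
        for k, (a, b) in enumerate(self.syllables):
            if a <= unit_index < b:
                return k
        raise IndexError(unit_index)


def normalize_form(raw: str) -> str:
    """Lowercase, NFC-compose, trim and collapse internal whitespace."""
    if raw is None:
        raise InvalidResponseError("missing written form")
    text = unicodedata.normalize("NFC", raw).lower().strip()
    text = " ".join(text.split())
    if not text:
        raise InvalidResponseError("blank written form")
    return text


def segment_graphemes(form: str) -> GraphemeString:
    """Maximal-munch left-to-right tokenization against the digraph inventory.

    Spaces are recorded as inter-token boundaries, never as units.
    """
    units: list[GraphemeUnit] = []
    spaces: set[int] = set()
    i = 0
    while i < len(form):
        ch = form[i]
        if ch == " ":
            spaces.add(len(units))
            i += 1
            continue
        if ch not in ALPHABET:
            raise NonAlphabeticError(f"non-alphabetic character {ch!r} in {form!r}")
        two = form[i:i + 2]
        # <sc>/<xc> spell a single /s/ — and <gu> the digraph /g/ — only
        # before a front vowel (contrast "aguda", where <u> is a full vowel)
        if two in ("sc", "xc", "gu"):
            after = form[i + 2] if i + 2 < len(form) else ""
            if not after or strip_accents(after) not in "ei":
                two = ""
        if two in DIGRAPHS:
            units.append(GraphemeUnit(two, "digraph", len(units)))
            i += 2
        else:
            units.append(GraphemeUnit(ch, "simple", len(units)))
            i += 1
    return GraphemeString(tuple(units), frozenset(spaces))


def strip_accents(s: str) -> str:
    """Remove acute/circumflex/grave and tilde; keep ç."""
    return "".join(_ACUTE_CIRC.get(c, _TILDE.get(c, c)) for c in s)


def base_letters(s: str) -> str:
    """Letters with acute/circumflex removed but tilde KEPT (the tilde is a
    nasalization marker, not a stress accent)."""
    return "".join(_ACUTE_CIRC.get(c, c) for c in s)


def _is_vowel(surface: Optional[str]) -> bool:
    return surface is not None and surface[0] in VOWELS


def _stress_nucleus_heuristic(surfaces: Sequence[str]) -> Optional[int]:
    """Default stress position for forms without lexicon metadata: an accented
    vowel wins; otherwise words ending in a/e/o (±s/m) are paroxytone-ish, so
    the stressed vowel is the second-to-last vowel; else the last vowel."""
    vowel_idx = [i for i, s in enumerate(surfaces) if _is_vowel(s)]
    if not vowel_idx:
        return None
    for i, s in enumerate(surfaces):
        if s in _ACUTE_CIRC or s in _TILDE:
            return i
    last = surfaces[-1]
    paroxytone = last in "aeo" or (last in "sm" and len(surfaces) > 1 and surfaces[-2] in "aeo")
    if paroxytone and len(vowel_idx) >= 2:
        return vowel_idx[-2]
    return vowel_idx[-1]


def phoneme_of_unit(surfaces: Sequence[str], i: int,
                    word_meta: Optional[TargetWord] = None,
                    stress_nucleus: Optional[int] = None) -> Optional[str]:
    """Broad phoneme of the unit at ``i`` given its despaced context.

    Returns None for silent units (word-initial <h>).  ``stress_nucleus``
    (unit index of the stressed vowel) overrides the heuristic; when
    ``word_meta`` is given its stress metadata is used.
    """
    u = surfaces[i]
    prev = surfaces[i - 1] if i > 0 else None
    nxt = surfaces[i + 1] if i + 1 < len(surfaces) else None
    last = i == len(surfaces) - 1
    first = i == 0
    if stress_nucleus is None:
        if word_meta is not None:
            stress_nucleus = word_meta.stressed_nucleus()
        else:
            stress_nucleus = _stress_nucleus_heuristic(surfaces)

    front = _is_vowel(nxt) and strip_accents(nxt)[0] in "ei"

    if u == "h":
        return None if first else "h"
    if u in ("ss", "sc", "sç", "xc", "xs", "ç"):
        return "s"
    if u == "s":
        if _is_vowel(prev) and _is_vowel(nxt):
            return "z"
        if last or not _is_vowel(nxt):
            return "S"
        return "s"
    if u == "z":
        return "S" if last else "z"
    if u == "c":
        return "s" if front else "k"
    if u == "qu":
        # /k/ before e,i; /kw/ before a,o — both carry the velar /k/; keep
        # the glide distinction so <cuado> does not equal <quando>
        return "k" if front else "kw"
    if u == "q":
        return "k"
    if u == "gu":
        return "g" if front else "gw"
    if u == "g":
        return "Z" if front else "g"  # Z = /ʒ/
    if u == "j":
        return "Z"
    if u in ("ch", "x"):
        if u == "x" and word_meta is not None and word_meta.x_reads:
            return word_meta.x_reads
        return "X"  # X = /ʃ/
    if u == "lh":
        return "L"  # /ʎ/
    if u == "nh":
        return "J"  # /ɲ/
    if u == "rr":
        return "R"
    if u == "r":
        return "R" if first else "r"
    if u == "l":
        # coda /l/ vocalizes to the glide /w/ in Brazilian Portuguese
        return "w" if (last or not _is_vowel(nxt)) else "l"
    if u in ("m", "n"):
        # coda (word-final or before a consonant): nasal archiphoneme
        if last or not _is_vowel(nxt):
            return "N"
        return u
    if u in _TILDE:
        return _TILDE[u] + "N"  # nasal vowel, single symbol
    if u[0] in VOWELS:
        v = strip_accents(u)
        accented = u in _ACUTE_CIRC
        # glide: unstressed high/back vowel directly after a vowel
        if v in "iuo" and not accented and i != stress_nucleus and _is_vowel(prev):
            return "j" if v == "i" else "w"
        # final unstressed vowel raising
        if v in "eo" and not accented and i != stress_nucleus:
            if last:
                return "i" if v == "e" else "u"
        return v
    # remaining consonants read as themselves
    return u


def g2p(gs: GraphemeString, word_meta: Optional[TargetWord] = None) -> PhonemeString:
    surfaces = gs.surfaces()
    nucleus = word_meta.stressed_nucleus() if word_meta is not None else None
    out = []
    for i in range(len(surfaces)):
        p = phoneme_of_unit(surfaces, i, word_meta, stress_nucleus=nucleus)
        if p is not None:
            out.append(p)
    return PhonemeString(tuple(out))


def phonologically_equivalent(a: str, b: str,
                              word_meta: Optional[TargetWord] = None) -> bool:
    """True iff the two forms read identically under the G2P table.

    ``word_meta`` stress metadata applies to ``a``'s slots (the target); the
    lexical x→/z/ override applies to any <x> in either form.  Token
    boundaries carry no sound, so a hyposegmented join is equivalent.
    """
    ga = segment_graphemes(normalize_form(a))
    gb = segment_graphemes(normalize_form(b))
    pa = g2p(ga, word_meta)
    # the response does not inherit the target's stress *index* (lengths may
    # differ) — use the default stress heuristic but keep lexical overrides
    sb = gb.surfaces()
    nb = _stress_nucleus_heuristic(sb)
    pb = PhonemeString(tuple(
        p for p in (phoneme_of_unit(sb, i, word_meta, stress_nucleus=nb)
                    for i in range(len(sb))) if p is not None))
    return pa == pb


# ---------------------------------------------------------------------------
# Orthographic rule registry (consumed by classifier.lookup / labeling)
# ---------------------------------------------------------------------------

RULES = {
    "nasal-before-pb": OrthoRule(
        "nasal-before-pb", RuleClass.CONTEXTUAL, frozenset({"m"}),
        "nasal coda before <p>/<b> must be written <m>"),
    "nasal-internal": OrthoRule(
        "nasal-internal", RuleClass.CONTEXTUAL, frozenset({"n"}),
        "internal nasal coda before other consonants is written <n>"),
    "nasal-final": OrthoRule(
        "nasal-final", RuleClass.LEXICAL, frozenset({"m"}),
        "word-final nasal is conventionally <m>; the choice m/n is opaque"),
    "digraph-rr": OrthoRule(
        "digraph-rr", RuleClass.CONTEXTUAL, frozenset({"rr"}),
        "intervocalic strong /R/ is the digraph <rr>"),
    "velar-digraph-ei": OrthoRule(
        "velar-digraph-ei", RuleClass.CONTEXTUAL, frozenset({"qu", "gu"}),
        "/k/,/g/ before <e>,<i> require the digraphs <qu>,<gu>"),
    "past-tense-semivowel": OrthoRule(
        "past-tense-semivowel", RuleClass.MORPHOLOGICAL, frozenset({"u"}),
        "simple-past final /w/ is the morpheme <u>"),
    "final-semivowel": OrthoRule(
        "final-semivowel", RuleClass.LEXICAL, frozenset({"l", "u", "o"}),
        "final /w/ in non-verbs can be <l>, <u> or <o>"),
    "posttonic-final-vowel": OrthoRule(
        "posttonic-final-vowel", RuleClass.CONTEXTUAL, frozenset({"e", "o"}),
        "paroxytone final unstressed /i/,/u/ are written <e>,<o>"),
    "pretonic-vowel": OrthoRule(
        "pretonic-vowel", RuleClass.LEXICAL, frozenset({"e", "i", "o", "u"}),
        "pre-stress unstressed /i/,/u/ spelling is opaque"),
    "g-j-before-ei": OrthoRule(
        "g-j-before-ei", RuleClass.LEXICAL, frozenset({"g", "j"}),
        "/Z/ before <e>,<i> is arbitrarily <g> or <j>"),
    "j-before-aou": OrthoRule(
        "j-before-aou", RuleClass.CONTEXTUAL, frozenset({"j"}),
        "/Z/ before <a>,<o>,<u> is written <j>"),
    "sibilant-lexical": OrthoRule(
        "sibilant-lexical", RuleClass.LEXICAL,
        frozenset({"s", "ss", "c", "ç", "sc", "sç", "xc", "xs", "z", "x"}),
        "/s/ and /z/ have many graphemic representations; the choice is opaque"),
    "x-position": OrthoRule(
        "x-position", RuleClass.CONTEXTUAL, frozenset({"x"}),
        "/X/ after a diphthong or the initial syllable <en> is written <x>"),
    "tilde-nasal": OrthoRule(
        "tilde-nasal", RuleClass.CONTEXTUAL, frozenset({"ã", "õ"}),
        "the tilde marks nasalization"),
    "disse-ss": OrthoRule(
        "disse-ss", RuleClass.MORPHOLOGICAL, frozenset({"ss"}),
        "past forms of 'dizer' keep the morphological <ss>"),
    "semivowel-coda": OrthoRule(
        "semivowel-coda", RuleClass.LEXICAL, frozenset({"l", "u"}),
        "internal coda /w/ can be <l> or <u>"),
}


def _has_diphthong_before(surfaces: Sequence[str], i: int) -> bool:
    return i >= 2 and _is_vowel(surfaces[i - 1]) and _is_vowel(surfaces[i - 2])


def lookup_rules(gs: GraphemeString, position: int,
                 word_meta: Optional[TargetWord] = None) -> list[OrthoRule]:
    """All orthographic rules whose context matches the slot, most specific
    first (morphological > contextual > lexical)."""
    surfaces = gs.surfaces()
    if not 0 <= position < len(surfaces):
        raise IndexError(position)
    u = surfaces[position]
    prev = surfaces[position - 1] if position > 0 else None
    nxt = surfaces[position + 1] if position + 1 < len(surfaces) else None
    last = position == len(surfaces) - 1
    front = _is_vowel(nxt) and strip_accents(nxt)[0] in "ei"
    found: list[OrthoRule] = []

    if word_meta is not None:
        for idx, rid in word_meta.slot_rules:
            if idx == position:
                found.append(RULES[rid])

    if u in ("m", "n") and (last or not _is_vowel(nxt)):
        if nxt in ("p", "b"):
            found.append(RULES["nasal-before-pb"])
        elif last:
            found.append(RULES["nasal-final"])
        else:
            found.append(RULES["nasal-internal"])
    if u in _TILDE:
        found.append(RULES["tilde-nasal"])
    if u == "rr":
        found.append(RULES["digraph-rr"])
    if u in ("qu", "gu") and front:
        found.append(RULES["velar-digraph-ei"])
    if u in ("l", "u", "o") and last and _is_vowel(prev):
        if word_meta is not None and word_meta.verb_past:
            found.append(RULES["past-tense-semivowel"])
        else:
            found.append(RULES["final-semivowel"])
    elif u in ("l", "u") and not last and _is_vowel(prev) and not _is_vowel(nxt):
        found.append(RULES["semivowel-coda"])
    if u in ("e", "o") and last and word_meta is not None \
            and word_meta.stress_kind == "paroxytone":
        found.append(RULES["posttonic-final-vowel"])
    if u in ("e", "i", "o", "u") and word_meta is not None \
            and position < word_meta.stressed_nucleus():
        found.append(RULES["pretonic-vowel"])
    if u in ("g", "j"):
        if front:
            found.append(RULES["g-j-before-ei"])
        elif u == "j":
            found.append(RULES["j-before-aou"])
    if u in SIBILANT_UNITS and phoneme_of_unit(surfaces, position, word_meta) in SIBILANT_PHONEMES:
        found.append(RULES["sibilant-lexical"])
    if u in ("x", "ch"):
        if _has_diphthong_before(surfaces, position) or \
                (position == 2 and surfaces[0] == "e" and surfaces[1] == "n"):
            found.append(RULES["x-position"])

    order = {RuleClass.MORPHOLOGICAL: 0, RuleClass.CONTEXTUAL: 1, RuleClass.LEXICAL: 2}
    found.sort(key=lambda r: order[r.rule_class])
    # de-duplicate, keep first occurrence
    seen, out = set(), []
    for r in found:
        if r.rule_id not in seen:
            seen.add(r.rule_id)
            out.append(r)
    return out
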