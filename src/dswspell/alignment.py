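"""Grapheme-unit-level alignment between a dictation target and a written
response.

The aligner is a Damerau-style dynamic program over grapheme UNITS (digraphs
count as one unit).  Costs: match 0, substitution 1 (0.5 when the two units
are phonologically equivalent in their contexts), insertion/deletion 1,
adjacent transposition 1.  Ties are broken by (a) preferring alignments with
more transpositions, then (b) fewer "unrelated" substitutions — substitutions
between units that share no base letter, sound, homorganic pairing or
grapheme family — then (c) a fixed traceback priority (transposition, match,
substitution, deletion, insertion), which yields a leftmost-normalized script.

Token boundaries carry no units; ``boundary_diff`` maps each space through
the unit alignment and emits ``join``/``split`` ops for the classifier's
word-segmentation layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .orthography import (
    DIGRAPHS,
    VOWELS,
    SIBILANT_UNITS,
    GraphemeString,
    TargetWord,
    _is_vowel,
    _stress_nucleus_heuristic,
    base_letters,
    phoneme_of_unit,
)

__all__ = ["EditOp", "EditScript", "align", "boundary_diff", "apply_script",
           "HOMORGANIC_PAIRS", "VELAR_UNITS", "units_equivalent",
           "units_related"]

# Voiced/voiceless pairs articulated at the same place; swapping one for the
# other changes the reading (the core "natural" substitution pattern).
HOMORGANIC_PAIRS = frozenset({
    frozenset({"p", "b"}), frozenset({"t", "d"}), frozenset({"f", "v"}),
    frozenset({"c", "g"}), frozenset({"s", "z"}), frozenset({"x", "j"}),
})
VELAR_UNITS = frozenset({"c", "q", "qu", "g", "gu"})
_NASALS = frozenset({"m", "n"})
_RHOTICS = frozenset({"r", "rr"})
SEMIVOWEL_LETTERS = frozenset({"l", "u", "o"})


@dataclass(frozen=True)
class EditOp:
    """One aligned edit.  Spans are half-open unit index ranges; ``join`` and
    ``split`` ops use the span start as the boundary position."""

    op: str  # match | sub | del | ins | transpose | join | split
    t_start: int
    t_stop: int
    r_start: int
    r_stop: int
    t_units: tuple[str, ...]
    r_units: tuple[str, ...]
    cost: float = 0.0


@dataclass(frozen=True)
class EditScript:
    ops: tuple[EditOp, ...]
    cost: float
    similarity: float
    t_units: tuple[str, ...]
    r_units: tuple[str, ...]


def units_equivalent(t_surfaces: Sequence[str], i: int,
                     r_surfaces: Sequence[str], j: int,
                     word_meta: Optional[TargetWord] = None,
                     t_nucleus: Optional[int] = None,
                     r_nucleus: Optional[int] = None) -> bool:
    """Whether substituting the target unit at ``i`` by the response unit at
    ``j`` preserves the word's sound.

    With lexicon metadata this is the classifier's judgment (the
    substitution falls in the arbitrary-spelling class); without it, plain
    phoneme equality under the G2P table.
    """
    if word_meta is not None and t_nucleus is not None:
        from .classifier import substitution_sound_preserving
        return substitution_sound_preserving(
            t_surfaces, i, r_surfaces, j, word_meta, t_nucleus, r_nucleus)
    pt = phoneme_of_unit(t_surfaces, i, word_meta, stress_nucleus=t_nucleus)
    pr = phoneme_of_unit(r_surfaces, j, word_meta, stress_nucleus=r_nucleus)
    return pt == pr


def _is_digraph_release(t_unit: str, r_unit: str) -> bool:
    return t_unit in DIGRAPHS and len(r_unit) == 1 and r_unit in t_unit


def units_related(t_unit: str, r_unit: str, equivalent: bool) -> bool:
    """Whether a substitution pairs 'plausibly related' units — used only as
    a tie-break so that e.g. <m>→<b> + <p>→<l> never beats omit-<m> +
    <p>→<b> at equal cost."""
    if equivalent:
        return True
    if base_letters(t_unit) == base_letters(r_unit):
        return True
    tv, rv = t_unit[0] in VOWELS, r_unit[0] in VOWELS
    if tv and rv:
        return True
    if tv != rv:
        return False
    pair = frozenset({t_unit, r_unit})
    if pair in HOMORGANIC_PAIRS:
        return True
    if t_unit in SIBILANT_UNITS and r_unit in SIBILANT_UNITS:
        return True
    if t_unit in VELAR_UNITS and r_unit in VELAR_UNITS:
        return True
    if t_unit in _NASALS and r_unit in _NASALS:
        return True
    if t_unit in _RHOTICS and r_unit in _RHOTICS:
        return True
    if _is_digraph_release(t_unit, r_unit) or _is_digraph_release(r_unit, t_unit):
        return True
    return False


def align(target: GraphemeString, response: GraphemeString,
          word_meta: Optional[TargetWord] = None) -> EditScript:
    """Optimal edit script between the despaced unit sequences.

    Applying the script to the target units reproduces the response units
    exactly (see ``apply_script``); token boundaries are handled separately
    by ``boundary_diff``.
    """
    t = target.surfaces()
    r = response.surfaces()
    n, m = len(t), len(r)
    t_nuc = word_meta.stressed_nucleus() if word_meta is not None else \
        _stress_nucleus_heuristic(t)
    r_nuc = _stress_nucleus_heuristic(r)

    equiv = [[units_equivalent(t, i, r, j, word_meta, t_nuc, r_nuc)
              for j in range(m)] for i in range(n)]

    BIG = (float("inf"), 0, 0)
    # DP value: (cost, -transpositions, unrelated substitutions)
    D = [[BIG] * (m + 1) for _ in range(n + 1)]
    D[0][0] = (0.0, 0, 0)
    for i in range(1, n + 1):
        D[i][0] = (float(i), 0, 0)
    for j in range(1, m + 1):
        D[0][j] = (float(j), 0, 0)

    def _cands(i: int, j: int):
        """Candidate (value, op) moves into cell (i, j), priority order."""
        out = []
        if i >= 2 and j >= 2 and t[i - 2] == r[j - 1] and t[i - 1] == r[j - 2] \
                and t[i - 2] != t[i - 1]:
            c, tr, u = D[i - 2][j - 2]
            out.append(((c + 1.0, tr - 1, u), "transpose"))
        if i >= 1 and j >= 1 and t[i - 1] == r[j - 1]:
            c, tr, u = D[i - 1][j - 1]
            out.append(((c, tr, u), "match"))
        if i >= 1 and j >= 1 and t[i - 1] != r[j - 1]:
            e = equiv[i - 1][j - 1]
            c, tr, u = D[i - 1][j - 1]
            bad = 0 if units_related(t[i - 1], r[j - 1], e) else 1
            out.append(((c + (0.5 if e else 1.0), tr, u + bad), "sub"))
        if i >= 1:
            c, tr, u = D[i - 1][j]
            out.append(((c + 1.0, tr, u), "del"))
        if j >= 1:
            c, tr, u = D[i][j - 1]
            out.append(((c + 1.0, tr, u), "ins"))
        return out

    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            D[i][j] = min(v for v, _ in _cands(i, j))

    # traceback (priority order = _cands order)
    ops: list[EditOp] = []
    i, j = n, m
    while i > 0 or j > 0:
        val = D[i][j]
        for v, op in _cands(i, j):
            if v != val:
                continue
            if op == "transpose":
                ops.append(EditOp("transpose", i - 2, i, j - 2, j,
                                  (t[i - 2], t[i - 1]), (r[j - 2], r[j - 1]), 1.0))
                i, j = i - 2, j - 2
            elif op == "match":
                ops.append(EditOp("match", i - 1, i, j - 1, j,
                                  (t[i - 1],), (r[j - 1],), 0.0))
                i, j = i - 1, j - 1
            elif op == "sub":
                cost = 0.5 if equiv[i - 1][j - 1] else 1.0
                ops.append(EditOp("sub", i - 1, i, j - 1, j,
                                  (t[i - 1],), (r[j - 1],), cost))
                i, j = i - 1, j - 1
            elif op == "del":
                ops.append(EditOp("del", i - 1, i, j, j, (t[i - 1],), (), 1.0))
                i -= 1
            else:
                ops.append(EditOp("ins", i, i, j - 1, j, (), (r[j - 1],), 1.0))
                j -= 1
            break
        else:  # pragma: no cover - DP invariant
            raise AssertionError("traceback failed")
    ops.reverse()

    cost = D[n][m][0]
    denom = max(n, m)
    similarity = 1.0 if denom == 0 else max(0.0, 1.0 - cost / denom)
    return EditScript(tuple(ops), cost, similarity, t, r)


def apply_script(script: EditScript) -> tuple[str, ...]:
    """Replay the script over the target units; must reproduce the response
    units exactly."""
    out: list[str] = []
    for op in script.ops:
        if op.op == "match":
            out.extend(op.t_units)
        elif op.op in ("sub", "ins"):
            out.extend(op.r_units)
        elif op.op == "transpose":
            out.extend(op.r_units)
        elif op.op == "del":
            pass
    return tuple(out)


def boundary_diff(target: GraphemeString, response: GraphemeString,
                  script: Optional[EditScript] = None,
                  word_meta: Optional[TargetWord] = None) -> tuple[EditOp, ...]:
    """Token-boundary edits: ``join`` for a target space missing from the
    response, ``split`` for a response space with no target counterpart.

    Boundary positions are mapped through the unit alignment so that unit
    edits do not shift the comparison.
    """
    if script is None:
        script = align(target, response, word_meta)
    # prefix correspondence: after consuming p target units, how many
    # response units are consumed (and vice versa)
    t2r: dict[int, int] = {0: 0}
    r2t: dict[int, int] = {0: 0}
    ti = ri = 0
    for op in script.ops:
        ti = op.t_stop
        ri = op.r_stop
        t2r[ti] = ri
        r2t[ri] = ti

    def _map(pos: int, table: dict[int, int]) -> int:
        if pos in table:
            return table[pos]
        below = max(k for k in table if k < pos)
        above = min(k for k in table if k > pos)
        # inside an op: interpolate, clamped to the op's span
        return min(table[below] + (pos - below), table[above])

    out: list[EditOp] = []
    for p in sorted(target.spaces):
        q = _map(p, t2r)
        if q not in response.spaces:
            out.append(EditOp("join", p, p, q, q, (), (), 0.0))
    for q in sorted(response.spaces):
        p = _map(q, r2t)
        if p not in target.spaces:
            out.append(EditOp("split", p, p, q, q, (), (), 0.0))
    return tuple(out)
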