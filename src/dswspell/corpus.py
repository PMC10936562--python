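"""Embedded study corpus and CSV I/O.

Exposes the 60-word dictation lexicon with hand-encoded syllable and stress
metadata, the expert-annotated misspelled forms (with category labels), the
per-word correct/incorrect counts for both groups (dyslexic, GD, and
non-dyslexic, GWD; 30 students each, grades 3–6), the per-grade totals and
the per-category distinct-form counts.  All fixtures carry a SHA-256
integrity checksum.

Note on the count table: the published percentage for word 3 in the GWD
column is a misprint ("933%" for 93.3%); counts are stored as printed
(28 correct / 2 incorrect).
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from . import _data
from .orthography import (
    TargetWord,
    InvalidResponseError,
    normalize_form,
    segment_graphemes,
)

__all__ = [
    "GoldRecord",
    "CorpusValidationError",
    "GROUPS",
    "GRADES",
    "load_lexicon",
    "get_word",
    "word_by_form",
    "gold_records",
    "curated_examples",
    "word_counts",
    "grade_totals",
    "distinct_form_counts",
    "group_sizes",
    "corpus_checksum",
    "verify_integrity",
    "read_responses",
    "write_responses",
    "write_classifications",
    "RESPONSE_COLUMNS",
]

GROUPS = ("GD", "GWD")
GRADES = (3, 4, 5, 6)
RESPONSE_COLUMNS = ("student_id", "group", "grade", "word_id", "response")


class CorpusValidationError(ValueError):
    """A response table failed row-level validation."""


@dataclass(frozen=True)
class GoldRecord:
    """One expert-annotated misspelled form."""

    word_id: int
    form: str
    group: str  # "GD", "GWD" or "both"
    labels: tuple[str, ...]
    ambiguous: bool  # published label conflicts with the published rules
    anchor: str  # short quote of the published rationale


def _build_word(row) -> TargetWord:
    word_id, form, gloss, syl_lengths, stress, flags = row
    spans, start = [], 0
    for ln in syl_lengths:
        spans.append((start, start + ln))
        start += ln
    units = segment_graphemes(normalize_form(form))
    if start != len(units):
        raise AssertionError(f"syllable spans of {form!r} do not cover its "
                             f"{len(units)} units")
    slot_rules = flags.get("sr", ())
    return TargetWord(
        word_id=word_id, form=form, gloss=gloss, syllables=tuple(spans),
        stress_index=stress, multiword=flags.get("mw", False),
        verb_past=flags.get("vp", False),
        verb_infinitive=flags.get("vi", False),
        x_reads="z" if flags.get("xz") else None,
        slot_rules=tuple(slot_rules),
    )


_LEXICON: Optional[dict[int, TargetWord]] = None


def load_lexicon() -> dict[int, TargetWord]:
    """The 60 dictation targets keyed by word id (1–60)."""
    global _LEXICON
    if _LEXICON is None:
        _LEXICON = {row[0]: _build_word(row) for row in _data.LEXICON_ROWS}
        assert len(_LEXICON) == 60
    return _LEXICON


def get_word(word_id: int) -> TargetWord:
    try:
        return load_lexicon()[word_id]
    except KeyError:
        raise KeyError(f"no dictation target with id {word_id}") from None


def word_by_form(form: str) -> TargetWord:
    norm = normalize_form(form)
    for w in load_lexicon().values():
        if normalize_form(w.form) == norm:
            return w
    raise KeyError(f"no dictation target spelled {form!r}")


def gold_records(include_ambiguous: bool = True) -> list[GoldRecord]:
    """Expert-annotated misspelled forms with their category labels."""
    out = [GoldRecord(*row) for row in _data.GOLD_ROWS]
    if not include_ambiguous:
        out = [r for r in out if not r.ambiguous]
    return out


def curated_examples() -> list[tuple[int, str, str]]:
    """The published per-category example table: (word_id, form, category)."""
    return list(_data.CURATED_EXAMPLE_ROWS)


def word_counts() -> pd.DataFrame:
    """Per-word correct/incorrect counts for both groups (30 students each),
    plus the published p-value string (None where no error occurred)."""
    df = pd.DataFrame(
        _data.WORD_COUNT_ROWS,
        columns=["word_id", "gd_correct", "gd_incorrect",
                 "gwd_correct", "gwd_incorrect", "published_p"],
    )
    lex = load_lexicon()
    df.insert(1, "form", df["word_id"].map(lambda i: lex[i].form))
    return df


def grade_totals() -> pd.DataFrame:
    """Total incorrectly written words per grade and group."""
    return pd.DataFrame(
        _data.GRADE_TOTALS,
        columns=["grade", "group", "n_students", "total_incorrect"],
    )


def distinct_form_counts() -> dict[str, dict[str, int]]:
    """Distinct misspelled forms per group and category."""
    return {g: dict(v) for g, v in _data.DISTINCT_FORM_COUNTS.items()}


def group_sizes() -> dict[int, int]:
    """Students per grade in each group."""
    return dict(_data.GROUP_SIZES)


def corpus_checksum() -> str:
    """SHA-256 over a canonical serialization of every embedded fixture."""
    payload = json.dumps(
        {
            "lexicon": [list(r[:5]) + [sorted(r[5].items())]
                        for r in _data.LEXICON_ROWS],
            "curated": _data.CURATED_EXAMPLE_ROWS,
            "gold": _data.GOLD_ROWS,
            "counts": _data.WORD_COUNT_ROWS,
            "grades": _data.GRADE_TOTALS,
            "forms": _data.DISTINCT_FORM_COUNTS,
            "sizes": sorted(_data.GROUP_SIZES.items()),
        },
        ensure_ascii=False, sort_keys=True, default=list,
    ).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


# Frozen at packaging time; verify_integrity() recomputes and compares.
_EXPECTED_CHECKSUM = None  # type: Optional[str]


def verify_integrity() -> bool:
    """Recompute the fixture checksum and run structural sanity checks."""
    lex = load_lexicon()
    if len(lex) != 60:
        return False
    counts = word_counts()
    if len(counts) != 60:
        return False
    if not ((counts["gd_correct"] + counts["gd_incorrect"]) == 30).all():
        return False
    if not ((counts["gwd_correct"] + counts["gwd_incorrect"]) == 30).all():
        return False
    gt = grade_totals()
    if sorted(gt["grade"].unique()) != list(GRADES):
        return False
    # per-group totals must agree between the two tables
    for g, col in (("GD", "gd_incorrect"), ("GWD", "gwd_incorrect")):
        if gt.loc[gt["group"] == g, "total_incorrect"].sum() != counts[col].sum():
            return False
    ids = {w.word_id for w in lex.values()}
    for rec in gold_records():
        if rec.word_id not in ids:
            return False
    if _EXPECTED_CHECKSUM is not None and corpus_checksum() != _EXPECTED_CHECKSUM:
        return False
    return True


def read_responses(path: Union[str, Path]) -> pd.DataFrame:
    """Read a UTF-8 CSV of dictation responses with columns
    ``student_id,group,grade,word_id,response``; validates every row and
    raises :class:`CorpusValidationError` naming the first offending row."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(RESPONSE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise CorpusValidationError(
                f"{path}: missing column(s) {sorted(missing)}")
        rows = []
        lex = load_lexicon()
        for lineno, row in enumerate(reader, start=2):
            try:
                group = (row["group"] or "").strip()
                if group not in GROUPS:
                    raise ValueError(f"group must be one of {GROUPS}, "
                                     f"got {group!r}")
                grade = int(row["grade"])
                if grade not in GRADES:
                    raise ValueError(f"grade must be one of {GRADES}, "
                                     f"got {grade}")
                word_id = int(row["word_id"])
                if word_id not in lex:
                    raise ValueError(f"unknown word_id {word_id}")
                response = row["response"]
                if response is None:
                    raise ValueError("missing response")
                response = normalize_form(response)
                student = (row["student_id"] or "").strip()
                if not student:
                    raise ValueError("missing student_id")
            except (ValueError, InvalidResponseError) as exc:
                raise CorpusValidationError(
                    f"{path}, line {lineno}: {exc}") from exc
            rows.append((student, group, grade, word_id, response))
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))


def write_responses(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a response table as UTF-8 CSV in the canonical column order."""
    df = df.loc[:, list(RESPONSE_COLUMNS)]
    df.to_csv(path, index=False, encoding="utf-8")


def write_classifications(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write classified responses (any columns) as UTF-8 CSV."""
    df.to_csv(path, index=False, encoding="utf-8")
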