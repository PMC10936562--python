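"""End-to-end orchestration: classify a response table (observed or
simulated), build per-word 2×2 comparisons, grade summaries, per-student
totals and category tallies, and write the results out.

Two input modes:

* a response table (``student_id, group, grade, word_id, response``) — real
  or produced by :func:`dswspell.synthetic_data.simulate_dataset`;
* counts-only — no raw responses, just the embedded per-word correct/incorrect
  counts and grade totals (``run(counts_only=True)``), which reproduces the
  study-level statistics without per-student data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import analysis, corpus
from .classifier import CATEGORIES, ClassifierConfig, DEFAULT_CONFIG, classify
from .orthography import InvalidResponseError

__all__ = ["PipelineConfig", "PipelineResult", "classify_table", "run",
           "self_test"]

logger = logging.getLogger("dswspell")


@dataclass(frozen=True)
class PipelineConfig:
    """Run parameters.  ``input_path`` and ``simulate`` are mutually
    exclusive ways of obtaining a response table; with neither set the run
    is counts-only."""

    input_path: Optional[Union[str, Path]] = None
    simulate: bool = False
    seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    output_dir: Optional[Union[str, Path]] = None
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    classified: Optional[pd.DataFrame]
    word_tests: pd.DataFrame
    grade_summary: pd.DataFrame
    group_stats: dict
    category_counts: Optional[dict]

    def to_dict(self) -> dict:
        return {
            "word_tests": self.word_tests.to_dict(orient="records"),
            "grade_summary": self.grade_summary.to_dict(orient="records"),
            "group_stats": self.group_stats,
            "category_counts": self.category_counts,
        }


def classify_table(responses: pd.DataFrame,
                   config: ClassifierConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Classify every row of a response table.  Adds ``correct``,
    ``labels`` (pipe-joined) and ``similarity`` columns."""
    lex = corpus.load_lexicon()
    out = []
    for row in responses.itertuples(index=False):
        word = lex[int(row.word_id)]
        try:
            c = classify(word, row.response, config)
        except InvalidResponseError:
            out.append((False, "OTHER", 0.0))
            continue
        out.append((c.correct, "|".join(sorted(c.labels)),
                    round(c.similarity, 4)))
    res = responses.copy()
    res[["correct", "labels", "similarity"]] = pd.DataFrame(
        out, index=responses.index)
    return res


def _word_counts_from(classified: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for wid, sub in classified.groupby("word_id"):
        rec = {"word_id": int(wid)}
        for g, col in (("GD", "gd"), ("GWD", "gwd")):
            gsub = sub[sub["group"] == g]
            rec[f"{col}_correct"] = int(gsub["correct"].sum())
            rec[f"{col}_incorrect"] = int((~gsub["correct"]).sum())
        rows.append(rec)
    return pd.DataFrame(rows)


def _grade_totals_from(classified: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (grade, g), sub in classified.groupby(["grade", "group"]):
        rows.append({"grade": int(grade), "group": g,
                     "n_students": sub["student_id"].nunique(),
                     "total_incorrect": int((~sub["correct"]).sum())})
    return pd.DataFrame(rows)


def _category_counts(classified: pd.DataFrame) -> dict:
    """Distinct misspelled forms per category and group (a form counts once
    per word regardless of how many students produced it)."""
    errors = classified[~classified["correct"]]
    out = {}
    for g, sub in errors.groupby("group"):
        distinct = sub.drop_duplicates(["word_id", "response"])
        counts = {c: 0 for c in CATEGORIES}
        for labels in distinct["labels"]:
            for lab in labels.split("|"):
                if lab:
                    counts[lab] += 1
        out[g] = counts
    return out


def _group_stats(classified: Optional[pd.DataFrame],
                 counts: pd.DataFrame) -> dict:
    stats: dict = {}
    for g, col in (("GD", "gd"), ("GWD", "gwd")):
        total_inc = int(counts[f"{col}_incorrect"].sum())
        n_students = 30
        mean = total_inc / n_students
        stats[g] = {
            "total_incorrect": total_inc,
            "mean_incorrect": analysis.round_half_up(mean, 1),
            "mean_pct_of_list": analysis.truncate_pct(
                analysis.round_half_up(mean, 1), 60),
        }
    if classified is not None:
        totals = (~classified["correct"]).groupby(
            [classified["group"], classified["student_id"]]).sum()
        gd = totals.loc["GD"].to_numpy(dtype=float)
        gwd = totals.loc["GWD"].to_numpy(dtype=float)
        stats["GD"]["describe"] = analysis.describe_totals(gd)
        stats["GWD"]["describe"] = analysis.describe_totals(gwd)
        mw = analysis.mann_whitney(gd, gwd)
        stats["mann_whitney"] = {"U": mw.statistic, "p": mw.p_formatted}
        norm = analysis.ks_normality(
            pd.concat([pd.Series(gd), pd.Series(gwd)]).to_numpy())
        stats["normality"] = {"test": norm.test, "p": norm.p_formatted}
    return stats


def run(config: Optional[PipelineConfig] = None,
        counts_only: bool = False) -> PipelineResult:
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    classified = None
    if not counts_only and (config.input_path or config.simulate):
        if config.input_path and config.simulate:
            raise ValueError("input_path and simulate are mutually exclusive")
        if config.simulate:
            from .synthetic_data import simulate_dataset
            logger.info("simulating dataset (seed=%d)", config.seed)
            responses = simulate_dataset(seed=config.seed)
            responses = responses[list(corpus.RESPONSE_COLUMNS)]
        else:
            responses = corpus.read_responses(config.input_path)
        classified = classify_table(responses, config.classifier)
        counts = _word_counts_from(classified)
        gtotals = _grade_totals_from(classified)
        cat_counts = _category_counts(classified)
    else:
        counts = corpus.word_counts()
        gtotals = corpus.grade_totals()
        cat_counts = corpus.distinct_form_counts()

    word_tests = analysis.compare_all_words(counts)
    grade_summary = analysis.grade_summaries(gtotals)
    group_stats = _group_stats(classified, counts)

    result = PipelineResult(classified, word_tests, grade_summary,
                            group_stats, cat_counts)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        if classified is not None:
            corpus.write_classifications(classified,
                                         outdir / "classified.csv")
        word_tests.to_csv(outdir / "word_tests.csv", index=False)
        grade_summary.to_csv(outdir / "grade_summary.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(result.to_dict(), indent=2, ensure_ascii=False),
            encoding="utf-8")
        logger.info("wrote results to %s", outdir)
    return result


def self_test() -> dict:
    """Internal consistency checks; raises AssertionError on failure."""
    from .alignment import apply_script

    assert corpus.verify_integrity()

    gold = corpus.gold_records(include_ambiguous=False)
    lex = corpus.load_lexicon()
    contained = 0
    for rec in gold:
        word = lex[rec.word_id]
        c = classify(word, rec.form)
        if set(rec.labels) <= set(c.labels):
            contained += 1
        if c.script is not None:
            assert apply_script(c.script) == c.script.r_units
    frac = contained / len(gold)
    assert frac >= 0.9, f"gold containment {frac:.3f} < 0.9"

    t1 = corpus.curated_examples()
    ok = sum(1 for wid, form, cat in t1
             if cat in classify(lex[wid], form).labels)
    assert ok == len(t1), f"curated examples: {ok}/{len(t1)}"

    return {"gold_containment": frac, "gold_n": len(gold),
            "curated_ok": ok, "curated_n": len(t1)}
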