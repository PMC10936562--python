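"""Statistical tests and reporting conventions, cross-checked against
hand-written enumeration oracles and published values."""

import math

import numpy as np
import pytest

from dswspell import analysis, corpus


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    p0 = prob(a)
    return sum(prob(k) for k in range(c1 + 1) if prob(k) <= p0 * (1 + 1e-9))


def chi2_oracle(a, b, c, d):
    """Closed-form Pearson chi-square for a 2x2 table (no correction)."""
    from scipy.stats import chi2
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    stat = n * (a * d - b * c) ** 2 / denom
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# published per-word values
# ---------------------------------------------------------------------------

FROZEN_WORD_PS = {  # word form -> published p (3 d.p.)
    "quando": "0.024",
    "ajuda": "0.005",
    "feliz": "0.002",
    "tenho": "0.026",
    "muito": "0.052",
}


@pytest.mark.parametrize("form,expected", sorted(FROZEN_WORD_PS.items()))
def test_published_p_anchor_words(form, expected):
    df = corpus.word_counts().set_index("form")
    row = df.loc[form]
    res = analysis.compare_word(row["gd_correct"], row["gd_incorrect"],
                                row["gwd_correct"], row["gwd_incorrect"])
    assert res.p_formatted == expected


def test_all_published_p_values_reproduced():
    """compare_word reproduces every printed per-word p at 3 d.p."""
    df = corpus.word_counts()
    for _, row in df.iterrows():
        res = analysis.compare_word(row["gd_correct"], row["gd_incorrect"],
                                    row["gwd_correct"], row["gwd_incorrect"])
        if row["published_p"] is None:
            assert res is None, row["form"]
        else:
            assert res.p_formatted == row["published_p"], row["form"]


# ---------------------------------------------------------------------------
# test machinery
# ---------------------------------------------------------------------------

def test_fisher_known_values():
    assert analysis.fisher_exact_2x2([[3, 0], [0, 3]]).p_value == pytest.approx(0.1)
    assert analysis.fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)


def test_fisher_matches_oracle_sample():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if a + b + c + d == 0:
            continue
        res = analysis.fisher_exact_2x2([[a, b], [c, d]])
        assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)


def test_chi_square_matches_closed_form():
    rng = np.random.default_rng(1)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
        res = analysis.chi_square_2x2([[a, b], [c, d]])
        stat, p = chi2_oracle(a, b, c, d)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)


def test_select_test_rule():
    # all expected counts >= 5 -> chi-square
    assert analysis.select_test([[20, 10], [25, 5]]) == "chi2"
    # expected counts below 5 in >20% of cells -> fisher
    assert analysis.select_test([[29, 1], [30, 0]]) == "fisher"


def test_compare_word_degenerate():
    assert analysis.compare_word(30, 0, 30, 0) is None


def test_mann_whitney_exact():
    res = analysis.mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_ties_fall_back_to_asymptotic():
    res = analysis.mann_whitney([1, 1, 2], [2, 3, 4])
    assert 0 < res.p_value <= 1


def test_ks_normality_runs():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    res = analysis.ks_normality(x)
    assert res.test == "lilliefors" and 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# reporting conventions
# ---------------------------------------------------------------------------

def test_round_half_up():
    assert analysis.round_half_up(3.25, 1) == 3.3
    assert analysis.round_half_up(23.25, 1) == 23.3
    assert analysis.round_half_up(0.125, 2) == 0.13
    assert analysis.round_half_up(2.5, 0) == 3.0


def test_format_p_conventions():
    assert analysis.format_p(0.0523) == "0.052"
    assert analysis.format_p(0.0007) == "0.001"   # rounds up to 0.001
    assert analysis.format_p(0.0004) == "<0.001"  # rounds below 0.001


def test_truncate_pct():
    assert analysis.truncate_pct(28.3, 60) == 47.16
    assert analysis.truncate_pct(4.3, 60) == 7.16


def test_grade_summaries_published_values():
    out = analysis.grade_summaries(corpus.grade_totals())
    idx = out.set_index(["grade", "group"])
    assert idx.loc[(3, "GD"), "mean_incorrect"] == 38.7
    assert idx.loc[(4, "GD"), "mean_incorrect"] == 29.5
    assert idx.loc[(4, "GWD"), "mean_incorrect"] == 4.6
    assert idx.loc[(3, "GD"), "share_pct"] == 86.19
    assert idx.loc[(4, "GD"), "share_pct"] == 86.45
    assert idx.loc[(6, "GD"), "share_pct"] == 93.01


def test_describe_totals():
    d = analysis.describe_totals([1, 2, 3, 4])
    assert d["n"] == 4 and d["mean"] == 2.5 and d["median"] == 2.5
    assert d["min"] == 1 and d["max"] == 4
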