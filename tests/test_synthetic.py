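"""Synthetic corpus generation: determinism, operator correctness,
round-trip through the classifier."""

import numpy as np
import pytest

from dswspell import corpus, synthetic_data as sd
from dswspell.classifier import CATEGORIES, classify
from dswspell.orthography import normalize_form


@pytest.fixture(scope="module")
def lex():
    return corpus.load_lexicon()


def test_corrupt_deterministic(lex):
    w = corpus.word_by_form("professora")
    a = sd.corrupt(w, "OIL", np.random.default_rng(5))
    b = sd.corrupt(w, "OIL", np.random.default_rng(5))
    assert a == b and a != normalize_form(w.form)


def test_corrupt_not_applicable(lex):
    w = corpus.word_by_form("casa")  # no accent to strip
    with pytest.raises(sd.OperatorNotApplicableError):
        sd.corrupt(w, "AAW")


def test_corrupt_unknown_category(lex):
    with pytest.raises(ValueError):
        sd.corrupt(corpus.word_by_form("casa"), "XYZ")


def test_every_site_round_trips(lex):
    """EVERY corruption the generator can emit is classified back to its
    generating category (single-error responses)."""
    failures = []
    n = 0
    for word in lex.values():
        for cat in CATEGORIES:
            for kind, payload in sd._sites(word, cat):
                n += 1
                response = normalize_form(sd._apply_site(word, kind, payload))
                c = classify(word, response)
                if cat not in c.labels:
                    failures.append((word.form, response, cat, c.labels))
    assert n > 1000  # the operator inventory is not trivial
    assert not failures, failures[:10]


def test_other_operator_is_lexical_only(lex):
    """OTHER draws from the fixed lexical list; no gibberish."""
    for wid, form in sd.OTHER_FORMS.items():
        sites = sd._sites(lex[wid], "OTHER")
        assert sites == [("lexical", form)]
    without = [w for w in lex.values() if w.word_id not in sd.OTHER_FORMS]
    assert all(not sd._sites(w, "OTHER") for w in without)


def test_profile_validation():
    prof = sd.default_profile()
    prof.validate()
    bad_rate = sd.SimulationProfile(
        word_error_rates={"GD": {1: 1.5}, "GWD": {}},
        category_mix=prof.category_mix, group_sizes=prof.group_sizes)
    with pytest.raises(ValueError):
        bad_rate.validate()
    bad_mix = sd.SimulationProfile(
        word_error_rates=prof.word_error_rates,
        category_mix={"GD": {"NOPE": 1.0}, "GWD": {"OIL": 1.0}},
        group_sizes=prof.group_sizes)
    with pytest.raises(ValueError):
        bad_mix.validate()
    bad_multi = sd.SimulationProfile(
        word_error_rates=prof.word_error_rates,
        category_mix=prof.category_mix, group_sizes=prof.group_sizes,
        multi_error_rate=2.0)
    with pytest.raises(ValueError):
        bad_multi.validate()


def test_simulate_shape_and_determinism():
    df = sd.simulate_dataset(seed=4)
    assert len(df) == 3600  # 60 students x 60 words
    assert set(df["group"]) == {"GD", "GWD"}
    assert df["student_id"].nunique() == 60
    assert sd.simulate_dataset(seed=4).equals(df)
    assert not sd.simulate_dataset(seed=5).equals(df)


def test_simulate_respects_zero_rate_words():
    """Words with no published error in either group never get corrupted."""
    counts = corpus.word_counts()
    zero = counts[(counts["gd_incorrect"] == 0)
                  & (counts["gwd_incorrect"] == 0)]["word_id"].tolist()
    assert zero  # the published table has such words
    df = sd.simulate_dataset(seed=6)
    sub = df[df["word_id"].isin(zero)]
    assert not sub["is_error"].any()


def test_simulated_errors_differ_from_targets(lex):
    df = sd.simulate_dataset(seed=7)
    err = df[df["is_error"]]
    for row in err.sample(100, random_state=0).itertuples():
        assert row.response != normalize_form(lex[row.word_id].form)


def test_calibrated_weights_match_mix_in_expectation(lex):
    """The calibrated sampler's expected category distribution equals the
    profile mix (that is what the calibration solves for)."""
    prof = sd.default_profile()
    for group in ("GD", "GWD"):
        weights = sd._calibrated_weights(prof, group, lex)
        mix = prof.category_mix[group]
        cats = [c for c in CATEGORIES if mix.get(c, 0) > 0]
        target = np.array([mix[c] for c in cats], dtype=float)
        target /= target.sum()
        expected = np.zeros(len(cats))
        total = 0.0
        for wid, rate in prof.word_error_rates[group].items():
            if rate <= 0:
                continue
            w = np.array([weights[c] if sd._sites(lex[wid], c) else 0.0
                          for c in cats])
            expected += rate * w / w.sum()
            total += rate
        expected /= total
        assert np.abs(expected - target).max() < 1e-6, group
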