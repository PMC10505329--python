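"""Dictionary matching in review text, percent increase, and Welch tests."""

import numpy as np
import pytest

import foodlex as fl
from foodlex.corpus_analysis import (
    ReviewRecord,
    district_report,
    match_terms,
    n_words_report,
    percent_increase,
    percent_increase_conventional,
    tokenize,
    welch_t_test,
)
from foodlex.lexicon import FoodTerm, Lexicon
from foodlex.synthetic_data import generate_review_corpus

# Reference district count pairs (original, expanded) and their printed
# percent increases under the difference-over-sum statistic.
DISTRICT_COUNTS = {
    "East York": (11_838, 13_969, 8.26),
    "Etobicoke": (23_667, 27_715, 7.88),
    "North York": (50_057, 58_452, 7.74),
    "Old Toronto": (111_668, 130_185, 7.66),
    "Scarborough": (40_179, 46_991, 7.81),
    "York": (18_379, 21_763, 8.43),
}


def _lex(*surfaces, ed=2.0):
    lex = Lexicon()
    for s in surfaces:
        lex.add(FoodTerm(surface=s, ed_kcal_per_g=ed))
    return lex


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Great BBQ!!", ["great", "bbq"]),
        ("", []),
        ("sweet-potato fries", ["sweet", "potato", "fries"]),
        ("The Crème brûlée... was 10/10", ["the", "creme", "brulee", "was", "10", "10"]),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


class TestMatchTerms:
    def test_greedy_longest_match_first(self):
        lex = _lex("sweet_potato_fries", "fries")
        tokens = tokenize("the sweet potato fries were great")
        assert [s for s, _ in match_terms(tokens, lex)] == ["sweet_potato_fries"]

    def test_repetition_counts_tokens(self):
        lex = _lex("beer")
        assert len(match_terms(["beer", "beer"], lex)) == 2

    def test_empty_lexicon(self):
        assert match_terms(["beer"], Lexicon()) == []

    def test_non_overlapping_jump(self):
        lex = _lex("chocolate_chip", "chip")
        matches = match_terms(tokenize("chocolate chip chip"), lex)
        assert [s for s, _ in matches] == ["chocolate_chip", "chip"]

    def test_overlapping_mode_counts_subterms(self):
        lex = _lex("sweet_potato_fries", "fries")
        tokens = tokenize("sweet potato fries")
        got = {s for s, _ in match_terms(tokens, lex, overlapping=True)}
        assert got == {"sweet_potato_fries", "fries"}

    def test_order_stability(self):
        """Lexicon insertion order never changes the match output."""
        tokens = tokenize("cheese cake with cheese and cake")
        a = _lex("cheese_cake", "cheese", "cake")
        b = _lex("cake", "cheese", "cheese_cake")
        assert match_terms(tokens, a) == match_terms(tokens, b)

    def test_superset_lexicon_never_fewer_matches(self):
        tokens = tokenize("ramen with pork belly and extra ramen noodles")
        small = _lex("ramen")
        big = _lex("ramen", "pork_belly", "noodles")
        assert len(match_terms(tokens, big)) >= len(match_terms(tokens, small))


class TestPercentIncrease:
    @pytest.mark.parametrize("district", list(DISTRICT_COUNTS))
    def test_reference_district_values(self, district):
        """The statistic reproduces every reference district percentage."""
        o, e, printed = DISTRICT_COUNTS[district]
        assert percent_increase(o, e) == pytest.approx(printed, abs=0.01)

    @pytest.mark.parametrize(
        "o,e,printed", [(87_669, 91_383, 2.07), (10_733, 22_137, 34.69)]
    )
    def test_reference_word_length_values(self, o, e, printed):
        assert percent_increase(o, e) == pytest.approx(printed, abs=0.01)

    def test_no_change_is_zero(self):
        assert percent_increase(500, 500) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            percent_increase(0, 0)

    def test_conventional_form(self):
        assert percent_increase_conventional(100, 150) == pytest.approx(50.0)


class TestWelchTTest:
    def test_identical_samples(self):
        res = welch_t_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        """t and df match the Welch formula evaluated by hand for [1,2,3] vs [2,4,6]."""
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        va, vb = 1.0, 4.0  # sample variances
        t_hand = (2.0 - 4.0) / np.sqrt(va / 3 + vb / 3)
        df_hand = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2
        )
        res = welch_t_test(a, b)
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == pytest.approx(df_hand, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.df == pytest.approx(r2.df)
        assert r1.p == pytest.approx(r2.p)

    def test_p_consistent_with_t_and_df(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        res = welch_t_test(rng.normal(0, 1, 12), rng.normal(0.5, 1, 9))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), res.df), abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])


class TestDistrictReport:
    @pytest.fixture(scope="class")
    def corpus(self):
        old = _lex("ramen", "beer", ed=2.0)
        new = _lex("ramen", "beer", "pork_belly", "ice_cream", ed=2.0)
        filler = [f"fill{c}" for c in "abcdefghij"]
        reviews, planted = generate_review_corpus(
            new, n_outlets=20, districts=["north", "south"],
            mean_terms_per_review=6.0, filler_vocab=filler, seed=99,
        )
        return old, new, reviews, planted

    def test_planted_counts_recovered_exactly(self, corpus):
        _, new, reviews, planted = corpus
        from foodlex.corpus_analysis import count_matches

        got = count_matches(reviews, new)
        planted_total = planted.groupby("outlet_id")["count"].sum()
        for row in got.itertuples(index=False):
            assert row.total == planted_total.get(row.outlet_id, 0)
        assert got["total"].sum() == planted["count"].sum()

    def test_report_structure_and_welch(self, corpus):
        old, new, reviews, _ = corpus
        report = district_report(reviews, old, new)
        assert sorted(report["district"]) == ["north", "south"]
        assert (report["expanded_total"] >= report["original_total"]).all()
        assert report["p"].between(0, 1).all()

    def test_identical_lexicons_zero_increase(self, corpus):
        old, _, reviews, _ = corpus
        report = district_report(reviews, old, old)
        assert (report["pct_increase"].fillna(0) == 0).all()
        assert (report["t"].fillna(0) == 0).all()

    def test_single_district_single_row(self):
        lex = _lex("beer")
        reviews = [
            ReviewRecord(f"o{i}", "only", "beer is beer") for i in range(4)
        ]
        report = district_report(reviews, lex, lex)
        assert len(report) == 1

    def test_n_words_report_lengths(self, corpus):
        old, new, reviews, _ = corpus
        table = n_words_report(reviews, old, new)
        assert list(table["n_words"]) == [1, 2, 3, 4]
        assert (table["expanded_total"] >= table["original_total"]).all()
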