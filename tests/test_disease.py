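"""Multi-source score normalization, integration, top-N selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbnet.config import WeightingConfig
from herbnet.disease import (
    IntegratedScoreTable,
    compare_rankings,
    integrate_additive,
    integrate_multiplicative,
    minmax_normalize_source,
    normalize_llm_counts,
    score_qualitative_source,
    top_n,
)

CFG = WeightingConfig()


class TestNormalizeLLMCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"t1": 10, "t2": 5, "t3": 2}, {"t1": 1.0, "t2": 0.5, "t3": 0.2}),
            ({"t": 7}, {"t": 1.0}),
            ({"t1": 3, "t2": 3}, {"t1": 1.0, "t2": 1.0}),
        ],
    )
    def test_division_by_max(self, counts, expected):
        assert normalize_llm_counts(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_llm_counts({"a": 0, "b": 0})


class TestMinMaxNormalize:
    def test_zero_lifted_to_epsilon(self):
        out = minmax_normalize_source({"a": 0.0, "b": 5.0, "c": 10.0}, CFG)
        assert out == pytest.approx({"a": 1e-5, "b": 0.5, "c": 1.0})

    def test_max_is_exactly_one(self):
        out = minmax_normalize_source({"a": 3.0, "b": 17.0}, CFG)
        assert out["b"] == 1.0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize_source({"a": 2.0, "b": 2.0, "c": 2.0}, CFG)


class TestQualitativeSource:
    def test_listed_one_unlisted_epsilon(self):
        out = score_qualitative_source({"A"}, {"A", "B"}, CFG)
        assert out == {"A": 1.0, "B": 1e-20}

    def test_fully_listed(self):
        out = score_qualitative_source({"A", "B"}, {"A", "B"}, CFG)
        assert set(out.values()) == {1.0}

    def test_empty_listed(self):
        out = score_qualitative_source(set(), {"A", "B"}, CFG)
        assert set(out.values()) == {1e-20}


def frame(rows: dict[str, list]) -> pd.DataFrame:
    symbols = rows.pop("symbol")
    return pd.DataFrame(rows, index=pd.Index(symbols, name="symbol"))


class TestIntegration:
    def test_multiplicative_identity_and_single_factor(self):
        table = frame(
            {"symbol": ["t1", "t2"], "s1": [1.0, 0.5], "s2": [1.0, 1.0],
             "s3": [1.0, 1.0], "s4": [1.0, 1.0], "s5": [1.0, 1.0]}
        )
        out = integrate_multiplicative(table, CFG)
        assert out.scores["t1"] == 1.0
        assert out.scores["t2"] == pytest.approx(0.5)

    def test_missing_entry_imputed_with_epsilon_missing(self):
        table = frame({"symbol": ["t"], "s1": [1.0], "s2": [np.nan]})
        out = integrate_multiplicative(table, CFG)
        assert out.scores["t"] == pytest.approx(1e-20)

    def test_additive_hand_sum_with_zero_imputation(self):
        table = frame(
            {"symbol": ["t"], "s1": [0.5], "s2": [np.nan], "s3": [1.0],
             "s4": [0.0], "s5": [0.25]}
        )
        out = integrate_additive(table)
        assert out.scores["t"] == pytest.approx(1.75)

    def test_additive_all_missing_is_zero(self):
        table = frame({"symbol": ["t"], "s1": [np.nan], "s2": [np.nan]})
        assert integrate_additive(table).scores["t"] == 0.0

    def test_additive_full_support_sums_to_source_count(self):
        table = frame({"symbol": ["t"], **{f"s{i}": [1.0] for i in range(1, 6)}})
        assert integrate_additive(table).scores["t"] == 5.0

    @given(
        scores=st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=6
        ),
        seed=st.integers(0, 100),
    )
    def test_multiplicative_source_order_invariance(self, scores, seed):
        cols = {f"s{i}": [v] for i, v in enumerate(scores)}
        table = frame({"symbol": ["t"], **cols})
        base = integrate_multiplicative(table, CFG).scores["t"]
        rng = np.random.default_rng(seed)
        shuffled = table[rng.permutation(table.columns)]
        assert integrate_multiplicative(shuffled, CFG).scores["t"] == pytest.approx(
            base, rel=1e-12
        )

    @given(
        low=st.floats(min_value=1e-6, max_value=0.5),
        bump=st.floats(min_value=1e-6, max_value=0.5),
    )
    def test_multiplicative_monotone_in_each_source(self, low, bump):
        base = frame({"symbol": ["t"], "s1": [low], "s2": [0.7]})
        raised = frame({"symbol": ["t"], "s1": [low + bump], "s2": [0.7]})
        assert (
            integrate_multiplicative(raised, CFG).scores["t"]
            >= integrate_multiplicative(base, CFG).scores["t"]
        )

    def test_multiplicative_scores_strictly_positive(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(
            np.where(rng.random((40, 5)) < 0.4, np.nan, rng.random((40, 5))),
            index=pd.Index([f"t{i}" for i in range(40)], name="symbol"),
        )
        table = table.clip(lower=1e-9)
        out = integrate_multiplicative(table, CFG)
        assert (out.scores > 0).all()


class TestTopN:
    def table(self):
        return IntegratedScoreTable(
            pd.Series({"A": 0.9, "B": 0.5, "C": 0.1}), "multiplicative"
        )

    def test_selects_highest(self):
        assert top_n(self.table(), 2).members == {"A", "B"}

    def test_full_table_identity(self):
        assert top_n(self.table(), 3).members == {"A", "B", "C"}

    def test_weights_renormalized_into_unit_interval(self):
        w = top_n(self.table(), 3, CFG)
        assert w.weight_of("A") == 1.0
        assert w.weight_of("C") == CFG.epsilon_norm

    def test_tie_at_cut_broken_lexicographically(self):
        t = IntegratedScoreTable(
            pd.Series({"B": 0.5, "A": 0.5, "C": 0.9}), "multiplicative"
        )
        assert top_n(t, 2).members == {"C", "A"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            top_n(self.table(), 4)


class TestCompareRankings:
    def test_identical_tables(self):
        t = IntegratedScoreTable(
            pd.Series({f"t{i}": 1.0 / (i + 1) for i in range(10)}), "multiplicative"
        )
        out = compare_rankings(t, t, [3, 5, 10])
        assert (out["jaccard"] == 1.0).all()
        assert np.allclose(out["spearman"], 1.0)

    def test_reversed_ranking_full_universe(self):
        scores = pd.Series({f"t{i}": float(i + 1) for i in range(8)})
        a = IntegratedScoreTable(scores, "multiplicative")
        b = IntegratedScoreTable(scores.max() + 1 - scores, "multiplicative")
        out = compare_rankings(a, b, [8])
        assert out.loc[0, "jaccard"] == 1.0
        assert out.loc[0, "spearman"] == pytest.approx(-1.0)

    def test_against_hand_enumeration(self):
        # a ranks t0..t9 descending; b swaps the top-5 with t5..t9
        a = IntegratedScoreTable(
            pd.Series({f"t{i}": 10.0 - i for i in range(10)}), "additive"
        )
        b_scores = {f"t{i}": (5.0 - (i - 5) if i >= 5 else 10.0 - i - 5) for i in range(10)}
        b = IntegratedScoreTable(pd.Series(b_scores), "additive")
        out = compare_rankings(a, b, [5])
        top_a = {"t0", "t1", "t2", "t3", "t4"}
        top_b = set(sorted(b_scores, key=lambda s: (-b_scores[s], s))[:5])
        expected_jaccard = len(top_a & top_b) / len(top_a | top_b)
        assert out.loc[0, "jaccard"] == pytest.approx(expected_jaccard)

    def test_n_exceeding_universe_rejected(self):
        t = IntegratedScoreTable(pd.Series({"a": 1.0, "b": 0.5}), "additive")
        with pytest.raises(ValueError):
            compare_rankings(t, t, [3])
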