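"""Biomarker statistics: AUC identity and invariances, genus ranking,
LEfSe-style scan behaviour, Fisher enumeration, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from biletyper.data import AbundanceTable
from biletyper.markers import (
    auc_mann_whitney,
    bh_adjust,
    fisher_exact_2x2,
    lefse_like,
    rank_genera_by_auc,
)
from biletyper.simulate import SyntheticCohortConfig, generate_cohort
from tests.conftest import make_metadata


def brute_force_auc(case, control):
    """Independent oracle: count ordered pairs directly."""
    wins = sum(1.0 for c in case for k in control if c > k)
    ties = sum(1.0 for c in case for k in control if c == k)
    return (wins + 0.5 * ties) / (len(case) * len(control))


class TestAucMannWhitney:
    def test_strict_separation_and_constant_cases(self):
        assert auc_mann_whitney([3, 4, 5], [0, 1, 2]) == 1.0
        assert auc_mann_whitney([1, 1], [1, 1, 1]) == 0.5

    def test_worked_example_matches_pair_count(self):
        case, control = [0.9, 0.8, 0.4], [0.7, 0.3, 0.2]
        assert auc_mann_whitney(case, control) == pytest.approx(8 / 9)
        assert brute_force_auc(case, control) == pytest.approx(8 / 9)

    def test_matches_brute_force_with_heavy_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            case = rng.integers(0, 4, size=rng.integers(1, 10)).astype(float)
            control = rng.integers(0, 4, size=rng.integers(1, 10)).astype(float)
            assert auc_mann_whitney(case, control) == pytest.approx(
                brute_force_auc(case, control), abs=1e-12
            )

    @settings(derandomize=True, max_examples=60)
    @given(
        case=st.lists(st.integers(0, 6), min_size=1, max_size=12),
        control=st.lists(st.integers(0, 6), min_size=1, max_size=12),
    )
    def test_complement_identity(self, case, control):
        a = auc_mann_whitney(case, control)
        b = auc_mann_whitney(control, case)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        case=st.lists(st.floats(0.01, 100), min_size=1, max_size=8),
        control=st.lists(st.floats(0.01, 100), min_size=1, max_size=8),
    )
    def test_invariant_under_monotone_transform(self, case, control):
        a = auc_mann_whitney(case, control)
        b = auc_mann_whitney(np.log(case), np.log(control))
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([], [1.0])


class TestRankGenera:
    def _fixture(self):
        # g_up enriched in cases, g_down depleted, g_tie1/g_tie2 identical signal
        df = pd.DataFrame(
            {
                "c1": [9.0, 1.0, 5.0, 5.0],
                "c2": [8.0, 2.0, 6.0, 6.0],
                "b1": [1.0, 9.0, 1.0, 1.0],
                "b2": [2.0, 8.0, 2.0, 2.0],
            },
            index=["g_up", "g_down", "g_tie2", "g_tie1"],
        )
        table = AbundanceTable(df, kind="counts")
        records = make_metadata({"c1": "CCA", "c2": "CCA", "b1": "BBD", "b2": "BBD"})
        return table, records

    def test_orientation_and_direction_flags(self):
        table, records = self._fixture()
        ranking = rank_genera_by_auc(table, records, "CCA", "BBD")
        e = ranking.entries.set_index("taxon_id")
        assert e.loc["g_down", "raw_auc"] < 0.5
        assert e.loc["g_down", "oriented_auc"] == pytest.approx(
            1 - e.loc["g_down", "raw_auc"]
        )
        assert e.loc["g_down", "direction"] == "depleted_in_case"
        assert e.loc["g_up", "direction"] == "enriched_in_case"
        assert (e["oriented_auc"] >= 0.5).all()

    def test_ties_broken_lexicographically(self):
        table, records = self._fixture()
        ranking = rank_genera_by_auc(table, records, "CCA", "BBD")
        e = ranking.entries.set_index("taxon_id")
        assert e.loc["g_tie1", "oriented_auc"] == e.loc["g_tie2", "oriented_auc"]
        assert e.loc["g_tie1", "rank"] < e.loc["g_tie2", "rank"]

    def test_recovers_most_planted_signature_taxa(self, default_cohort, default_ranking):
        _, _, truth = default_cohort
        top = set(default_ranking.top(2 * len(truth.signature_taxa)))
        hits = len(top & set(truth.signature_taxa))
        assert hits >= 0.8 * len(truth.signature_taxa)

    def test_missing_label_rejected(self):
        table, records = self._fixture()
        with pytest.raises(ValueError):
            rank_genera_by_auc(table, records, "CCA", "nope")


class TestLefseLike:
    def test_planted_signal_passes_with_largest_score(self):
        rng = np.random.default_rng(6)
        n = 40
        base = rng.dirichlet(np.ones(20), size=n).T * 1.0
        base[5, :20] *= 100.0  # 100-fold separation in the first class
        df = pd.DataFrame(
            base, index=[f"g{i}" for i in range(20)], columns=[f"s{i}" for i in range(n)]
        )
        table = AbundanceTable(df, kind="counts")
        records = make_metadata(
            {f"s{i}": ("CCA" if i < 20 else "BBD") for i in range(n)}
        )
        res = lefse_like(table, records, seed=0)
        e = res.entries.set_index("taxon_id")
        assert e.loc["g5", "passes"]
        assert e.loc["g5", "lda_score"] == e["lda_score"].max()

    def test_null_pass_fraction_within_alpha(self):
        fractions = []
        for s in range(5):
            cfg = SyntheticCohortConfig(
                seed=300 + s,
                fold_change_signature=1.0,
                fold_change_subsignature=1.0,
                hazard_ratio_aggressive=1.0,
            )
            table, records, _ = generate_cohort(cfg)
            res = lefse_like(table, records, seed=s)
            fractions.append(res.entries["passes"].mean())
        assert np.mean(fractions) <= 0.05

    def test_raising_threshold_only_shrinks_the_passing_set(self, default_cohort):
        table, records, _ = default_cohort
        low = lefse_like(table, records, lda_threshold=2.0, seed=1)
        high = lefse_like(table, records, lda_threshold=3.6, seed=1)
        assert set(high.passing()) <= set(low.passing())


class TestFisherExact:
    def test_balanced_table_gives_p_one(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_staph_stage_table_matches_enumeration_oracle(self):
        """The 2x2 of high/low genus abundance vs advanced TNM stage
        ([[7,1],[6,10]]) against a direct hypergeometric enumeration."""
        a_obs = 7
        n, row1, col1 = 24, 8, 13

        def hyp(a):
            return (
                comb(col1, a, exact=True)
                * comb(n - col1, row1 - a, exact=True)
                / comb(n, row1, exact=True)
            )

        p_obs = hyp(a_obs)
        oracle = sum(
            hyp(a)
            for a in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            if hyp(a) <= p_obs * (1 + 1e-9)
        )
        odds, p = fisher_exact_2x2([[7, 1], [6, 10]])
        assert p == pytest.approx(oracle, abs=1e-12)
        # printed value in the source analysis is 0.034 (software variant)
        assert abs(p - 0.034) < 2e-3
        assert odds == pytest.approx(7 * 10 / 6)

    def test_extreme_diagonal_table(self):
        _, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10, exact=True))

    def test_invariant_to_simultaneous_row_and_column_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            swapped = t[::-1, ::-1]
            assert fisher_exact_2x2(t)[1] == pytest.approx(
                fisher_exact_2x2(swapped)[1], abs=1e-12
            )

    def test_mid_p_never_exceeds_standard_p(self):
        t = [[7, 1], [6, 10]]
        _, p = fisher_exact_2x2(t)
        _, p_mid = fisher_exact_2x2(t, mid_p=True)
        assert p_mid < p

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestBhAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_constant_inputs_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()
        assert (np.argsort(np.argsort(p)) <= np.argsort(np.argsort(q + p * 1e-15))).any()
        # monotone: sorting p sorts q identically
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
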