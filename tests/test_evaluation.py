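"""SBS/VBS metrics against brute-force oracles; stability and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_random_table, make_table_from_scores
from dockselect.evaluation import (
    evaluate,
    gap_closed,
    improvement,
    margin_reliability,
    rank_stability,
    sbs,
    selected_at_k,
    selection_distribution,
    vbs_at_k,
    vbs_curve,
    vbs_entropy,
)
from dockselect.selector import PredictionVector


def brute_sbs(mat):
    """Reference: best column mean by exhaustive comparison."""
    best, best_mean = 0, -1.0
    for j in range(mat.shape[1]):
        mean = sum(mat[:, j]) / mat.shape[0]
        if mean > best_mean:
            best, best_mean = j, mean
    return best


class TestBaselines:
    def test_sbs_worked_example(self):
        table = make_table_from_scores([[1, 0], [1, 0], [0, 1]])
        assert sbs(table, "mean_score") == 0

    def test_sbs_tie_break_earliest(self):
        table = make_table_from_scores([[0.5, 0.5], [0.5, 0.5]])
        assert sbs(table, "mean_score") == 0

    def test_single_instance_degenerate_mean(self):
        table = make_table_from_scores([[0.2, 0.9, 0.4]])
        assert sbs(table, "mean_score") == 1

    def test_vbs_row_maxima(self):
        table = make_table_from_scores([[1, 0], [1, 0], [0, 1]])
        per, mean = vbs_curve(table, "mean_score")
        assert np.array_equal(per, [1, 1, 1])
        assert mean == 1.0

    def test_vbs_constant_matrix(self):
        table = make_table_from_scores(np.full((4, 3), 0.7))
        assert vbs_curve(table, "mean_score")[1] == pytest.approx(0.7)

    def test_vbs_at_k_order_statistics(self):
        table = make_table_from_scores([[0.9, 0.7, 0.2]])
        assert vbs_at_k(table, 2, "mean_score")[1] == pytest.approx(0.7)
        assert vbs_at_k(table, 1, "mean_score")[1] == vbs_curve(table, "mean_score")[1]
        assert vbs_at_k(table, 3, "mean_score")[1] == pytest.approx(0.2)
        with pytest.raises(ValueError):
            vbs_at_k(table, 4, "mean_score")

    def test_against_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 21))
            m = int(rng.integers(2, 9))
            table = make_random_table(rng, n, m)
            mat = table.metric_matrix("mean_score")
            assert sbs(table, "mean_score") == brute_sbs(mat)
            per, mean = vbs_curve(table, "mean_score")
            assert np.array_equal(per, [max(row) for row in mat])
            for k in range(1, m + 1):
                _, mk = vbs_at_k(table, k, "mean_score")
                expected = np.mean([sorted(row, reverse=True)[k - 1] for row in mat])
                assert mk == pytest.approx(expected)
            # oracle bound and degenerate endpoints
            sbs_perf = mat[:, sbs(table, "mean_score")].mean()
            vbs_perf = mean
            if vbs_perf > sbs_perf:
                assert gap_closed(vbs_perf, sbs_perf, vbs_perf) == pytest.approx(100.0)
                assert gap_closed(sbs_perf, sbs_perf, vbs_perf) == pytest.approx(0.0)
            # vbs_at_k means are non-increasing in k
            means_k = [vbs_at_k(table, k, "mean_score")[1] for k in range(1, m + 1)]
            assert all(a >= b - 1e-12 for a, b in zip(means_k, means_k[1:]))


class TestSelectedAtK:
    def test_counting_example(self):
        sels = [0, 0, 1, 0, 2, 1]     # A,A,B,A,C,B
        assert selected_at_k(sels, 1) == (0, 3)
        assert selected_at_k(sels, 2) == (1, 2)
        assert selected_at_k(sels, 3) == (2, 1)

    def test_all_same(self):
        assert selected_at_k([4] * 7, 1) == (4, 7)

    def test_frequency_tie_earliest_index(self):
        assert selected_at_k([0, 0, 1, 1], 1) == (0, 2)

    def test_k_beyond_distinct_count(self):
        with pytest.raises(ValueError):
            selected_at_k([0, 0, 1], 3)


class TestGapClosed:
    def test_endpoints(self):
        assert gap_closed(0.5, 0.5, 0.9) == 0.0
        assert gap_closed(0.9, 0.5, 0.9) == 100.0

    def test_worked_arithmetic(self):
        assert gap_closed(0.8, 2 / 3, 1.0) == pytest.approx(40.0)

    def test_degenerate_na_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(gap_closed(0.5, 0.5, 0.5))

    def test_oracle_violation_is_error(self):
        with pytest.raises(ValueError):
            gap_closed(0.5, 0.9, 0.8)

    def test_improvement_percentage_points(self):
        assert improvement(50.01, 43.41) == pytest.approx(6.60)
        assert improvement(74.68, 68.17) == pytest.approx(6.51)
        assert improvement(3.0, 3.0) == 0.0


class TestRankStability:
    def test_identity(self, small_bench):
        rep = rank_stability(small_bench.table, small_bench.table)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.kendall_tau_b == pytest.approx(1.0)
        assert np.allclose(rep.jk_curve, 1.0)
        assert rep.jbar == pytest.approx(1.0)

    def test_full_reversal_hand_enumeration(self):
        p = make_table_from_scores(np.tile([0.3, 0.2, 0.1], (4, 1)))
        q = make_table_from_scores(np.tile([0.1, 0.2, 0.3], (4, 1)))
        rep = rank_stability(p, q)
        assert rep.spearman_rho == pytest.approx(-1.0)
        assert rep.kendall_tau_b == pytest.approx(-1.0)
        assert rep.j1 == 0.0
        np.testing.assert_allclose(rep.jk_curve, [0.0, 1 / 3, 1.0])
        assert rep.jbar == pytest.approx(4 / 9)

    def test_matches_scipy_including_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = int(rng.integers(3, 9))
            scores_p = np.round(rng.random((6, m)), 1)   # rounding induces ties
            scores_q = np.round(rng.random((6, m)), 1)
            p, q = make_table_from_scores(scores_p), make_table_from_scores(scores_q)
            mp, mq = scores_p.mean(axis=0), scores_q.mean(axis=0)
            if np.ptp(mp) == 0 or np.ptp(mq) == 0:
                continue
            rep = rank_stability(p, q)
            ref_rho = sps.spearmanr(mp, mq).statistic
            ref_tau = sps.kendalltau(mp, mq, variant="b").statistic
            assert rep.spearman_rho == pytest.approx(ref_rho, abs=1e-9)
            assert rep.kendall_tau_b == pytest.approx(ref_tau, abs=1e-9)

    def test_small_m_tau_b_with_ties_hand_computed(self):
        # means p = (0.2, 0.2, 0.1), q = (0.3, 0.1, 0.2):
        # pairs: (0,1) tied in p, discordant->tie_x; (0,2) concordant; (1,2) discordant
        p = make_table_from_scores(np.tile([0.2, 0.2, 0.1], (2, 1)))
        q = make_table_from_scores(np.tile([0.3, 0.1, 0.2], (2, 1)))
        rep = rank_stability(p, q)
        assert rep.kendall_tau_b == pytest.approx((1 - 1) / math.sqrt(3 * 2))

    def test_portfolio_mismatch(self, small_bench):
        other = make_table_from_scores(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            rank_stability(small_bench.table, other)


class TestVbsEntropy:
    def test_single_dominant_solver(self):
        table = make_table_from_scores(np.tile([0.9, 0.1, 0.1], (5, 1)))
        assert vbs_entropy(table) == 0.0

    def test_uniform_winners_log2_m(self):
        table = make_table_from_scores(np.eye(8))
        assert vbs_entropy(table) == pytest.approx(3.0)

    def test_win_counts_2_1_1(self):
        scores = np.zeros((4, 4))
        scores[0, 0] = scores[1, 0] = 1.0
        scores[2, 1] = 1.0
        scores[3, 2] = 1.0
        assert vbs_entropy(make_table_from_scores(scores)) == pytest.approx(1.5)

    def test_bounds_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            table = make_random_table(rng, int(rng.integers(1, 15)),
                                      int(rng.integers(2, 7)))
            h = vbs_entropy(table)
            assert 0.0 <= h <= math.log2(table.m) + 1e-12


def _preds_for_selection(selections, m, margins=None):
    preds = []
    for i, s in enumerate(selections):
        logits = np.zeros(m)
        logits[s] = 1.0 + (margins[i] if margins is not None else 0.1 * (i % 7))
        preds.append(PredictionVector(logits))
    return preds


class TestMarginReliability:
    def test_equal_mass_bins(self):
        rng = np.random.default_rng(3)
        table = make_random_table(rng, 120, 4)
        sels = rng.integers(0, 4, size=120)
        preds = _preds_for_selection(sels, 4, margins=rng.random(120))
        report = margin_reliability(preds, table, n_bins=12)
        assert [b["n"] for b in report] == [10] * 12

    def test_remainder_to_lowest_bins(self):
        rng = np.random.default_rng(4)
        table = make_random_table(rng, 125, 4)
        sels = rng.integers(0, 4, size=125)
        preds = _preds_for_selection(sels, 4, margins=rng.random(125))
        sizes = [b["n"] for b in margin_reliability(preds, table, n_bins=12)]
        assert sizes == [11] * 5 + [10] * 7

    def test_oracle_selector_fully_reliable(self):
        rng = np.random.default_rng(5)
        table = make_random_table(rng, 60, 4)
        oracle = np.argmax(table.scores, axis=1)
        preds = _preds_for_selection(oracle, 4, margins=rng.random(60))
        for b in margin_reliability(preds, table, n_bins=12):
            assert b["p_oracle_agree"] == 1.0

    def test_sbs_selector_matches_never_beats(self):
        rng = np.random.default_rng(6)
        table = make_random_table(rng, 60, 4)
        j = sbs(table, "mean_score")
        preds = _preds_for_selection([j] * 60, 4, margins=rng.random(60))
        for b in margin_reliability(preds, table, n_bins=12):
            assert b["p_beats_sbs"] == 0.0
            assert b["p_matches_sbs"] == 1.0

    def test_too_few_instances(self):
        rng = np.random.default_rng(7)
        table = make_random_table(rng, 5, 3)
        preds = _preds_for_selection([0] * 5, 3)
        with pytest.raises(ValueError):
            margin_reliability(preds, table, n_bins=12)


class TestSelectionDistribution:
    def test_selector_equals_single_oracle_winner(self):
        table = make_table_from_scores(np.tile([0.9, 0.1, 0.2], (10, 1)))
        preds = _preds_for_selection([0] * 10, 3)
        dist = selection_distribution(preds, table)
        assert dist["top_solvers"][0]["selector_frequency"] == 1.0
        assert dist["top_solvers"][0]["oracle_frequency"] == 1.0
        assert dist["oracle_agreement_rate"] == 1.0

    def test_frequencies_normalised(self):
        rng = np.random.default_rng(8)
        table = make_random_table(rng, 90, 5)
        sels = rng.integers(0, 5, size=90)
        dist = selection_distribution(_preds_for_selection(sels, 5), table)
        assert dist["selector_frequencies"].sum() == pytest.approx(1.0)
        assert dist["oracle_frequencies"].sum() == pytest.approx(1.0)

    def test_uniform_random_selection_frequencies(self):
        rng = np.random.default_rng(9)
        m, n = 4, 4000
        table = make_random_table(rng, 200, m)
        sels = rng.integers(0, m, size=200)
        dist = selection_distribution(_preds_for_selection(sels, m), table)
        assert np.allclose(dist["selector_frequencies"], 1 / m, atol=0.12)


class TestEvaluate:
    def test_oracle_closes_full_gap(self):
        rng = np.random.default_rng(10)
        table = make_random_table(rng, 40, 5)
        for criterion in ("strict", "relaxed"):
            mat = table.metric_matrix(criterion)
            oracle = np.argmax(mat, axis=1)
            rep = evaluate(oracle, table)
            assert rep.gap_closed_percent[criterion] == pytest.approx(100.0)

    def test_sbs_as_selector_closes_nothing(self):
        rng = np.random.default_rng(11)
        table = make_random_table(rng, 40, 5)
        for criterion in ("strict", "relaxed"):
            rep = evaluate(np.full(40, sbs(table, criterion)), table)
            assert rep.gap_closed_percent[criterion] == pytest.approx(0.0)

    def test_report_structure(self):
        rng = np.random.default_rng(12)
        table = make_random_table(rng, 30, 4)
        rep = evaluate(rng.integers(0, 4, size=30), table)
        assert set(rep.gap_closed_percent) == {"strict", "relaxed"}
        assert 0.0 <= rep.p_value <= 1.0
        assert rep.sbs_rate["relaxed"] <= rep.vbs_rate["relaxed"]
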