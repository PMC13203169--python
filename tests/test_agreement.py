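"""Agreement statistics: published rater table, kappa, entropy, consensus,
McNemar — each against an independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shouldermorph.agreement import (
    RatingsMatrix,
    UndefinedKappaError,
    case_entropy,
    fleiss_kappa,
    load_rater_records,
    mcnemar_test,
    panel_entropies,
    rater_counts_table,
    rater_summary,
    ratings_to_matrix,
    virtual_consensus,
)
from shouldermorph.phantoms import RaterProfile, generate_rater_panel


def round2(x):
    """Round half away from zero to 2 decimals, as printed tables do."""
    return np.floor(np.asarray(x, dtype=float) * 100 + 0.5) / 100


# The published ten-surgeon summary cells (accuracy, A SE, R SE per rater).
PRINTED_ROWS = {
    "01": (0.65, 0.58, 0.72), "02": (0.62, 0.51, 0.73), "03": (0.62, 0.53, 0.71),
    "04": (0.55, 0.47, 0.63), "05": (0.69, 0.64, 0.74), "06": (0.51, 0.48, 0.54),
    "07": (0.60, 0.60, 0.60), "08": (0.59, 0.54, 0.64), "09": (0.59, 0.38, 0.80),
    "10": (0.68, 0.56, 0.80),
}


class TestRaterTable:
    def test_every_printed_cell_reproduced(self):
        summary = rater_summary(load_rater_records())
        by_id = summary.set_index("rater_id")
        for rid, (acc, a_se, r_se) in PRINTED_ROWS.items():
            row = by_id.loc[rid]
            assert round2(row.accuracy) == pytest.approx(acc)
            assert round2(row.a_se) == pytest.approx(a_se)
            assert round2(row.r_se) == pytest.approx(r_se)

    def test_cohort_mean_and_sd_rows(self):
        summary = rater_summary(load_rater_records()).set_index("rater_id")
        mean, sd = summary.loc["mean"], summary.loc["SD"]
        assert round2(mean.accuracy) == pytest.approx(0.61)
        assert round2(sd.accuracy) == pytest.approx(0.06)
        assert round2(mean.a_se) == pytest.approx(0.53)
        assert round2(mean.r_se) == pytest.approx(0.69)
        assert mean.a_tp == pytest.approx(26.6)
        assert round2(sd.a_tp) == pytest.approx(3.66)
        assert mean.r_tp == pytest.approx(34.4)
        assert mean.a_fn == pytest.approx(23.7)
        assert mean.r_fn == pytest.approx(15.3)

    def test_accuracy_range(self):
        summary = rater_summary(load_rater_records())
        raters = summary[~summary.rater_id.isin(["mean", "SD"])]
        assert round2(raters.accuracy.min()) == pytest.approx(0.51)
        assert round2(raters.accuracy.max()) == pytest.approx(0.69)

    def test_sensitivities_use_tp_plus_fn_denominator(self):
        """Three raters total 51 anatomical cases; only TP/(TP+FN) matches
        the printed sensitivity cells there."""
        table = rater_counts_table()
        over = table[table.a_tp + table.a_fn == 51]
        assert len(over) == 3
        row = table[table.rater_id == "02"].iloc[0]
        assert round2(row.a_tp / (row.a_tp + row.a_fn)) == pytest.approx(0.51)
        # the naive TP/50 convention would print 0.52 instead
        assert round2(row.a_tp / 50) == pytest.approx(0.52)

    def test_perfect_rater_is_all_ones(self):
        df = pd.DataFrame([{"rater_id": "x", "role": "Con", "a_tp": 50,
                            "r_tp": 50, "a_fn": 0, "r_fn": 0}])
        summary = rater_summary(load_rater_records(df)).iloc[0]
        assert summary.accuracy == summary.a_se == summary.r_se == 1.0


def oracle_fleiss(counts):
    """Independent combinatorial evaluation: per-item agreement as the
    fraction of concordant rater pairs."""
    counts = np.asarray(counts)
    k = counts.sum(axis=1)[0]
    po_i = [sum(math.comb(int(n), 2) for n in row) / math.comb(k, 2)
            for row in counts]
    po = float(np.mean(po_i))
    pj = counts.sum(axis=0) / counts.sum()
    pe = float((pj**2).sum())
    return (po - pe) / (1 - pe)


class TestFleissKappa:
    def test_unanimous_raters_kappa_one(self):
        m = RatingsMatrix([[4, 0], [0, 4], [4, 0]])
        stats = fleiss_kappa(m)
        assert stats.kappa == pytest.approx(1.0)
        assert stats.observed_agreement == pytest.approx(1.0)

    def test_worked_two_item_example(self):
        stats = fleiss_kappa(RatingsMatrix([[3, 0], [0, 3]]))
        assert stats.observed_agreement == pytest.approx(1.0)
        np.testing.assert_allclose(stats.category_proportions, [0.5, 0.5])
        assert stats.expected_agreement == pytest.approx(0.5)
        assert stats.kappa == pytest.approx(1.0)

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedKappaError):
            fleiss_kappa(RatingsMatrix([[3, 0], [3, 0]]))

    def test_matches_pairwise_oracle_on_all_small_compositions(self):
        """Exhaustive N<=4 items, k<=4 raters, 2 categories."""
        checked = 0
        for k in (2, 3, 4):
            for n_items in (1, 2, 3, 4):
                for combo in itertools.product(range(k + 1), repeat=n_items):
                    counts = [[c, k - c] for c in combo]
                    m = RatingsMatrix(counts)
                    pj = np.asarray(counts).sum(axis=0) / (n_items * k)
                    if (pj**2).sum() >= 1 - 1e-12:
                        continue
                    assert fleiss_kappa(m).kappa == pytest.approx(
                        oracle_fleiss(counts), abs=1e-12)
                    checked += 1
        assert checked > 300

    def test_matches_statsmodels_on_random_tables(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(0)
        for _ in range(10):
            votes = rng.integers(0, 3, size=(20, 6))
            counts = np.stack([np.bincount(r, minlength=3) for r in votes])
            assert fleiss_kappa(RatingsMatrix(counts)).kappa == pytest.approx(
                sm_fleiss(counts), abs=1e-12)

    def test_random_ratings_kappa_near_zero(self):
        """500 items, 10 raters, fair coin per rating: kappa within 0.05 of 0."""
        rng = np.random.default_rng(7)
        votes = rng.integers(0, 2, size=(500, 10))
        counts = np.stack([np.bincount(r, minlength=2) for r in votes])
        assert abs(fleiss_kappa(RatingsMatrix(counts)).kappa) < 0.05

    def test_unequal_row_sums_rejected(self):
        with pytest.raises(ValueError):
            RatingsMatrix([[3, 0], [2, 2]])

    def test_ratings_to_matrix_from_panel(self):
        panel = generate_rater_panel([0, 1, 1],
                                     [RaterProfile(1, 1, 0)] * 3, seed=0)
        m = ratings_to_matrix(panel, categories=2)
        np.testing.assert_array_equal(m.counts, [[3, 0], [0, 3], [0, 3]])


class TestEntropy:
    def test_full_agreement_zero(self):
        assert case_entropy(10, 0).H == 0.0
        assert case_entropy(0, 10).H == 0.0

    def test_even_split_is_one_bit(self):
        assert case_entropy(5, 5).H == pytest.approx(1.0)

    def test_seven_three_split(self):
        expected = -(0.7 * np.log2(0.7) + 0.3 * np.log2(0.3))
        assert case_entropy(7, 3).H == pytest.approx(expected, abs=1e-12)
        assert case_entropy(7, 3).H == pytest.approx(0.8813, abs=5e-5)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            case_entropy(0, 0)

    @given(st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_range(self, n1, n2):
        if n1 + n2 == 0:
            return
        a, b = case_entropy(n1, n2), case_entropy(n2, n1)
        assert a.H == pytest.approx(b.H, abs=1e-12)
        assert 0.0 <= a.H <= 1.0
        assert (a.H == 0.0) == (n1 * n2 == 0)

    def test_unimodal_peak_at_even_split(self):
        hs = [case_entropy(n, 10 - n).H for n in range(11)]
        assert np.argmax(hs) == 5
        assert all(hs[i] < hs[i + 1] for i in range(5))
        assert all(hs[i] > hs[i + 1] for i in range(5, 10))

    def test_strict_concavity_in_proportion(self):
        """H(p) evaluated on a grid satisfies the midpoint concavity
        inequality strictly away from ties."""
        def h(p):
            q = 1 - p
            return -(p * np.log2(p) + q * np.log2(q))

        for p1, p2 in [(0.1, 0.5), (0.2, 0.9), (0.3, 0.6)]:
            assert h((p1 + p2) / 2) > (h(p1) + h(p2)) / 2

    def test_panel_entropies_table(self):
        panel = pd.DataFrame({"case_id": ["a", "b"],
                              "rater_01": [1, 1], "rater_02": [1, 0]})
        ent = panel_entropies(panel)
        assert ent.entropy_bits.tolist() == pytest.approx([0.0, 1.0])


class TestVirtualConsensus:
    def test_perfect_raters_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        X = np.tile(y[:, None], (1, 10))
        assert virtual_consensus(X, y, folds=5, seed=0) == 1.0

    def test_coin_flip_raters_chance_level(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 100)
        X = rng.integers(0, 2, size=(200, 10))
        acc = virtual_consensus(X, y, folds=5, seed=0)
        assert abs(acc - 0.5) < 0.1

    def test_ensemble_beats_best_single_rater(self):
        """Raters at 0.75 sensitivity: the pooled logistic regression beats
        the best individual in at least 2 of 3 seeds."""
        wins = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(100 + seed)
            y = np.array([0, 1] * 100)
            rng.shuffle(y)
            profiles = [RaterProfile(0.75, 0.75, 0.0)] * 10
            panel = generate_rater_panel(list(y), profiles, seed=seed)
            X = panel[[c for c in panel.columns if c != "case_id"]].to_numpy()
            best_single = max((X[:, j] == y).mean() for j in range(10))
            acc = virtual_consensus(X, y, folds=5, seed=seed)
            wins += int(acc > best_single)
        assert wins >= 2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            virtual_consensus(np.zeros((20, 3)), np.zeros(20), folds=2)


class TestMcNemar:
    def test_identical_vectors_p_one(self):
        a = np.array([True, False, True, True])
        stat, p = mcnemar_test(a, a)
        assert p == 1.0

    def test_known_discordant_counts_vs_binomial_enumeration(self):
        """b=15, c=3 discordant pairs: exact two-sided binomial tail."""
        a = np.array([True] * 15 + [False] * 3 + [True] * 30)
        b = np.array([False] * 15 + [True] * 3 + [True] * 30)
        _, p = mcnemar_test(a, b)
        n = 18
        tail = sum(math.comb(n, i) for i in range(0, 4)) / 2**n
        assert p == pytest.approx(min(1.0, 2 * tail), abs=1e-12)

    def test_swap_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.random(50) > 0.4
        b = rng.random(50) > 0.6
        assert mcnemar_test(a, b)[1] == pytest.approx(mcnemar_test(b, a)[1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test([True], [True, False])
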