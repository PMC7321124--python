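"""Metrics, selection policy and the Mann–Whitney machinery."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from dockpick.evaluation import (
    ligand_centric_eval,
    mann_whitney_one_sided,
    oracle_selection,
    pearson_r,
    per_family_eval,
    per_protocol_eval,
    select_protocol,
    selection_comparison,
)
from dockpick.splits import RandomSplit


class TestPearson:
    def test_perfect_and_inverse(self):
        x = np.array([1.0, 2.0, 4.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance_flagged_missing(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))


def _cv_frame(n=20, p=4, k=2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.abs(rng.normal(2.0, 0.8, size=(n, p, 3)))
    labels[..., 2] = rng.integers(0, 20, size=(n, p))
    ids = [f"c{i}" for i in range(n)]
    plan = RandomSplit(k, seed=seed).plan(ids)
    return labels, ids, plan


class TestPerProtocolEval:
    def test_perfect_predictions(self):
        labels, ids, plan = _cv_frame()
        pred = labels.transpose(0, 2, 1).copy()
        df = per_protocol_eval(pred, labels, plan, ids=ids)
        body = df[df.protocol != "Average"]
        assert np.allclose(body["rmse_mean"], 0.0)
        assert np.allclose(body["r_mean"], 1.0)

    def test_constant_shift_gives_rmse_shift_r_one(self):
        labels, ids, plan = _cv_frame(seed=1)
        pred = labels.transpose(0, 2, 1) + 0.7
        df = per_protocol_eval(pred, labels, plan, ids=ids)
        body = df[df.protocol != "Average"]
        assert np.allclose(body["rmse_mean"], 0.7, atol=1e-12)
        assert np.allclose(body["r_mean"], 1.0)

    def test_fold_aggregation_mean_std(self):
        # protocol RMSE 1.0 in fold 0 and 2.0 in fold 1 -> 1.5 (+/- 0.5)
        n, p = 4, 1
        ids = [f"c{i}" for i in range(n)]
        from dockpick.splits import SplitPlan

        plan = SplitPlan("random", 2, 0, {"c0": 0, "c1": 0, "c2": 1, "c3": 1})
        labels = np.zeros((n, p, 3))
        labels[..., 2] = 1
        pred = np.zeros((n, 3, p))
        pred[:2, :2, 0] = 1.0  # fold 0: rmsd error 1
        pred[2:, :2, 0] = 2.0  # fold 1: rmsd error 2
        pred[:, 2, 0] = 1.0
        df = per_protocol_eval(pred, labels, plan, ids=ids)
        row = df[(df.protocol == "protocol-0") & (df.target == "rmsd_ave")].iloc[0]
        assert row.rmse_mean == pytest.approx(1.5)
        assert row.rmse_std == pytest.approx(0.5)

    def test_average_row_present_per_target(self):
        labels, ids, plan = _cv_frame()
        pred = labels.transpose(0, 2, 1).copy()
        df = per_protocol_eval(pred, labels, plan, ids=ids)
        assert (df.protocol == "Average").sum() == 3


class TestLigandCentricEval:
    def test_perfect(self):
        labels, ids, plan = _cv_frame()
        out = ligand_centric_eval(labels.transpose(0, 2, 1), labels, plan, ids=ids)
        assert out["r_mean"] == pytest.approx(1.0)
        assert out["rmse_mean"] == pytest.approx(0.0)

    def test_hand_computed_pooled_example(self):
        # 2 complexes x 2 protocols, one fold: labels (1,2,3,4), preds (1,2,3,5)
        from dockpick.splits import SplitPlan

        ids = ["a", "b"]
        plan = SplitPlan("random", 1, 0, {"a": 0, "b": 0})
        labels = np.zeros((2, 2, 3))
        labels[:, :, 1] = [[1, 2], [3, 4]]
        pred = np.zeros((2, 3, 2))
        pred[:, 1, :] = [[1, 2], [3, 5]]
        out = ligand_centric_eval(pred, labels, plan, ids=ids)
        assert out["rmse_mean"] == pytest.approx(0.5)
        assert out["r_mean"] == pytest.approx(
            pearson_r([1, 2, 3, 4], [1, 2, 3, 5]), abs=1e-12)
        assert out["r_mean"] == pytest.approx(0.9827, abs=1e-4)

    def test_pooled_vector_length(self):
        labels, ids, plan = _cv_frame(n=10, p=4, k=1)
        out = ligand_centric_eval(labels.transpose(0, 2, 1), labels, plan, ids=ids)
        assert len(out["per_fold_r"]) == 1  # one pooled value per fold


class TestSelection:
    def test_single_protocol(self):
        pred = np.array([[[1.0], [2.0], [3.0]]])
        assert (select_protocol(pred)[0] == 0).all()

    def test_argmin_for_rmsd(self):
        pred = np.zeros((3, 3))
        pred[1] = [2.0, 1.5, 3.0]
        assert select_protocol(pred)[1] == 1

    def test_tie_breaks_to_lowest_index(self):
        pred = np.zeros((3, 3))
        pred[2] = [3.0, 7.0, 7.0]
        assert select_protocol(pred)[2] == 1

    def test_oracle_selection_dominates_every_fixed_protocol(self, small_benchmark):
        labels = small_benchmark.labels
        sel = oracle_selection(labels)
        chosen = labels.values[np.arange(len(labels)), sel[:, 1], 1]
        for j in range(len(labels.protocols)):
            assert chosen.mean() <= labels.values[:, j, 1].mean() + 1e-12


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_one_sided([1, 2], [3, 4], "less")
        assert u == 0
        assert p == pytest.approx(1 / 6)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "less")
        assert p >= 0.5

    def test_matches_scipy_exact_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            for alt in ("less", "greater"):
                u, p = mann_whitney_one_sided(x, y, alt)
                ref = stats.mannwhitneyu(x, y, alternative=alt, method="exact")
                assert u == pytest.approx(ref.statistic)
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_direction_swap(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        _, p_less = mann_whitney_one_sided(x, y, "less")
        _, p_greater = mann_whitney_one_sided(y, x, "greater")
        assert p_less == pytest.approx(p_greater)

    def test_exact_agrees_with_normal_approximation(self):
        # balanced samples of size 10: compare enumeration-regime logic
        # (via scipy exact) against our asymptotic branch
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(0.5, 1.0, size=10)
        _, p_asym = mann_whitney_one_sided(x, y, "less")  # n=20 -> asymptotic
        p_exact = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
        assert abs(p_asym - p_exact) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0], "less")


class TestSelectionComparison:
    def test_report_shape(self, small_benchmark):
        labels = small_benchmark.labels
        sel = oracle_selection(labels)
        df = selection_comparison(sel, labels)
        p = len(labels.protocols)
        assert len(df) == 3 * p
        assert (df[df.target == "rmsd_ave"].shape[0]) == p

    def test_oracle_selection_means_dominate(self, small_benchmark):
        labels = small_benchmark.labels
        df = selection_comparison(oracle_selection(labels), labels)
        ave = df[df.target == "rmsd_ave"]
        assert (ave.mean_selected <= ave.mean_protocol + 1e-12).all()
        cnt = df[df.target == "n_rmsd"]
        assert (cnt.mean_selected >= cnt.mean_protocol - 1e-12).all()

    def test_random_selection_rarely_significant_under_null(self):
        """Protocol-exchangeable labels: random picks should almost never
        look significantly better at alpha=0.01."""
        rng = np.random.default_rng(0)
        n, p = 30, 6
        false_hits = 0
        reps = 100
        for _ in range(reps):
            labels = np.abs(rng.normal(2.0, 0.7, size=(n, p, 3)))
            labels[..., 2] = rng.integers(0, 20, size=(n, p))
            sel = rng.integers(0, p, size=(n, 3))
            df = selection_comparison(sel, labels, alpha=0.01)
            if df[df.target == "rmsd_ave"].significant.any():
                false_hits += 1
        assert false_hits <= 5  # non-significant in >= 95% of repetitions


class TestPerFamilyEval:
    def test_single_family_equals_ligand_centric(self):
        labels, ids, plan = _cv_frame(n=12, p=3, k=2, seed=5)
        pred = labels.transpose(0, 2, 1) + np.random.default_rng(0).normal(
            0, 0.1, size=(12, 3, 3))
        fams = {i: "F0" for i in ids}
        df = per_family_eval(pred, labels, plan, fams, ids=ids)
        lig = ligand_centric_eval(pred, labels, plan, ids=ids)
        assert len(df) == 1
        assert df.r_mean.iloc[0] == pytest.approx(lig["r_mean"])

    def test_ranking_and_top_n(self):
        labels, ids, plan = _cv_frame(n=20, p=2, k=2, seed=6)
        pred = labels.transpose(0, 2, 1).copy()
        fams = {i: ("Fbig" if k < 12 else "Fsmall") for k, i in enumerate(ids)}
        df = per_family_eval(pred, labels, plan, fams, ids=ids, top_n=50)
        assert list(df.family) == ["Fbig", "Fsmall"]  # count-descending
        assert df.n_complexes.tolist() == [12, 8]

    def test_sparse_fold_flagged_missing(self):
        labels, ids, plan = _cv_frame(n=10, p=2, k=2, seed=7)
        fams = {i: ("F0" if k == 0 else "F1") for k, i in enumerate(ids)}
        df = per_family_eval(labels.transpose(0, 2, 1), labels, plan, fams,
                             ids=ids, min_count=3)
        row = df[df.family == "F0"].iloc[0]
        assert np.isnan(row.r_mean)  # one member: flagged, never fabricated
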