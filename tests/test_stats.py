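import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sensefuse.stats import (
    bh_adjust,
    build_delta_rows,
    compare_distributions,
    cramers_v,
    mae_table,
    pad_mae_association,
    per_subject_mae,
    rank_biserial,
    sensitivity_table,
    severity_metrics,
    severity_table,
    signed_rank_test,
)


def exact_signed_rank_p_greater(deltas: np.ndarray) -> float:
    """Full sign-assignment enumeration oracle (zero-free, tie-free)."""
    d = np.asarray(deltas, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.asarray(signs, dtype=bool)].sum()
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n


class TestPerSubjectMae:
    def _frame(self, subjects, y, yhat):
        return pd.DataFrame({"subject": subjects, "y_true": y, "y_pred": yhat})

    def test_perfect(self):
        by, macro = per_subject_mae(self._frame(["a", "a"], [1, 2], [1, 2]))
        assert macro == 0.0

    def test_hand_arithmetic(self):
        by, macro = per_subject_mae(self._frame(["a", "a"], [0, 2], [1, 1]))
        assert by["a"] == 1.0 and macro == 1.0

    def test_macro_differs_from_pooled(self):
        # subject a: 1 instance err 0; subject b: 3 instances err 1
        df = self._frame(["a", "b", "b", "b"], [0, 0, 0, 0], [0, 1, 1, 1])
        by, macro = per_subject_mae(df)
        pooled = np.abs(df["y_true"] - df["y_pred"]).mean()
        assert macro == 0.5
        assert pooled == 0.75
        assert macro != pooled


class TestSignedRank:
    def test_all_positive_n10_exact(self):
        res = signed_rank_test(np.arange(1, 11), alternative="greater")
        assert abs(res.p_value - 2.0**-10) < 1e-12

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n in (5, 8, 12):
            for _ in range(3):
                d = rng.normal(size=n)
                d = np.sign(d) * (np.abs(d) + np.linspace(0.01, 1, n))  # tie-free
                res = signed_rank_test(d, alternative="greater")
                assert abs(res.p_value - exact_signed_rank_p_greater(d)) < 1e-9

    def test_symmetric_pairs_near_null(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = signed_rank_test(d, alternative="greater")
        assert res.p_value >= 0.4
        assert res.effect_size == 0.0

    def test_all_zero_degenerate(self):
        res = signed_rank_test(np.zeros(5), alternative="greater")
        assert res.p_value == 1.0 and res.degenerate

    def test_clustered_requires_clusters(self):
        with pytest.raises(ValueError):
            signed_rank_test([1.0, 2.0], clustered=True)

    def test_clustered_detects_strong_signal(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.5, 1.5, size=40)
        cl = np.repeat(np.arange(10), 4)
        res = signed_rank_test(d, alternative="greater", clustered=True,
                               clusters=cl)
        assert res.p_value < 0.01

    def test_clustered_singleton_clusters_close_to_normal_approx(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, size=60)
        cl = np.arange(60)
        res = signed_rank_test(d, alternative="greater", clustered=True,
                               clusters=cl)
        ref = signed_rank_test(d, alternative="greater")
        assert abs(res.p_value - ref.p_value) < 0.05

    def test_clustered_accounts_for_correlation(self):
        # cluster-correlated null: the clustered test stays near nominal,
        # the naive test over-rejects (quick 500-rep version)
        rng = np.random.default_rng(3)
        rej_cl = rej_un = 0
        reps = 500
        for _ in range(reps):
            u = rng.normal(0, 1, 12)
            d = (u[:, None] + rng.normal(0, 1, (12, 5))).ravel()
            cl = np.repeat(np.arange(12), 5)
            if signed_rank_test(d, "greater", clustered=True,
                                clusters=cl).p_value < 0.05:
                rej_cl += 1
            if signed_rank_test(d, "greater").p_value < 0.05:
                rej_un += 1
        assert rej_cl / reps < 0.09
        assert rej_un / reps > 0.09


class TestRankBiserial:
    def test_all_positive_is_one(self):
        assert rank_biserial([1.0, 2.0, 0.5], paired=True) == 1.0

    def test_symmetric_is_zero(self):
        assert rank_biserial([1.0, -1.0, 2.0, -2.0], paired=True) == 0.0

    def test_paired_toy_matches_bruteforce(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        d = a - b
        ranks = sps.rankdata(np.abs(d))
        expected = (ranks[d > 0].sum() - ranks[d < 0].sum()) / ranks.sum()
        assert rank_biserial(a, b, paired=True) == expected == -1.0

    def test_unpaired_from_u(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert rank_biserial(a, b, paired=False) == -1.0
        assert rank_biserial(b, a, paired=False) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial([], paired=True)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_paired_bounded(self, deltas):
        assert -1.0 <= rank_biserial(deltas, paired=True) <= 1.0


class TestCramersV:
    def test_independent_table_is_zero(self):
        margins_r = np.array([0.3, 0.7])
        margins_c = np.array([0.5, 0.2, 0.3])
        table = np.outer(margins_r, margins_c) * 1000
        assert cramers_v(table) < 1e-6

    def test_diagonal_table_is_one(self):
        assert cramers_v([[10, 0], [0, 10]]) == 1.0

    def test_hand_computed_chi_square(self):
        table = np.array([[10, 20], [20, 10]])
        # expected counts all 15 -> chi2 = 4 * 25/15; V = sqrt(chi2/60)
        expected = np.sqrt((4 * 25 / 15) / 60)
        assert abs(cramers_v(table) - expected) < 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cramers_v([[0, 0], [1, 2]])


class TestBhAdjust:
    def test_all_ones_no_rejections(self):
        assert not bh_adjust(np.ones(5), fdr=0.25).any()

    def test_single_p_reduces_to_alpha_test(self):
        assert bh_adjust([0.01], fdr=0.25).tolist() == [True]
        assert bh_adjust([0.3], fdr=0.25).tolist() == [False]

    def test_hand_step_up(self):
        # thresholds at FDR 0.25, m=4: 0.0625, 0.125, 0.1875, 0.25
        flags = bh_adjust([0.01, 0.02, 0.2, 0.9], fdr=0.25)
        assert flags.tolist() == [True, True, False, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_rejections(self, pvals):
        p = np.asarray(pvals)
        flags = bh_adjust(p, fdr=0.25)
        if flags.any():
            thresh = p[flags].max()
            assert flags[p <= thresh].all()


class TestSeverityMetrics:
    def test_perfect(self):
        y = np.array([0, 0, 3, 3])
        m = severity_metrics(y, y.astype(float), severe_low=False)
        assert m.sensitivity == m.specificity == m.ppv == 1.0

    def test_all_predicted_non_severe(self):
        y = np.array([3.0, 0.0])
        m = severity_metrics(y, np.array([0.0, 0.0]), severe_low=False)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_hand_counts(self):
        m_obj = severity_metrics(
            np.array([3, 3, 3, 3, 0, 0, 0, 0, 0, 0]),
            np.array([3, 3, 3, 0, 3, 0, 0, 0, 0, 0], dtype=float),
            severe_low=False,
        )
        assert (m_obj.tp, m_obj.fp, m_obj.tn, m_obj.fn) == (3, 1, 5, 1)
        assert m_obj.sensitivity == 0.75
        assert m_obj.specificity == 5 / 6
        assert m_obj.ppv == 0.75

    def test_sleep_direction_flips_threshold(self):
        m = severity_metrics(np.array([0.0]), np.array([1.0]), severe_low=True)
        assert m.tp == 1
        m2 = severity_metrics(np.array([0.0]), np.array([2.0]), severe_low=True)
        assert m2.fn == 1

    def test_no_positives_sensitivity_nan(self):
        m = severity_metrics(np.array([0.0]), np.array([0.0]), severe_low=False)
        assert np.isnan(m.sensitivity)


def synthetic_predictions(seed=0, n_subjects=6, per_subject=12, modes=None,
                          combined_better=0.0):
    """Prediction records for two hyperparameter settings and all modes."""
    rng = np.random.default_rng(seed)
    modes = modes or ["single", "combined", "baseline_single",
                      "baseline_combined"]
    rows = []
    for s in range(n_subjects):
        subject = f"s{s}"
        for lr in (0.01, 0.1):
            for mode in modes:
                hp = (lr, 100, 3, False, "all")
                if mode.startswith("baseline"):
                    hp = (np.nan, np.nan, np.nan, False, "all")
                bias = -combined_better if mode == "combined" else 0.0
                for t in range(per_subject):
                    y = float(rng.integers(0, 4))
                    err = rng.normal(0.8 + bias, 0.1)
                    rows.append(
                        {
                            "subject": subject, "study": "studyA",
                            "item": "stress", "mode": mode,
                            "learning_rate": hp[0], "n_trees": hp[1],
                            "depth": hp[2], "smote": hp[3], "k": hp[4],
                            "timestamp": pd.Timestamp("2020-01-01")
                            + pd.Timedelta(days=t),
                            "y_true": y,
                            "y_pred": np.clip(y + err, 0, 3),
                        }
                    )
    return pd.DataFrame(rows)


class TestSensitivityTable:
    def test_all_nonsignificant_counts_zero(self):
        preds = synthetic_predictions(seed=1)
        maes = mae_table(preds)
        summary, detail = sensitivity_table(maes)
        assert (summary["n_SC"] == 0).all() and (summary["n_CS"] == 0).all()

    def test_combined_advantage_detected(self):
        preds = synthetic_predictions(seed=2, combined_better=0.5,
                                      n_subjects=10)
        maes = mae_table(preds)
        summary, detail = sensitivity_table(maes)
        row = summary.iloc[0]
        assert row["n_SC"] == row["n_settings"]
        assert row["n_BC"] == row["n_settings"]
        assert row["n_CS"] == 0

    def test_percentages_recompute(self):
        preds = synthetic_predictions(seed=3, combined_better=0.5)
        summary, _ = sensitivity_table(mae_table(preds))
        for _, row in summary.iterrows():
            for comp in ("BC", "BS", "SC", "CS"):
                assert row[f"pct_{comp}"] == int(
                    round(100 * row[f"n_{comp}"] / row["n_settings"])
                )

    def test_severity_table_shapes(self):
        preds = synthetic_predictions(seed=4)
        core = preds[preds["mode"].isin(["single", "combined"])]
        sev = severity_table(core, severe_low=False)
        assert {"sensitivity", "specificity", "ppv", "mae"} <= set(sev.columns)
        pooled = severity_table(core, severe_low=False, per_subject=True)
        assert len(pooled) == len(sev)


class TestAssociation:
    @staticmethod
    def _rows(slope=0.07, intercept=0.3, noise=0.0, seed=0, n_subjects=8):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            for item in ("sleep", "stress"):
                for k in ("5", "10", "all"):
                    dpad = rng.normal(0, 1)
                    rows.append(
                        {
                            "subject": f"s{s}", "item": item, "k": k,
                            "dpad": dpad,
                            "dmae": intercept + slope * dpad
                            + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_noiseless_matches_ols(self):
        df = self._rows(noise=0.0)
        res = pad_mae_association(df)
        ols = np.polyfit(df["dpad"], df["dmae"], 1)[0]
        gee_slope = res.gee.loc[res.gee["term"] == "dpad", "beta"].iloc[0]
        lmm_slope = res.lmm.loc[res.lmm["term"] == "dpad", "beta"].iloc[0]
        assert abs(gee_slope - 0.07) < 1e-6
        assert abs(lmm_slope - 0.07) < 1e-3
        assert abs(ols - 0.07) < 1e-6

    def test_zero_effect_ci_covers_zero(self):
        df = self._rows(slope=0.0, noise=0.05, seed=5, n_subjects=20)
        res = pad_mae_association(df)
        row = res.gee[res.gee["term"] == "dpad"].iloc[0]
        assert row["ci_low"] <= 0.0 <= row["ci_high"]

    def test_requires_two_clusters(self):
        df = self._rows().query("subject == 's0'")
        with pytest.raises(ValueError):
            pad_mae_association(df)

    def test_both_estimators_same_rows(self):
        df = self._rows(noise=0.02, seed=6)
        res = pad_mae_association(df)
        assert res.n_rows == len(df)
        assert set(res.gee["term"]) == set(res.lmm["term"])


class TestBuildDeltaRows:
    def test_deltas_recompute_from_operands(self):
        preds = synthetic_predictions(seed=7)
        maes = mae_table(preds)
        pads = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(6)] * 2,
                "item": "stress",
                "mode": ["single"] * 6 + ["combined"] * 6,
                "k": "all",
                "pad": np.linspace(0, 1, 12),
            }
        )
        rows = build_delta_rows(maes, pads)
        assert np.allclose(rows["dmae"],
                           rows["mae_single"] - rows["mae_combined"])
        ok = rows["dpad"].notna()
        assert np.allclose(rows.loc[ok, "dpad"],
                           rows.loc[ok, "pad_single"]
                           - rows.loc[ok, "pad_combined"])
        assert {"mae_baseline_single", "mae_baseline_combined"} <= set(
            rows.columns
        )


class TestCompareDistributions:
    def test_identical_samples_rbc_zero(self):
        a = np.arange(50, dtype=float)
        res = compare_distributions(a, a.copy())
        assert res.effect_size == 0.0
        assert res.statistic == 50 * 50 / 2

    def test_disjoint_support_rbc_one(self):
        res = compare_distributions(np.arange(10.0), np.arange(20.0, 30.0))
        assert res.effect_size == -1.0

    def test_lognormal_shift_power(self):
        rng = np.random.default_rng(8)
        a = rng.lognormal(0, 1, 500)
        b = rng.lognormal(1, 1, 500)
        res = compare_distributions(a, b)
        assert res.p_value < 1e-6
        assert res.extras["normality_p_a"] < 0.001

    def test_categorical_path(self):
        a = np.array([0] * 30 + [1] * 10)
        b = np.array([0] * 10 + [1] * 30)
        res = compare_distributions(a, b, kind="categorical")
        assert res.name == "chi-square"
        assert 0.0 <= res.effect_size <= 1.0
        assert res.p_value < 0.01

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1, 1], [1, 1], kind="categorical")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])
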