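"""Log-rank prognosis, trend classification, VIF pruning, Cox fit, strata, SVM."""

import numpy as np
import pandas as pd
import pytest

from stagewire.survival import (
    classify_trends,
    dunn_posthoc,
    fit_cox,
    km_logrank,
    quartile_strata,
    strata_logrank,
    stratify_risk,
    svm_validate,
    vif_select,
)
from stagewire.synthetic import CONDITIONS, SurvivalEffectSpec, generate_survival


def expr_frame(seed, genes=3, n=100):
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[0])
    return pd.DataFrame(
        rng.normal(0, 1, (genes, n)),
        index=[f"g{i}" for i in range(genes)],
        columns=[f"p{i}" for i in range(n)],
    )


def stage_design(n=30):
    idx, cond = [], []
    for c in CONDITIONS:
        idx += [f"{c}_{i}" for i in range(n)]
        cond += [c] * n
    return pd.DataFrame({"condition": cond}, index=idx)


class TestKmLogrank:
    def test_identical_groups_give_p_one(self):
        # two groups with exactly the same survival experience
        times = [5.0, 10.0, 15.0, 20.0] * 2
        events = [1, 1, 0, 1] * 2
        surv = pd.DataFrame(
            {"time": times, "event": events}, index=[f"p{i}" for i in range(8)]
        )
        x = pd.Series([1, 2, 3, 4, 11, 12, 13, 14], index=surv.index, dtype=float)
        # construct so low/high groups carry identical times and events
        res = km_logrank(x, surv)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_median_value_goes_to_low_group(self):
        x = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0], index=[f"p{i}" for i in range(5)])
        surv = pd.DataFrame(
            {"time": [1, 2, 3, 4, 5.0], "event": [1, 1, 1, 1, 1]}, index=x.index
        )
        res = km_logrank(x, surv)
        assert res["groups"]["p1"] == "Low" and res["groups"]["p2"] == "Low"

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(2, 1, 40), index=[f"p{i}" for i in range(40)])
        surv = pd.DataFrame(
            {"time": rng.exponential(100, 40), "event": rng.integers(0, 2, 40)},
            index=x.index,
        )
        p1 = km_logrank(x, surv)["p"]
        p2 = km_logrank(np.exp(x), surv)["p"]
        assert p1 == pytest.approx(p2)

    def test_degenerate_split_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0, 1.0], index=[f"p{i}" for i in range(4)])
        surv = pd.DataFrame({"time": [1, 2, 3, 4.0], "event": [1, 1, 1, 1]}, index=x.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            km_logrank(x, surv)


class TestClassifyTrends:
    def test_descending_medians_with_separation(self):
        design = stage_design()
        rng = np.random.default_rng(1)
        means = {"normal": 5, "I": 5, "II": 4, "III": 3, "IV": 2}
        x = pd.Series(
            [rng.normal(means[c], 0.5) for c in design["condition"]],
            index=design.index, name="g",
        )
        call = classify_trends(x, design)
        assert call.trend == "descending"
        assert call.kw_p < 0.05

    def test_ascending_medians(self):
        design = stage_design()
        rng = np.random.default_rng(2)
        means = {"normal": 1, "I": 1, "II": 2, "III": 3, "IV": 4}
        x = pd.Series(
            [rng.normal(means[c], 0.5) for c in design["condition"]],
            index=design.index, name="g",
        )
        assert classify_trends(x, design).trend == "ascending"

    def test_outset_cancer_shift_without_stage_trend(self):
        design = stage_design()
        rng = np.random.default_rng(3)
        means = {"normal": 2, "I": 6, "II": 6, "III": 6, "IV": 6}
        x = pd.Series(
            [rng.normal(means[c], 0.8) for c in design["condition"]],
            index=design.index, name="g",
        )
        call = classify_trends(x, design)
        assert call.trend == "outset-cancer"
        assert call.outset_t_p < 0.05

    def test_null_gene_mostly_none(self):
        design = stage_design()
        calls = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = pd.Series(rng.normal(0, 1, len(design)), index=design.index, name="g")
            calls.append(classify_trends(x, design).trend)
        assert calls.count("none") >= 8

    def test_bh_adjustment_preserves_order(self):
        design = stage_design()
        rng = np.random.default_rng(4)
        means = {"normal": 1, "I": 1, "II": 1.4, "III": 2, "IV": 3}
        x = pd.Series(
            [rng.normal(means[c], 0.6) for c in design["condition"]],
            index=design.index, name="g",
        )
        call = classify_trends(x, design)
        raw = dunn_posthoc(
            {s: x[design.index[design["condition"] == s]].to_numpy() for s in ("I", "II", "III", "IV")}
        )
        assert list(call.posthoc_p.sort_values().index) == list(raw.sort_values().index)


class TestVifSelect:
    def test_orthogonal_covariates_all_kept(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(0, 1, (50, 4)))
        x = pd.DataFrame(q, columns=list("abcd"))
        assert vif_select(x) == list("abcd")

    def test_exact_duplicate_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        x = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(0, 1, 40)})
        kept = vif_select(x)
        assert "b" in kept and len(kept) == 2

    def test_survivors_all_below_threshold(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
        x = pd.DataFrame({"a": a, "b": b, "c": a + b + rng.normal(0, 0.05, 60)})
        kept = vif_select(x, threshold=10)
        # independent recomputation of the survivors' VIFs
        sub = x[kept].to_numpy()
        for j in range(len(kept)):
            others = np.delete(sub, j, axis=1)
            d = np.column_stack([np.ones(len(sub)), others])
            beta, *_ = np.linalg.lstsq(d, sub[:, j], rcond=None)
            res = sub[:, j] - d @ beta
            r2 = 1 - res @ res / ((sub[:, j] - sub[:, j].mean()) ** 2).sum()
            assert 1.0 / (1.0 - r2) < 10


class TestFitCox:
    def test_perfect_risk_ordering_gives_unit_c_index(self):
        n = 20
        expr = pd.DataFrame(
            {"g0": np.arange(n, dtype=float)}, index=[f"p{i}" for i in range(n)]
        ).T
        surv = pd.DataFrame(
            {"time": np.arange(n, 0, -1, dtype=float), "event": np.ones(n, int)},
            index=expr.columns,
        )
        model = fit_cox(["g0"], expr, surv)
        assert model.c_index == pytest.approx(1.0)

    def test_hazard_ratios_equal_exp_coefficients(self):
        expr = expr_frame(5, genes=2, n=150)
        spec = SurvivalEffectSpec(("g0",), log_hazard_per_unit=0.7, censoring_rate=0.1)
        surv = generate_survival(expr, spec, seed=5)
        model = fit_cox(["g0", "g1"], expr, surv)
        assert np.allclose(model.hazard_ratios, np.exp(model.coefficients))

    def test_zero_events_rejected(self):
        expr = expr_frame(0, genes=1, n=10)
        surv = pd.DataFrame(
            {"time": np.arange(1.0, 11.0), "event": np.zeros(10, int)}, index=expr.columns
        )
        with pytest.raises(ValueError, match="events"):
            fit_cox(["g0"], expr, surv)


class TestStratification:
    def test_eight_distinct_scores_split_two_four_two(self):
        s = pd.Series(np.arange(1.0, 9.0), index=[f"p{i}" for i in range(8)])
        strata = quartile_strata(s)
        counts = strata.value_counts()
        assert counts["low"] == 2 and counts["medium"] == 4 and counts["high"] == 2
        assert set(strata[["p0", "p1"]]) == {"low"}
        assert set(strata[["p6", "p7"]]) == {"high"}

    def test_identical_scores_all_medium(self):
        s = pd.Series([3.0] * 6, index=[f"p{i}" for i in range(6)])
        assert (quartile_strata(s) == "medium").all()

    def test_partition_is_total(self):
        rng = np.random.default_rng(3)
        s = pd.Series(rng.exponential(1, 37), index=[f"p{i}" for i in range(37)])
        strata = quartile_strata(s)
        assert strata.isin(["low", "medium", "high"]).all()
        assert len(strata) == 37

    def test_planted_effect_cohort_orders_km_curves(self):
        expr = expr_frame(9, genes=3, n=300)
        spec = SurvivalEffectSpec(("g0", "g1"), log_hazard_per_unit=1.2, censoring_rate=0.2)
        surv = generate_survival(expr, spec, seed=9)
        model = fit_cox(["g0", "g1"], expr, surv)
        strata = stratify_risk(model, expr)
        p = strata_logrank(strata, surv)
        assert p < 0.05
        med = surv.groupby(strata)["time"].median()
        assert med["low"] > med["medium"] > med["high"]


class TestSvmValidate:
    @staticmethod
    def _cohort(seed, effect=0.0, n=60):
        rng = np.random.default_rng(seed)
        labels = pd.Series(
            ["normal"] * n + ["I"] * n,
            index=[f"s{i}" for i in range(2 * n)],
        )
        e = pd.DataFrame(
            rng.normal(0, 1, (4, 2 * n)),
            index=[f"g{i}" for i in range(4)],
            columns=labels.index,
        )
        e.loc[:, labels == "I"] += effect
        return e, labels

    def test_separable_classes_high_accuracy(self):
        e, labels = self._cohort(0, effect=3.0)
        out = svm_validate(e, labels, seed=0)
        assert out["accuracy"] >= 95.0

    def test_permuted_labels_near_chance(self):
        accs = []
        for seed in range(5):
            e, labels = self._cohort(seed, effect=3.0)
            rng = np.random.default_rng(seed)
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            accs.append(svm_validate(e, perm, seed=seed)["accuracy"])
        assert 35.0 <= float(np.median(accs)) <= 65.0

    def test_stratified_folds_balanced(self):
        from sklearn.model_selection import StratifiedKFold

        e, labels = self._cohort(1, effect=1.0, n=31)
        y = labels.to_numpy()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
        global_ratio = (y == "I").mean()
        for _, test in skf.split(e.T.to_numpy(), y):
            fold = y[test]
            assert abs((fold == "I").sum() - global_ratio * len(fold)) <= 1

    def test_small_class_rejected(self):
        e, labels = self._cohort(2, n=10)
        small = labels[list(labels.index[:4]) + list(labels.index[-10:])]
        with pytest.raises(ValueError, match="at least 5"):
            svm_validate(e[small.index], small)
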