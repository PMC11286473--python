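"""Standardization, t-test filter, Lasso selection, group assembly."""

import numpy as np
import pandas as pd
import pytest

from perfrad.selection import (
    GROUP_NAMES,
    assemble_group,
    group_regions,
    lasso_select,
    select_region_features,
    standardize,
    ttest_filter,
)


class TestStandardize:
    def test_hand_case(self):
        t = pd.DataFrame({"f": [0.0, 5.0, 10.0]})
        std, stats = standardize(t, t.index)
        np.testing.assert_allclose(std["f"], [-0.5, 0.0, 0.5])

    def test_constant_column_maps_to_zero(self):
        t = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning, match="constant feature"):
            std, _ = standardize(t, t.index)
        assert (std["f"] == 0.0).all()

    def test_two_value_column(self):
        t = pd.DataFrame({"f": [1.0, 2.0]})
        std, stats = standardize(t, t.index)
        np.testing.assert_allclose(std["f"], [-0.5, 0.5])
        assert stats.mean["f"] == 1.5
        assert (stats.max["f"] - stats.min["f"]) == 1.0

    def test_fit_statistics_ignore_test_rows(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"f": rng.normal(size=10)})
        fit_rows = t.index[:6]
        _, stats_a = standardize(t, fit_rows)
        shuffled = pd.concat([t.iloc[:6], t.iloc[6:].sample(frac=1, random_state=1)])
        _, stats_b = standardize(shuffled, fit_rows)
        t2 = t.copy()
        t2.iloc[6:] = 999.0  # changing test rows must not change the fit
        _, stats_c = standardize(t2, fit_rows)
        assert stats_a.mean.equals(stats_b.mean) and stats_a.mean.equals(stats_c.mean)

    def test_empty_fit_set(self):
        t = pd.DataFrame({"f": [1.0]})
        with pytest.raises(ValueError, match="empty fit set"):
            standardize(t, [])


class TestTtestFilter:
    def test_no_group_difference_dropped(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=20)
        t = pd.DataFrame({"f": np.concatenate([vals, vals])})
        y = pd.Series([0] * 20 + [1] * 20)
        rep = ttest_filter(t, y)
        assert rep.loc["f", "p"] == pytest.approx(1.0)
        assert not rep.loc["f", "passed_ttest"]

    def test_large_effect_retained(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({"f": np.concatenate([rng.normal(0, 1e-3, 5), 1 + rng.normal(0, 1e-3, 5)])})
        y = pd.Series([0] * 5 + [1] * 5)
        rep = ttest_filter(t, y)
        assert rep.loc["f", "p"] < 1e-6
        assert rep.loc["f", "passed_ttest"]

    def test_strict_alpha_boundary(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"f": rng.normal(size=20)})
        y = pd.Series([0] * 10 + [1] * 10)
        p = ttest_filter(t, y).loc["f", "p"]
        assert not ttest_filter(t, y, alpha=p).loc["f", "passed_ttest"]  # p == alpha drops

    def test_type_one_error_calibrated(self):
        # 1000 null features, 30 vs 30 subjects: retained fraction inside
        # the binomial 99% CI around alpha=0.05
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.standard_normal((60, 1000)))
        t.columns = [f"f{i}" for i in t.columns]
        y = pd.Series([0] * 30 + [1] * 30)
        frac = ttest_filter(t, y).passed_ttest.mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - half <= frac <= 0.05 + half

    def test_small_class_rejected(self):
        t = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="at least 2"):
            ttest_filter(t, pd.Series([0, 1, 1]))


class TestLassoSelect:
    def test_planted_feature_dominates(self):
        rng = np.random.default_rng(11)
        n = 60
        y = pd.Series(rng.integers(0, 2, n))
        X = pd.DataFrame(rng.standard_normal((n, 51)))
        X.columns = [f"f{i}" for i in range(51)]
        X["f0"] = y + rng.normal(0, 0.05, n)
        rep = lasso_select(X, y, seed=0)
        assert rep.loc["f0", "retained"]
        assert rep.lasso_weight.abs().idxmax() == "f0"

    def test_pure_noise_may_select_nothing(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("abcde"))
        y = pd.Series(rng.integers(0, 2, 30))
        rep = lasso_select(X, y, seed=0)  # must not raise, whatever is kept
        assert set(rep.index) == set("abcde")
        assert rep.retained.dtype == bool

    def test_duplicated_informative_columns(self):
        rng = np.random.default_rng(13)
        n = 60
        y = pd.Series(rng.integers(0, 2, n))
        base = y + rng.normal(0, 0.1, n)
        X = pd.DataFrame({"a": base, "b": base, "c": rng.standard_normal(n)})
        rep = lasso_select(X, y, seed=0)
        assert rep.loc[["a", "b"], "retained"].any()

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="no features"):
            rep = lasso_select(pd.DataFrame(index=range(4)), pd.Series([0, 1, 0, 1]))
        assert len(rep) == 0

    def test_constant_labels_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            lasso_select(X, pd.Series([1, 1, 1]))


def _schema_table(rng, n, spec):
    """Feature table with schema names; spec maps column -> effect size d."""
    cols = {}
    y = pd.Series([0] * (n // 2) + [1] * (n - n // 2), index=[f"s{i}" for i in range(n)])
    for name, d in spec.items():
        x = rng.standard_normal(n)
        x[y.to_numpy() == 1] += d
        cols[name] = x
    return pd.DataFrame(cols, index=y.index), y


class TestRegionPipeline:
    def test_inclusion_chain_and_recovery(self):
        rng = np.random.default_rng(21)
        spec = {f"ischemic__CBF__original__firstorder__F{i}": 0.0 for i in range(20)}
        spec["ischemic__CBF__original__firstorder__Planted"] = 2.5
        spec["ischemic__Tmax__original__firstorder__Planted2"] = 2.5
        table, y = _schema_table(rng, 60, spec)
        std, rep = select_region_features(table, y, table.index, seed=0)
        survivors = set(rep.table.index[rep.table.passed_ttest])
        retained = set(rep.retained)
        assert retained <= survivors <= set(table.columns)
        assert "ischemic__CBF__original__firstorder__Planted" in retained
        assert "ischemic__Tmax__original__firstorder__Planted2" in retained
        # retained implies passed t-test and non-zero weight
        sub = rep.table[rep.table.retained]
        assert sub.passed_ttest.all() and (sub.lasso_weight != 0).all()

    def test_planted_sensitivity_over_seeds(self):
        # planted features at effect size d=1.5, n=60: selection sensitivity
        # at least 0.9 over 50 simulated tables
        hits, total = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            spec = {f"ischemic__CBF__original__firstorder__N{i}": 0.0 for i in range(15)}
            for i in range(4):
                spec[f"ischemic__CBF__original__firstorder__P{i}"] = 1.5
            table, y = _schema_table(rng, 60, spec)
            _, rep = select_region_features(table, y, table.index, seed=seed)
            hits += sum(1 for i in range(4)
                        if f"ischemic__CBF__original__firstorder__P{i}" in rep.retained)
            total += 4
        assert hits / total >= 0.9


class TestGroups:
    def test_group_enumeration(self):
        assert len(GROUP_NAMES) == 14
        assert sum(g.endswith("_radiomics") for g in GROUP_NAMES) == 7
        assert sum(g.endswith("_parameters") for g in GROUP_NAMES) == 7
        assert "Ischemic_infarct_radiomics" in GROUP_NAMES
        assert group_regions("Ischemic_hypoxic_parameters") == (("ischemic", "hypoxic"), "parameters")

    def _tables(self):
        idx = ["s0", "s1"]
        params = {
            r: pd.DataFrame({f"{r}__{m}": [1.0, 2.0] for m in ("CBF", "CBV", "MTT", "Tmax")}, index=idx)
            for r in ("ischemic", "infarct", "hypoxic")
        }
        radiomics = {
            "ischemic": pd.DataFrame(np.ones((2, 3)), index=idx,
                                     columns=[f"ischemic__CBF__original__firstorder__F{i}" for i in range(3)]),
            "infarct": pd.DataFrame(np.ones((2, 2)), index=idx,
                                    columns=[f"infarct__CBF__original__firstorder__F{i}" for i in range(2)]),
        }
        return radiomics, params

    def test_parameter_group_widths(self):
        radiomics, params = self._tables()
        assert assemble_group("Ischemic_parameters", radiomics, params).shape[1] == 4
        assert assemble_group("Ischemic_infarct_hypoxic_parameters", radiomics, params).shape[1] == 12

    def test_radiomics_concatenation_width(self):
        radiomics, params = self._tables()
        out = assemble_group("Ischemic_infarct_radiomics", radiomics, params)
        assert out.shape[1] == 3 + 2

    def test_unknown_group_name_lists_valid(self):
        radiomics, params = self._tables()
        with pytest.raises(ValueError, match="Ischemic_radiomics"):
            assemble_group("Ischemic_radiomic", radiomics, params)

    def test_missing_region_rejected(self):
        radiomics, params = self._tables()
        with pytest.raises(ValueError, match="hypoxic"):
            assemble_group("Ischemic_hypoxic_radiomics", radiomics, params)
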