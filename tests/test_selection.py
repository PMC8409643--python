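"""Correlation grouping, univariate selection, jackknife pruning, AICc
tuning, variable importance, response curves, extent comparison."""

import numpy as np
import pandas as pd
import pytest

from growrisk import (
    GridError,
    GridSpec,
    SampleTable,
    aicc_formula,
    assign_folds,
    compare_extent_models,
    compute_aicc,
    group_correlated,
    response_curve,
    stepwise_jackknife,
    tune_hyperparameters,
    univariate_select,
    variable_importance,
)
from growrisk.maxent import FeatureSpec, expand_features, fit_maxent
from growrisk.selection import CVEvaluator
from conftest import make_stack


def table_from_arrays(X_pres, X_bg, names, k=5, seed=0):
    dfs = []
    for flag, X in [(1, X_pres), (0, X_bg)]:
        d = pd.DataFrame(X, columns=names)
        d.insert(0, "presence", flag)
        d.insert(1, "id", [f"{'p' if flag else 'b'}{i}" for i in range(len(X))])
        d.insert(2, "x", 0.0)
        d.insert(3, "y", 0.0)
        dfs.append(d)
    t = SampleTable(pd.concat(dfs, ignore_index=True), list(names))
    return assign_folds(t, k=k, seed=seed)


def signal_noise_table(n_pres=60, n_bg=400, seed=0, k=5):
    """Presences concentrated at high values of 'signal'; 'noise' is
    uninformative."""
    rng = np.random.default_rng(seed)
    bg = np.column_stack([rng.uniform(0, 1, n_bg), rng.uniform(0, 1, n_bg)])
    w = np.exp(4 * bg[:, 0])
    idx = rng.choice(n_bg, size=n_pres, p=w / w.sum())
    pres = bg[idx] + rng.normal(0, 0.01, size=(n_pres, 2))
    return table_from_arrays(pres, bg, ["signal", "noise"], k=k, seed=seed)


class TestGrouping:
    def test_duplicated_column_grouped(self, rng):
        x = rng.random(100)
        t = table_from_arrays(np.column_stack([x[:20], x[:20]]),
                              np.column_stack([x[20:], x[20:]]), ["a", "b"])
        groups = group_correlated(t)
        assert [sorted(g.members) for g in groups] == [["a", "b"]]

    def test_independent_noise_all_singletons(self, rng):
        X = rng.random((200, 3))
        t = table_from_arrays(X[:40], X[40:], ["a", "b", "c"])
        groups = group_correlated(t)
        assert all(len(g.members) == 1 for g in groups)

    def test_boundary_correlation_is_strict(self):
        # construct |r| exactly 0.7 via a 2-point trick is fragile; use the
        # threshold argument instead: r = 1 pair grouped at 0.999 threshold,
        # not grouped at threshold 1.0 semantics (strict >)
        x = np.linspace(0, 1, 50)
        t = table_from_arrays(np.column_stack([x[:10], x[:10]]),
                              np.column_stack([x[10:], x[10:]]), ["a", "b"])
        groups = group_correlated(t, threshold=1.0)  # |r| = 1 is not > 1
        assert all(len(g.members) == 1 for g in groups)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        n_var = 6
        base = rng.random((150, n_var))
        # randomly duplicate some columns with noise to induce groups
        for j in range(1, n_var):
            if rng.random() < 0.5:
                base[:, j] = base[:, j - 1] + rng.normal(0, 0.1, 150)
        names = list("abcdef")
        t = table_from_arrays(base[:30], base[30:], names)
        groups = group_correlated(t)
        # brute force: transitive closure over the |r| > 0.7 edge set
        R = np.corrcoef(t.values("all"), rowvar=False)
        adj = np.abs(R) > 0.7
        np.fill_diagonal(adj, False)
        reach = adj.copy()
        for m in range(n_var):
            reach = reach | (reach @ reach)
        expected = set()
        seen = set()
        for i in range(n_var):
            if i in seen:
                continue
            comp = {i} | {j for j in range(n_var) if reach[i, j]}
            seen |= comp
            expected.add(frozenset(names[j] for j in comp))
        got = {frozenset(g.members) for g in groups}
        assert got == expected

    def test_constant_variable_singleton_with_warning(self, rng):
        X = np.column_stack([rng.random(100), np.ones(100)])
        t = table_from_arrays(X[:20], X[20:], ["a", "const"])
        with pytest.warns(UserWarning, match="constant"):
            groups = group_correlated(t)
        assert {frozenset(g.members) for g in groups} == {
            frozenset(["a"]), frozenset(["const"])}


class TestUnivariateSelect:
    def test_singleton_passthrough_without_fitting(self):
        from growrisk.selection import VariableGroup
        t = signal_noise_table()
        groups = [VariableGroup(["signal"]), VariableGroup(["noise"])]
        selected = univariate_select(groups, t, evaluator=_DummyEvaluator())
        assert selected == ["signal", "noise"]

    def test_signal_beats_noise(self):
        from growrisk.selection import VariableGroup
        wins = 0
        for seed in range(5):
            t = signal_noise_table(seed=seed)
            ev = CVEvaluator(t, spec=FeatureSpec("auto", 10))
            sel = univariate_select([VariableGroup(["signal", "noise"])], t, ev)
            wins += sel == ["signal"]
        assert wins >= 4

    def test_exact_tie_broken_lexicographically(self, rng):
        x = rng.random(150)
        t = table_from_arrays(np.column_stack([x[:30], x[:30]]),
                              np.column_stack([x[30:], x[30:]]), ["b_var", "a_var"])
        from growrisk.selection import VariableGroup
        ev = CVEvaluator(t, spec=FeatureSpec("lqp"))
        sel = univariate_select([VariableGroup(["b_var", "a_var"])], t, ev)
        assert sel == ["a_var"]


class _DummyEvaluator:
    def mean_test_auc(self, variables, r=1.0):  # pragma: no cover
        raise AssertionError("singleton groups must not trigger fits")


class TestJackknife:
    def test_single_variable_trace_empty(self):
        t = signal_noise_table()
        ev = CVEvaluator(t, spec=FeatureSpec("lqp"))
        trace = stepwise_jackknife(["signal"], ev)
        assert trace.steps == [] and trace.retained == ["signal"]

    def test_noise_removed_first(self):
        removed_first = 0
        for seed in range(5):
            t = signal_noise_table(seed=10 + seed)
            ev = CVEvaluator(t, spec=FeatureSpec("auto", 10))
            trace = stepwise_jackknife(["signal", "noise"], ev)
            if trace.steps and trace.steps[0][0] == "noise":
                removed_first += 1
            elif not trace.steps:
                removed_first += 1  # stopped: every removal hurt
        assert removed_first >= 4

    def test_retained_auc_at_least_full_set(self):
        t = signal_noise_table(seed=3)
        ev = CVEvaluator(t, spec=FeatureSpec("auto", 10))
        trace = stepwise_jackknife(["signal", "noise"], ev)
        assert trace.retained_auc >= trace.full_auc - 1e-12


class TestAICc:
    def test_hand_formula(self):
        # K=3, LL=-10, n=20 -> 6 + 20 + 24/16 = 27.5
        assert aicc_formula(3, -10.0, 20) == pytest.approx(27.5)

    def test_standardized_grid_likelihood_and_invalid_flag(self, rng):
        Xp = rng.uniform(0, 1, (12, 2))
        Xb = rng.uniform(0, 1, (100, 2))
        fm = expand_features(Xp, Xb, ["a", "b"], FeatureSpec("lqp"))
        model = fit_maxent(fm, r=1.0)
        Xg = rng.uniform(0, 1, (400, 2))
        res = compute_aicc(model, Xp, Xg)
        # grid-standardized probabilities sum to 1
        s = fm.expander.transform(Xg) @ model.lambdas
        p = np.exp(s - s.max())
        p /= p.sum()
        assert p.sum() == pytest.approx(1.0)
        if res.valid:
            assert res.AICc == pytest.approx(
                aicc_formula(res.K, res.LL, 12))
        # force invalidity: n too small relative to K
        res2 = compute_aicc(model, Xp[: max(model.n_nonzero, 2) - 0], Xg)
        if model.n_nonzero >= len(Xp) - 1:
            assert not res2.valid


class TestTuning:
    @pytest.fixture(scope="class")
    def tuned(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(20, 20, 90.0)
        vals = rng.random((20, 20))
        stack = make_stack(grid, a=vals, b=rng.random((20, 20)))
        bg = np.column_stack([rng.uniform(0, 1, 300), rng.uniform(0, 1, 300)])
        w = np.exp(3 * bg[:, 0])
        pres = bg[rng.choice(300, size=40, p=w / w.sum())]
        t = table_from_arrays(pres, bg, ["a", "b"])
        return tune_hyperparameters(t, ["a", "b"], stack, n_hinge_knots=10), t

    def test_eighteen_combinations(self, tuned):
        result, _ = tuned
        assert len(result.table) == 18
        assert result.winner[0] in ("auto", "lqp", "hinge")

    def test_winner_minimizes_aicc(self, tuned):
        result, _ = tuned
        valid = result.table[result.table["valid"]]
        best = valid["AICc"].min()
        win = result.table[(result.table["mode"] == result.winner[0])
                           & (result.table["multiplier"] == result.winner[1])]
        assert win["AICc"].iloc[0] == pytest.approx(best)

    def test_sparsity_weakly_decreasing_in_multiplier(self, tuned):
        result, _ = tuned
        for mode in ("lqp", "hinge", "auto"):
            sub = result.table[result.table["mode"] == mode].sort_values("multiplier")
            K = sub["K"].to_numpy()
            # L1 path: allow tiny non-monotonicity from solver tolerance
            assert np.all(np.diff(K) <= 2)


class TestImportance:
    def test_single_variable_gets_everything(self, rng):
        bg = rng.uniform(0, 1, (200, 1))
        w = np.exp(3 * bg[:, 0])
        pres = bg[rng.choice(200, size=30, p=w / w.sum())]
        t = table_from_arrays(pres, bg, ["only"])
        fm = expand_features(pres, bg, ["only"], FeatureSpec("lqp"))
        model = fit_maxent(fm, r=1.0)
        imp = variable_importance(model, t, seed=0)
        assert imp["percent_contribution"].iloc[0] == pytest.approx(100.0)
        assert imp["permutation_importance"].iloc[0] == pytest.approx(100.0)

    def test_dominant_signal_outranks_noise(self):
        t = signal_noise_table(seed=4)
        Xp = t.values("presence")
        Xb = t.values("background")
        fm = expand_features(Xp, Xb, ["signal", "noise"], FeatureSpec("lqp"))
        model = fit_maxent(fm, r=1.0)
        imp = variable_importance(model, t, seed=0).set_index("variable")
        assert (imp.loc["signal", "permutation_importance"]
                > imp.loc["noise", "permutation_importance"])
        assert imp["percent_contribution"].sum() == pytest.approx(100.0, abs=0.1)
        assert imp["permutation_importance"].sum() == pytest.approx(100.0, abs=0.1)


class TestResponseCurve:
    def test_linear_mode_monotone(self):
        t = signal_noise_table(seed=6)
        curve = response_curve(t, "signal", mode="linear", n_points=50)
        y = curve["logistic"].to_numpy()
        assert np.all(np.diff(y) >= -1e-12)
        assert len(curve) == 50

    def test_unknown_variable_errors(self):
        t = signal_noise_table()
        with pytest.raises(GridError):
            response_curve(t, "missing")


class TestExtentComparison:
    def test_single_region_matches_pooled(self):
        t = signal_noise_table(seed=7, k=5)
        df = t.df.copy()
        df["region"] = "R1"
        t2 = SampleTable(df, t.variables)
        out = compare_extent_models(t2, k=5, seed=0)
        assert len(out) == 2
        assert out["mean_test_auc"].iloc[0] == pytest.approx(
            out["mean_test_auc"].iloc[1], abs=0.05)

    def test_small_region_skipped_with_warning(self):
        t = signal_noise_table(seed=8, k=5)
        df = t.df.copy()
        df["region"] = "big"
        pres_idx = df.index[df["presence"] == 1][:3]
        df.loc[pres_idx, "region"] = "tiny"
        t2 = SampleTable(df, t.variables)
        with pytest.warns(UserWarning, match="tiny"):
            out = compare_extent_models(t2, k=5, seed=0)
        assert set(out["region"]) == {"all", "big"}
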