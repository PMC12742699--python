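import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncmorph import (StepwiseConfig, error_rates, fit_lda, iterate_confirmative,
                     loo_error_rates, pearson_with_latitude, pvalue_from_r,
                     stepwise_lda, stepwise_select, ttest_table)


def two_group_frame(rng, n=60, p=6, shift=None, names=None):
    names = names or [f"v{i}" for i in range(p)]
    X = rng.normal(size=(2 * n, p))
    if shift is not None:
        X[n:] += shift
    labels = pd.Series(["A"] * n + ["B"] * n)
    return pd.DataFrame(X, columns=names), labels


class TestStepwiseSelect:
    def test_single_informative_variable(self, rng):
        shift = np.zeros(6)
        shift[2] = 3.0
        data, labels = two_group_frame(rng, shift=shift)
        selected, _ = stepwise_select(data, labels)
        assert selected == ["v2"]

    def test_identical_groups_select_nothing(self, rng):
        data, labels = two_group_frame(rng, n=40)
        selected, _ = stepwise_select(data, labels)
        assert selected == []

    def test_two_informative_among_noise(self, rng):
        shift = np.zeros(14)
        shift[[3, 9]] = 2.0
        data, labels = two_group_frame(rng, n=200, p=14, shift=shift)
        selected, log = stepwise_select(data, labels)
        assert {"v3", "v9"} <= set(selected)
        assert len(set(selected) - {"v3", "v9"}) <= 1
        assert log[0]["step"] == "enter"

    def test_f_thresholds_bracket_selection(self, rng):
        shift = np.zeros(5)
        shift[0] = 1.0
        data, labels = two_group_frame(rng, n=50, p=5, shift=shift)
        none = stepwise_select(data, labels,
                               config=StepwiseConfig(f_enter=1e9, f_remove=1e8))
        assert none[0] == []
        everything = stepwise_select(
            data, labels, config=StepwiseConfig(f_enter=1e-9, f_remove=1e-10))
        assert set(everything[0]) == set(data.columns)

    def test_first_step_equals_anova_f(self, rng):
        # entering the first variable reduces to the one-way F statistic
        data, labels = two_group_frame(rng, n=30, p=1,
                                       shift=np.array([1.2]), names=["x"])
        _, log = stepwise_select(data, labels,
                                 config=StepwiseConfig(f_enter=0.001, f_remove=0.0005))
        a = data.loc[labels == "A", "x"]
        b = data.loc[labels == "B", "x"]
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert log[0]["partial_F"] == pytest.approx(t ** 2, rel=1e-9)


class TestFitLda:
    def test_symmetric_1d_boundary_at_zero(self):
        data = pd.DataFrame({"x": [-2.0, -1.0, -1.5, 1.0, 2.0, 1.5]})
        labels = pd.Series(["neg"] * 3 + ["pos"] * 3)
        model = fit_lda(data, labels, ["x"], positive_group="pos")
        s = model.score(data)
        assert np.all(s[:3] < 0) and np.all(s[3:] > 0)
        # midpoint of group means scores zero
        mid = pd.DataFrame({"x": [data["x"][:3].mean() / 2 + data["x"][3:].mean() / 2]})
        assert model.score(mid).iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_group_means_score_opposite_and_equal(self, rng):
        data, labels = two_group_frame(rng, n=40, p=3, shift=np.ones(3))
        model = fit_lda(data, labels, list(data.columns))
        means = data.groupby(labels.values).mean()
        s = model.score(means)
        assert s.iloc[0] == pytest.approx(-s.iloc[1], rel=1e-9)

    def test_label_swap_antisymmetry(self, rng):
        data, labels = two_group_frame(rng, n=30, p=4, shift=np.ones(4))
        m1 = fit_lda(data, labels, list(data.columns), positive_group="B")
        m2 = fit_lda(data, labels, list(data.columns), positive_group="A")
        np.testing.assert_allclose(m1.score(data), -m2.score(data), rtol=1e-9)

    def test_affine_rescaling_invariance(self, rng):
        data, labels = two_group_frame(rng, n=40, p=3, shift=np.ones(3))
        model = fit_lda(data, labels, list(data.columns))
        rescaled = data.copy()
        rescaled["v0"] = data["v0"] * 250.0 + 7.0  # e.g. unit change
        model2 = fit_lda(rescaled, labels, list(data.columns))
        np.testing.assert_allclose(model.score(data), model2.score(rescaled),
                                   rtol=1e-8)

    def test_singular_covariance_raises(self):
        data = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        labels = pd.Series(["x", "x", "y", "y"])
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(data, labels, ["a", "b"])


class TestErrorRates:
    def test_separable_data_zero_percent(self, rng):
        data, labels = two_group_frame(rng, n=25, p=2, shift=np.array([8.0, 8.0]))
        nests = pd.Series([f"nest{i // 5}" for i in range(50)])
        model = fit_lda(data, labels, list(data.columns))
        err = error_rates(model, data, labels, nest_ids=nests)
        assert (err["error_pct"] == 0).all()
        assert set(err["level"]) == {"worker", "nest"}

    def test_counting_one_mislabelled_worker(self, rng):
        data, labels = two_group_frame(rng, n=50, p=1, shift=np.array([10.0]))
        flipped = labels.copy()
        flipped.iloc[0] = "B"  # one A-worker mislabelled
        model = fit_lda(data, labels, ["v0"])
        err = error_rates(model, data, flipped)
        b_row = err[(err["group"] == "B") & (err["level"] == "worker")].iloc[0]
        assert b_row["n"] == 51
        assert b_row["error_pct"] == pytest.approx(100.0 / 51)

    def test_loo_close_to_resubstitution_when_separable(self, rng):
        data, labels = two_group_frame(rng, n=20, p=2, shift=np.array([8.0, 8.0]))
        loo = loo_error_rates(data, labels, list(data.columns))
        assert (loo["error_pct"] == 0).all()


class TestConfirmative:
    def test_no_wildcards_is_fixed_point(self, rng):
        data, labels = two_group_frame(rng, n=30, p=3, shift=np.ones(3) * 4)
        nests = pd.Series([f"n{i // 3}" for i in range(60)])
        nest_labels = {f"n{i // 3}": labels[i] for i in range(60)}
        final, model, info = iterate_confirmative(data, nests, nest_labels, [])
        assert info == {"iterations": 1, "converged": True, "unassignable": []}
        assert dict(final) == nest_labels

    def test_wildcards_assigned_to_nearest_group(self, rng):
        data, labels = two_group_frame(rng, n=30, p=3, shift=np.ones(3) * 5)
        nests = pd.Series([f"n{i // 3}" for i in range(60)])
        nest_labels = {f"n{i // 3}": labels[i] for i in range(60)}
        wild = ["n0", "n12"]  # one from each side withheld
        known = {k: v for k, v in nest_labels.items() if k not in wild}
        final, model, info = iterate_confirmative(data, nests, known, wild)
        assert info["converged"]
        assert final["n0"] == nest_labels["n0"]
        assert final["n12"] == nest_labels["n12"]

    def test_synthetic_recovery_with_ambiguous_nests(self, small_synth):
        records, truth = small_synth
        nest_species = pd.Series(truth["nest_species"])
        wild = list(nest_species.index[::5])  # withhold every fifth nest
        known = {n: s for n, s in nest_species.items() if n not in wild}
        from ncmorph.morphodata import CHARACTERS
        final, model, info = iterate_confirmative(
            records, records["nest_id"], known, wild,
            variables=CHARACTERS, positive_group="imitans")
        assert info["converged"] and info["iterations"] <= 3
        agreement = (final.reindex(nest_species.index) == nest_species).mean()
        assert agreement >= 1.0 - truth["bayes_error_worker"] - 0.05


class TestPearson:
    def test_perfect_and_hand_computed(self):
        r = pearson_with_latitude([0, 1, 2], [0, 1, 2])
        assert r.R == pytest.approx(1.0)
        r2 = pearson_with_latitude([0, 1, 2], [0, 2, 1])
        assert r2.R == pytest.approx(0.5)

    def test_matches_scipy_on_random_pairs(self, rng):
        x, y = rng.normal(size=(2, 12))
        ours = pearson_with_latitude(x, y)
        ref_r, ref_p = stats.pearsonr(x, y)
        assert ours.R == pytest.approx(ref_r, rel=1e-12)
        assert ours.p == pytest.approx(ref_p, rel=1e-9)

    def test_t_transform_consistency(self):
        # R = -0.2680 with n = 100 corresponds to two-sided p ~= 0.0070
        assert pvalue_from_r(-0.2680, 100) == pytest.approx(0.0070, abs=5e-5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_latitude([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestTtestTable:
    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(size=30)
        df = pd.DataFrame({"species": ["a"] * 30 + ["b"] * 30,
                           "CS": np.concatenate([vals, vals])})
        table = ttest_table(df, characters=["CS"])
        assert table.loc[0, "p"] == pytest.approx(1.0)
        assert not table.loc[0, "significant_holm"]

    def test_forced_difference_significant_after_holm(self, rng):
        df = pd.DataFrame({
            "species": ["a"] * 50 + ["b"] * 50,
            "CS": np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)]),
            "x": rng.normal(size=100),
        })
        table = ttest_table(df, characters=["CS", "x"]).set_index("character")
        assert table.loc["CS", "p"] < 1e-10
        assert table.loc["CS", "significant_holm"]
        assert not table.loc["x", "significant_holm"]

    def test_equal_variance_statistic_matches_pooled_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        df = pd.DataFrame({"species": ["a"] * 3 + ["b"] * 3,
                           "CS": np.concatenate([a, b])})
        table = ttest_table(df, characters=["CS"])
        sp = np.sqrt(((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4))
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert table.loc[0, "t"] == pytest.approx(t_hand, rel=1e-12)

    def test_synthetic_species_differ_in_offset_indices(self, default_synth):
        from ncmorph import compute_indices
        records, _ = default_synth
        table = ttest_table(compute_indices(records)).set_index("character")
        assert len(table) == 14  # CS + 13 indices
        # the offset pattern makes the shape indices differ strongly
        assert table.loc["HTL/CS", "significant_holm"]
        assert table.loc["SL/CS", "significant_holm"]
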