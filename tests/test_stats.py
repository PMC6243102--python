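import numpy as np
import pandas as pd
import pytest

import improvlearn as il
from oracles import mixed_anova_ss_oracle


def anova_frame(Y, groups):
    rows = []
    for i, (row, grp) in enumerate(zip(Y, groups)):
        for j, value in enumerate(row):
            rows.append({
                "piece_id": f"s{i}", "musician_id": grp,
                "pattern": f"w{j}", "logit_tp": float(value),
            })
    return pd.DataFrame(rows)


class TestPca:
    def test_identical_rows_one_orthogonal(self):
        frame = pd.DataFrame(
            [[1.0, 0.1, 0.9, 0.2], [1.0, 0.1, 0.9, 0.2], [0.1, 1.0, 0.2, 0.9]],
            index=["a", "b", "c"],
        )
        result = il.run_pca(frame)
        pc1 = result.loadings["PC1"]
        assert np.sign(pc1["a"]) == np.sign(pc1["b"]) != np.sign(pc1["c"]) or (
            abs(pc1["a"] - pc1["b"]) < 1e-9 and abs(pc1["c"] - pc1["a"]) > 0.1
        )

    def test_eigenvalue_sum_equals_piece_count(self, rng):
        frame = pd.DataFrame(rng.random((6, 20)), index=[f"p{i}" for i in range(6)])
        result = il.run_pca(frame)
        assert result.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)
        assert result.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(result.eigenvalues) <= 1e-12).all()
        assert (result.retained == (result.eigenvalues > 1.0)).all()

    def test_group_profiles_separate_on_first_component(self, rng):
        base_a, base_b = rng.random(30), rng.random(30)
        rows, index = [], []
        for i in range(5):
            rows.append(base_a + rng.normal(0, 0.02, 30))
            index.append(f"a{i}")
        for i in range(5):
            rows.append(base_b + rng.normal(0, 0.02, 30))
            index.append(f"b{i}")
        result = il.run_pca(pd.DataFrame(rows, index=index))
        sil = il.loading_silhouette(
            result, {pid: pid[0] for pid in index}
        )
        assert sil > 0.5

    def test_constant_row_names_offender(self):
        frame = pd.DataFrame(
            [[0.5, 0.5, 0.5], [0.1, 0.2, 0.7], [0.3, 0.3, 0.4]],
            index=["flat", "x", "y"],
        )
        with pytest.raises(ValueError, match="flat"):
            il.run_pca(frame)

    def test_too_few_pieces_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            il.run_pca(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"]))


class TestMixedAnova:
    def test_constant_data_yields_null_result(self):
        Y = np.ones((9, 3))
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        result = il.run_anova(anova_frame(Y, groups))
        assert (result.effects["F"] <= 1e-9).all()
        assert (result.effects["p"] >= 0.999).all()

    def test_np2_matches_bruteforce_sums_of_squares(self, rng):
        Y = rng.normal(size=(9, 3))
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        result = il.run_anova(anova_frame(Y, groups))
        oracle = mixed_anova_ss_oracle(Y, groups)
        effects = result.effects.set_index("effect")
        assert effects.loc["musician", "np2"] == pytest.approx(
            oracle["np2_between"], abs=1e-9
        )
        assert effects.loc["sequence", "np2"] == pytest.approx(
            oracle["np2_within"], abs=1e-9
        )
        assert effects.loc["musician x sequence", "np2"] == pytest.approx(
            oracle["np2_inter"], abs=1e-9
        )

    def test_unbalanced_design_rejected(self, rng):
        frame = anova_frame(rng.normal(size=(6, 3)), ["A"] * 3 + ["B"] * 3)
        frame = frame.iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            il.run_anova(frame)

    def test_injected_interaction_detected_with_power(self, rng):
        """A musician x pattern interaction of d = 2.5 cell shift is detected
        reliably at 7 pieces per musician."""
        hits, reps = 0, 150
        for _ in range(reps):
            Y = rng.normal(0, 0.6, size=(21, 3))
            Y[:7, 0] += 1.5  # one group shifted on one pattern only
            groups = ["A"] * 7 + ["B"] * 7 + ["C"] * 7
            result = il.run_anova(anova_frame(Y, groups))
            p = result.effects.set_index("effect").loc["musician x sequence", "p"]
            hits += p < 0.05
        assert hits / reps > 0.8

    def test_gg_correction_shrinks_dfs_when_sphericity_violated(self, rng):
        # strongly heterogeneous covariance across 4 within levels
        n = 30
        base = rng.normal(size=(n, 1))
        Y = np.hstack([
            base * 3 + rng.normal(0, 0.1, (n, 1)),
            base * 3 + rng.normal(0, 0.1, (n, 1)),
            rng.normal(0, 1.0, (n, 2)),
        ])
        groups = ["A"] * (n // 2) + ["B"] * (n // 2)
        result = il.run_anova(anova_frame(Y, groups))
        if result.gg_applied:
            seq = result.effects.set_index("effect").loc["sequence"]
            assert seq["df1"] < 3.0  # corrected below the uncorrected k-1 = 3
        else:
            assert result.mauchly_p >= 0.05

    def test_posthoc_is_bonferroni_adjusted(self, rng):
        Y = rng.normal(size=(9, 3))
        Y[:3] += 2.0
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        result = il.run_anova(anova_frame(Y, groups))
        pcorr = "p_corr" if "p_corr" in result.posthoc.columns else "p-corr"
        punc = "p_unc" if "p_unc" in result.posthoc.columns else "p-unc"
        sub = result.posthoc.dropna(subset=[pcorr])
        assert (sub[pcorr] >= sub[punc] - 1e-12).all()
        assert (result.posthoc["p_adjust"].dropna() == "bonf").all()


class TestStepwise:
    def test_perfect_predictor_selected(self):
        y = [1, 2, 3, 4, 5, 6, 7]
        X = pd.DataFrame({"lin": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]})
        result = il.stepwise_regression(y, X)
        assert result.selected == ["lin"]
        assert result.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert result.predictors.iloc[0]["B"] == pytest.approx(10.0, abs=1e-6)

    def test_empty_model_is_valid_under_noise(self, rng):
        nonempty = 0
        reps = 100
        for _ in range(reps):
            X = pd.DataFrame(
                {f"n{i}": rng.normal(size=7) for i in range(5)}
            )
            result = il.stepwise_regression(list(range(1, 8)), X)
            nonempty += not result.is_empty
        assert nonempty / reps <= 0.15

    def test_drifting_pattern_recovered_with_sign(self, rng):
        k = np.arange(1, 8)
        X = pd.DataFrame({
            "drift": 0.2 + 0.04 * (k - 1) + rng.normal(0, 0.02, 7),
            "noise1": 0.2 + rng.normal(0, 0.02, 7),
            "noise2": 0.2 + rng.normal(0, 0.02, 7),
        })
        result = il.stepwise_regression(list(k), X)
        assert "drift" in result.selected
        b = result.predictors.set_index("name").loc["drift", "B"]
        assert b > 0

    def test_collinear_duplicate_refused(self, rng):
        k = np.arange(1, 8)
        signal = 0.2 + 0.05 * (k - 1) + rng.normal(0, 0.01, 7)
        X = pd.DataFrame({"a": signal, "b": signal + 1e-9})
        result = il.stepwise_regression(list(k), X)
        assert len(result.selected) == 1
        assert result.condition_index < 20

    def test_vif_reported_for_selected(self, rng):
        k = np.arange(1, 8)
        X = pd.DataFrame({
            "x1": 0.1 * k + rng.normal(0, 0.05, 7),
            "x2": rng.normal(0, 1, 7),
        })
        result = il.stepwise_regression(list(k), X)
        if not result.is_empty:
            assert (result.predictors["VIF"] < 2.0).all()

    def test_response_must_be_chronological_permutation(self):
        X = pd.DataFrame({"x": np.arange(7.0)})
        with pytest.raises(ValueError, match="permutation"):
            il.stepwise_regression([1, 2, 3, 4, 5, 6, 8], X)

    def test_order_invariance_of_selection(self, rng):
        k = np.arange(1, 8)
        X = pd.DataFrame({
            "a": 0.3 + 0.05 * (k - 1) + rng.normal(0, 0.02, 7),
            "b": rng.normal(size=7),
            "c": rng.normal(size=7),
        })
        r1 = il.stepwise_regression(list(k), X)
        r2 = il.stepwise_regression(list(k), X[["c", "b", "a"]])
        assert sorted(r1.selected) == sorted(r2.selected)


class TestConditionIndex:
    def test_orthogonal_design_is_well_conditioned(self):
        X = np.column_stack([np.ones(8), np.tile([1, -1], 4), np.repeat([1, -1], 4)])
        assert il.condition_index(X) == pytest.approx(1.0, abs=1e-9)

    def test_near_singular_design_is_flagged(self):
        x = np.arange(8.0)
        X = np.column_stack([np.ones(8), x, x + 1e-9])
        assert il.condition_index(X) > 1e3
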