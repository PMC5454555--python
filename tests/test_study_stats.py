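"""Repeated-measures ANOVA and Bonferroni post-hocs, checked against
closed-form and brute-force sequential least-squares oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import balancelab as bl
from balancelab.study_stats import validate_long_table


def _long_table(values, sexes=None):
    """values: (n_subjects, k_conditions) array."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    sexes = sexes if sexes is not None else ["male" if i % 2 else "female" for i in range(n)]
    rows = [
        {"participant_id": f"P{i:02d}", "sex": sexes[i], "condition": f"C{j}",
         "value": values[i, j]}
        for i in range(n)
        for j in range(k)
    ]
    return pd.DataFrame(rows)


def sequential_ss_oracle(df):
    """Brute-force sequential (Type I) SS via nested least-squares fits.

    Design order: intercept, sex, subject indicators, condition indicators.
    The SS of each term is the drop in residual sum of squares when the
    term's columns enter the design.
    """
    y = df["value"].to_numpy(dtype=float)
    ones = np.ones((len(df), 1))
    sex = pd.get_dummies(df["participant_id"].map(
        df.groupby("participant_id")["sex"].first()), drop_first=False).to_numpy(float)
    subj = pd.get_dummies(df["participant_id"]).to_numpy(float)
    cond = pd.get_dummies(df["condition"]).to_numpy(float)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    r0 = rss(ones)
    r1 = rss(np.hstack([ones, sex]))
    r2 = rss(np.hstack([ones, sex, subj]))
    r3 = rss(np.hstack([ones, sex, subj, cond]))
    return {
        "total": r0,
        "covariate": r0 - r1,
        "subject": r1 - r2,
        "exercise": r2 - r3,
        "residual": r3,
    }


class TestReciprocalTransform:
    def test_elementwise_values(self):
        np.testing.assert_allclose(bl.reciprocal_transform([2.0, 4.0]), [0.5, 0.25])
        np.testing.assert_allclose(bl.reciprocal_transform([1.0]), [1.0])

    def test_involution(self):
        x = np.array([0.5, 1.0, 3.7, 9.81])
        np.testing.assert_allclose(bl.reciprocal_transform(bl.reciprocal_transform(x)), x)

    def test_nonpositive_input_names_row(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            bl.reciprocal_transform([1.0, 2.0, 0.0, 3.0])


class TestRmAnova:
    def test_constant_data_has_no_exercise_effect(self):
        res = bl.rm_anova(_long_table(np.full((4, 3), 2.5)))
        assert res.ss_exercise == pytest.approx(0.0)
        assert np.isnan(res.f_exercise)
        assert res.p_exercise == 1.0

    def test_pure_condition_offsets_match_closed_form(self):
        """No noise, no subject effect: SS_exercise = Σ_j n(μ_j − μ̄)², SS_res = 0."""
        offsets = np.array([1.0, 3.0, 7.0, 9.0])
        n = 6
        values = np.tile(offsets, (n, 1))
        res = bl.rm_anova(_long_table(values), covariate=None)
        expected = n * ((offsets - offsets.mean()) ** 2).sum()
        assert res.ss_exercise == pytest.approx(expected, rel=1e-12)
        assert res.ss_residual == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("covariate", ["sex", None])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_glm(self, seed, covariate):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(3, 9), rng.integers(2, 9)
        values = (rng.normal(0, 1, (n, 1)) + rng.normal(0, 2, (1, k))
                  + rng.normal(0, 0.5, (n, k)))
        df = _long_table(values)
        res = bl.rm_anova(df, covariate=covariate)
        oracle = sequential_ss_oracle(df)
        assert res.ss_exercise == pytest.approx(oracle["exercise"], rel=1e-8, abs=1e-10)
        assert res.ss_residual == pytest.approx(oracle["residual"], rel=1e-8, abs=1e-10)
        if covariate == "sex":
            assert res.ss_covariate == pytest.approx(oracle["covariate"], rel=1e-8, abs=1e-10)
            assert res.ss_subject == pytest.approx(oracle["subject"], rel=1e-8, abs=1e-10)
        assert res.ss_total == pytest.approx(oracle["total"], rel=1e-10)

    def test_ss_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            df = _long_table(rng.normal(0, 1, (5, 4)))
            res = bl.rm_anova(df)
            total = res.ss_covariate + res.ss_subject + res.ss_exercise + res.ss_residual
            assert total == pytest.approx(res.ss_total, rel=1e-9)

    def test_two_conditions_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, (10, 2)) + [0.0, 0.8]
        res = bl.rm_anova(_long_table(values), covariate=None)
        t, p = stats.ttest_rel(values[:, 0], values[:, 1])
        assert res.f_exercise == pytest.approx(t**2, rel=1e-8)
        assert res.p_exercise == pytest.approx(p, rel=1e-8)

    def test_permuting_condition_labels_preserves_exercise_ss(self):
        rng = np.random.default_rng(9)
        df = _long_table(rng.normal(0, 1, (5, 4)))
        relabel = {"C0": "C3", "C1": "C2", "C2": "C0", "C3": "C1"}
        df2 = df.assign(condition=df["condition"].map(relabel))
        assert bl.rm_anova(df2).ss_exercise == pytest.approx(bl.rm_anova(df).ss_exercise)

    def test_unbalanced_design_lists_missing_cells(self):
        df = _long_table(np.ones((3, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            bl.rm_anova(df)

    def test_covariate_varying_within_participant_rejected(self):
        df = _long_table(np.ones((3, 3)))
        df.loc[0, "sex"] = "male"
        df.loc[1, "sex"] = "female"
        with pytest.raises(ValueError, match="varies within"):
            bl.rm_anova(df)

    def test_duplicate_cell_rejected(self):
        df = _long_table(np.ones((3, 3)))
        df = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            bl.rm_anova(df)

    def test_exercise_effect_detected_on_simulated_knee_trials(self):
        """Sway amplitudes rising with difficulty must yield p < 0.05 in
        nearly all seeded replicates."""
        params = bl.SwayParams()
        hits = 0
        n_rep = 20
        for seed in range(1, n_rep + 1):
            rows = []
            for pi in range(2):
                for cond in bl.CONDITIONS:
                    rec = bl.simulate_trial(
                        cond, "left", "knee", params,
                        seed=np.random.default_rng([seed, pi, bl.CONDITIONS.index(cond)]),
                    )
                    tm = bl.mean_r(rec, "deviation")
                    rows.append({"participant_id": f"P{pi}", "sex": "female",
                                 "condition": cond, "value": 1.0 / tm.mean_r})
            res = bl.rm_anova(pd.DataFrame(rows), covariate=None)
            hits += res.p_exercise < 0.05
        assert hits >= 0.95 * n_rep


class TestBonferroniPairwise:
    def test_two_conditions_single_pair_unadjusted(self):
        rng = np.random.default_rng(10)
        df = _long_table(rng.normal(0, 1, (6, 2)))
        out = bl.bonferroni_pairwise(df)
        assert len(out) == 1
        assert out.loc[0, "p_adjusted"] == pytest.approx(out.loc[0, "p_raw"])

    def test_eight_conditions_give_28_pairs_with_multiplier(self):
        rng = np.random.default_rng(11)
        df = _long_table(rng.normal(0, 1, (5, 8)))
        out = bl.bonferroni_pairwise(df)
        assert len(out) == 28
        adjustable = out[out["p_raw"] * 28 <= 1.0]
        np.testing.assert_allclose(adjustable["p_adjusted"], adjustable["p_raw"] * 28)
        assert (out["p_adjusted"] <= 1.0).all()

    def test_identical_conditions_give_zero_difference_and_unit_p(self):
        values = np.ones((4, 3))
        values[:, 2] = [1.0, 2.0, 3.0, 4.0]
        out = bl.bonferroni_pairwise(_long_table(values))
        row = out[(out.condition_a == "C0") & (out.condition_b == "C1")].iloc[0]
        assert row.mean_difference == 0.0
        assert row.p_raw == 1.0

    def test_validate_long_table_passthrough(self):
        df = _long_table(np.ones((3, 3)))
        assert validate_long_table(df) is df
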