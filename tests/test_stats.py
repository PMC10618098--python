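"""Mixed models, FDR, permutation alignment, demographics statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from brainctl import (bh_fdr, cohens_d, control_input_diff,
                      demographics_table, efficiency, fit_efficiency_model,
                      fit_energy_model, receptor_alignment_suite,
                      receptor_alignment_test)


def crossover_table(n_per_group=10, effects=(0.0, 0.0, 0.0, 0.0),
                    noise_sd=0.0, subject_sd=0.0, seed=0,
                    task="memory", condition="threat"):
    """Balanced 2x2 crossover energies: intercept, group, drug, interaction."""
    rng = np.random.default_rng(seed)
    b0, bg, bd, bgd = effects
    rows = []
    for g, group in enumerate(("control", "relative")):
        for i in range(n_per_group):
            subj = f"{group[0]}{i}"
            a = rng.normal(0, subject_sd)
            for d, drug in enumerate(("placebo", "alprazolam")):
                y = b0 + bg * g + bd * d + bgd * g * d + a \
                    + rng.normal(0, noise_sd)
                rows.append((subj, group, drug, task, condition, y))
    return pd.DataFrame(rows, columns=["subject", "group", "drug", "task",
                                       "condition", "energy"])


class TestEnergyModel:
    def test_constant_outcome_degenerate(self):
        df = crossover_table(effects=(3.0, 0, 0, 0))
        res = fit_energy_model(df, "memory", "threat", standardize=False)
        assert res.coef("gamma00")["estimate"] == pytest.approx(3.0)
        for sym in ("gamma01", "beta1i", "gamma11"):
            assert res.coef(sym)["estimate"] == 0.0

    def test_matches_ols_on_balanced_zero_variance_data(self):
        # no subject variance: mixed fixed effects equal plain least squares
        df = crossover_table(effects=(1.0, 0.5, -0.3, 0.8), noise_sd=0.2,
                             seed=4)
        res = fit_energy_model(df, "memory", "threat", standardize=False)
        X = np.column_stack([
            np.ones(len(df)),
            (df.group == "relative").astype(float),
            (df.drug == "alprazolam").astype(float),
            ((df.group == "relative") & (df.drug == "alprazolam")).astype(float),
        ])
        beta_ols = np.linalg.lstsq(X, df.energy.to_numpy(), rcond=None)[0]
        for sym, ref in zip(("gamma00", "gamma01", "beta1i", "gamma11"),
                            beta_ols):
            assert res.coef(sym)["estimate"] == pytest.approx(ref, abs=1e-6)

    def test_recovers_injected_interaction(self):
        df = crossover_table(effects=(1.0, 0.0, 0.0, 1.0), noise_sd=0.1,
                             subject_sd=0.3, seed=1)
        res = fit_energy_model(df, "memory", "threat", standardize=False)
        c = res.coef("gamma11")
        assert c["estimate"] == pytest.approx(1.0, abs=0.2)
        assert c["p"] < 0.05
        assert res.converged

    def test_requires_two_subjects_per_group(self):
        df = crossover_table(n_per_group=1)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_energy_model(df, "memory", "threat")


class TestEfficiencyModel:
    def _records(self, slope, noise_sd=0.0, seed=0, n=16):
        rng = np.random.default_rng(seed)
        rows = []
        for g, group in enumerate(("control", "relative")):
            for i in range(n):
                subj = f"{group[0]}{i}"
                age = rng.uniform(20, 60)
                sex = "F" if rng.uniform() < 0.5 else "M"
                for drug in ("placebo", "alprazolam"):
                    pe = rng.uniform(1, 5)
                    eff = 0.6 + slope * pe + rng.normal(0, noise_sd)
                    acc = 0.9
                    rows.append((subj, group, drug, "identification",
                                 "threat", pe, acc, acc / eff, age, sex))
        return pd.DataFrame(rows, columns=[
            "subject", "group", "drug", "task", "condition", "energy",
            "accuracy", "median_rt", "age", "sex"])

    def test_positive_coupling_detected(self):
        res = fit_efficiency_model(self._records(slope=0.1),
                                   "identification", "threat")
        c = res.coef("beta")
        assert c["estimate"] > 0
        assert c["p"] < 0.05

    def test_label_permutation_destroys_association(self):
        df = self._records(slope=0.1, noise_sd=0.01, seed=2)
        beta0 = abs(fit_efficiency_model(df, "identification", "threat")
                    .coef("beta")["estimate"])
        rng = np.random.default_rng(0)
        betas = []
        for _ in range(20):
            perm = df.copy()
            idx = rng.permutation(len(df))
            perm[["accuracy", "median_rt"]] = \
                df[["accuracy", "median_rt"]].to_numpy()[idx]
            betas.append(abs(fit_efficiency_model(perm, "identification",
                                                  "threat")
                             .coef("beta")["estimate"]))
        assert np.mean(betas) < 0.5 * beta0


class TestEfficiencyMeasure:
    @pytest.mark.parametrize("acc,rt,expected", [
        (1.0, 2.0, 0.5), (0.0, 1.7, 0.0), (0.9, 1.5, 0.6)])
    def test_values(self, acc, rt, expected):
        assert efficiency(acc, rt) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="median_rt"):
            efficiency(0.5, 0.0)
        with pytest.raises(ValueError, match="accuracy"):
            efficiency(1.5, 1.0)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_statsmodels_reference(self, rng):
        p = rng.uniform(size=40)
        np.testing.assert_allclose(bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1])

    def test_never_decreases_and_preserves_order(self, rng):
        p = rng.uniform(size=25)
        q = bh_fdr(p)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestControlInputDiff:
    def test_examples(self):
        np.testing.assert_array_equal(
            control_input_diff([1.0, 3.0], [2.0, 1.0]), [1.0, 2.0])
        np.testing.assert_array_equal(
            control_input_diff([1.0, 2.0], [1.0, 2.0]), [0.0, 0.0])
        np.testing.assert_array_equal(
            control_input_diff([1.0, 3.0], [2.0, 1.0], mode="signed"),
            [-1.0, 2.0])

    def test_parcel_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            control_input_diff([1.0], [1.0, 2.0])


class TestReceptorAlignment:
    def test_rank_identical_map_hits_p_floor(self, rng):
        receptor = rng.standard_normal(30)
        diff_maps = np.tile(receptor, (4, 1))
        res = receptor_alignment_test(diff_maps, receptor, n_perm=500, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 501)

    def test_observed_statistic_matches_scipy_oracle(self, rng):
        D = rng.standard_normal((5, 40))
        receptor = rng.standard_normal(40)
        res = receptor_alignment_test(D, receptor, n_perm=100, seed=1)
        ref = np.mean([spearmanr(d, receptor).statistic for d in D])
        assert res.observed == pytest.approx(ref, abs=1e-12)

    def test_seed_determinism(self, rng):
        D = rng.standard_normal((3, 20))
        receptor = rng.standard_normal(20)
        a = receptor_alignment_test(D, receptor, n_perm=200, seed=5)
        b = receptor_alignment_test(D, receptor, n_perm=200, seed=5)
        assert a.p == b.p

    def test_slab_mask_restricts(self, rng):
        D = rng.standard_normal((3, 20))
        receptor = rng.standard_normal(20)
        mask = np.array([True] * 10 + [False] * 10)
        res = receptor_alignment_test(D, receptor, n_perm=100, seed=2,
                                      slab_mask=mask)
        ref = np.mean([spearmanr(d[:10], receptor[:10]).statistic for d in D])
        assert res.observed == pytest.approx(ref, abs=1e-12)

    def test_constant_receptor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            receptor_alignment_test(rng.standard_normal((3, 10)),
                                    np.ones(10), n_perm=10, seed=0)

    def test_suite_applies_fdr_across_maps(self, rng):
        D = rng.standard_normal((4, 25))
        maps = pd.DataFrame(rng.standard_normal((25, 3)),
                            columns=["r1", "r2", "r3"])
        out = receptor_alignment_suite(D, maps, n_perm=100, seed=0)
        assert list(out["receptor"]) == ["r1", "r2", "r3"]
        np.testing.assert_allclose(out["q"], bh_fdr(out["p"].to_numpy()))


def table1_frame():
    """Reconstruction of the study's demographic counts from printed totals."""
    rows = []
    rows += [("control", "F", "R")] * 14 + [("control", "M", "R")] * 11
    rows += [("control", "M", "L")] * 2
    rows += [("relative", "F", "R")] * 10 + [("relative", "F", "L")] * 1
    rows += [("relative", "M", "R")] * 6 + [("relative", "M", "L")] * 3
    df = pd.DataFrame(rows, columns=["group", "sex", "handedness"])
    assert (df.group == "control").sum() == 27
    assert (df.group == "relative").sum() == 20
    return df


class TestDemographicsTable:
    def test_sex_odds_ratio_from_study_counts(self):
        # controls 14 F / 13 M vs relatives 11 F / 9 M
        out = demographics_table(table1_frame(), categorical=["sex"])
        row = out[out.variable == "sex"].iloc[0]
        assert row.odds_ratio == pytest.approx((14 * 9) / (13 * 11), abs=1e-9)
        assert row.p == pytest.approx(1.0, abs=0.01)

    def test_handedness_odds_ratio_left_event(self):
        # controls 25 R / 2 L vs relatives 16 R / 4 L with L as the event
        out = demographics_table(table1_frame(), categorical=["handedness"],
                                 events={"handedness": "L"})
        row = out[out.variable == "handedness"].iloc[0]
        assert row.odds_ratio == pytest.approx(0.32, abs=1e-9)

    def test_balanced_table_is_null(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"],
                           "smoke": ["Y", "N", "Y", "N"]})
        out = demographics_table(df, categorical=["smoke"])
        row = out.iloc[0]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p == pytest.approx(1.0)

    def test_zero_cell_or_undefined(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                           "v": ["x", "x", "x", "x", "y", "y"]})
        out = demographics_table(df, categorical=["v"])
        assert np.isnan(out.iloc[0].odds_ratio)

    def test_continuous_t_and_wilcoxon(self, rng):
        df = pd.DataFrame({
            "group": ["a"] * 15 + ["b"] * 15,
            "age": np.r_[rng.normal(40, 10, 15), rng.normal(45, 10, 15)],
            "score": np.r_[rng.normal(10, 2, 15), rng.normal(12, 2, 15)],
        })
        out = demographics_table(df, continuous=["score", "age"],
                                 nonnormal=("age",))
        t_row = out[out.variable == "score"].iloc[0]
        w_row = out[out.variable == "age"].iloc[0]
        assert t_row.test == "t_test" and "df=28" in t_row.note
        assert w_row.test == "wilcoxon_ranksum"
        assert np.isfinite(w_row.cohens_d)


class TestCohensD:
    def test_study_schizotypy_effect_size(self):
        # totals (11.5, 7.2, n=27) vs (15.0, 7.2, n=20): d = 3.5/7.2
        assert cohens_d(11.5, 7.2, 27, 15.0, 7.2, 20) == \
            pytest.approx(3.5 / 7.2, abs=1e-12)

    def test_basic_cases(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 1.0, 10) == 0.0
        assert cohens_d(0.0, 1.0, 10, 1.0, 1.0, 10) == pytest.approx(1.0)

    def test_degenerate_pooled_sd(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d(0.0, 0.0, 5, 1.0, 0.0, 5)
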