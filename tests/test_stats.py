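"""Statistical machinery against independent matrix-algebra oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from connica.simulate import DEFAULT_GROUP_SIZES, generate_weights
from connica.stats import (
    ALL_TESTS,
    DOMAINS,
    ZScoreTable,
    classify_mci,
    compute_zscores,
    fdr_adjust,
    nested_model_f,
    nested_model_report,
    posthoc_pairwise,
    rm_anova_trait,
    screen_traits,
)


def _control_stats(mean=10.0, sd=2.0):
    return pd.DataFrame({"mean": mean, "sd": sd}, index=list(ALL_TESTS))


def _ztable(z_frame):
    return ZScoreTable(z=z_frame, domain_composites=pd.DataFrame(), control_stats=_control_stats())


class TestZScores:
    def test_raw_equal_to_control_mean_is_zero(self):
        raw = pd.DataFrame({t: [10.0] for t in ALL_TESTS})
        table = compute_zscores(raw, _control_stats())
        assert (table.z == 0).all().all()

    def test_formula_raw8_mean10_sd2_gives_minus_one(self):
        raw = pd.DataFrame({"span_inverse": [8.0]})
        table = compute_zscores(raw, _control_stats())
        assert table.z.iloc[0, 0] == pytest.approx(-1.0)

    def test_domain_composite_is_mean_of_its_two_tests(self):
        raw = pd.DataFrame({t: [10.0] for t in ALL_TESTS})
        raw["span_inverse"] = 10.0 - 2 * 0.343  # z = -0.343
        raw["digit_symbol"] = 10.0 - 2 * 0.346  # z = -0.346
        table = compute_zscores(raw, _control_stats())
        assert table.domain_composites.loc[0, "attention"] == pytest.approx(-0.3445)

    def test_zero_control_sd_rejected(self):
        stats = _control_stats()
        stats.loc["ravlt", "sd"] = 0.0
        with pytest.raises(ValueError, match="ravlt"):
            compute_zscores(pd.DataFrame({"ravlt": [1.0]}), stats)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="no control stats"):
            compute_zscores(pd.DataFrame({"mystery": [1.0]}), _control_stats())


class TestMCIClassification:
    def _frame(self, overrides):
        data = {t: 0.0 for t in ALL_TESTS}
        data.update(overrides)
        return pd.DataFrame([data])

    def test_unimpaired_subject_is_cn(self):
        out = classify_mci(_ztable(self._frame({})))
        assert out.loc[0, "status"] == "CN"

    def test_two_impaired_tests_in_one_domain_is_mci(self):
        out = classify_mci(_ztable(self._frame({"span_inverse": -1.6, "digit_symbol": -1.6})))
        assert out.loc[0, "status"] == "MCI"
        assert out.loc[0, "impaired_tests"] == ["span_inverse", "digit_symbol"]

    def test_two_impaired_tests_across_domains_is_mci(self):
        out = classify_mci(_ztable(self._frame({"ravlt": -2.0, "boston_naming": -1.51})))
        assert out.loc[0, "status"] == "MCI"

    def test_single_deep_deficit_stays_cn(self):
        out = classify_mci(_ztable(self._frame({"trail_making": -2.5})))
        assert out.loc[0, "status"] == "CN"

    def test_boundary_minus_one_point_five_not_impaired(self):
        out = classify_mci(_ztable(self._frame({"ravlt": -1.5, "rocf": -1.5})))
        assert out.loc[0, "status"] == "CN"

    def test_missing_test_is_an_error(self):
        frame = self._frame({}).drop(columns=["rocf"])
        with pytest.raises(ValueError, match="missing test"):
            classify_mci(_ztable(frame))

    def test_hand_computed_twelve_subject_fixture(self):
        rng = np.random.default_rng(99)
        frame = pd.DataFrame(rng.normal(0, 1.2, size=(12, 10)), columns=list(ALL_TESTS))
        expected = ["MCI" if (row < -1.5).sum() >= 2 else "CN" for _, row in frame.iterrows()]
        out = classify_mci(_ztable(frame))
        assert out["status"].tolist() == expected
        assert "MCI" in expected and "CN" in expected  # fixture exercises both


def _design(n_per_group, rng, groups=("HC", "PD-CN", "PD-MCI")):
    rows = {}
    for g, n in zip(groups, n_per_group):
        for i in range(n):
            rows[f"{g}-{i}"] = {
                "group": g,
                "age": rng.normal(70, 5),
                "gender": rng.choice(["male", "female"]),
                "tgm": rng.normal(600, 50),
            }
    return pd.DataFrame(rows).T.rename_axis("subject")


def _weights_for(design, rng, shift=None):
    keys, vals = [], []
    for subj, row in design.iterrows():
        base = rng.normal()
        if shift and row["group"] in shift:
            base += shift[row["group"]]
        for sess in ("monoband", "multiband"):
            keys.append((subj, sess))
            vals.append(base + 0.2 * rng.normal())
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(keys, names=["subject", "session"]))


class TestRMAnova:
    def test_constant_weights_give_zero_f(self, rng):
        design = _design([5, 5, 5], rng)
        w = _weights_for(design, rng) * 0 + 3.0
        f, p = rm_anova_trait(w, design)
        assert f == 0.0 and p == 1.0

    def test_two_group_no_covariate_equals_classical_oneway_f(self, rng):
        design = _design([8, 9], rng, groups=("HC", "PD-CN"))
        w = _weights_for(design, rng, shift={"PD-CN": 1.0})
        f, p = rm_anova_trait(w, design, covariates=())
        means = w.groupby(level=0).mean()
        by_group = [means[design.index[design["group"] == g]] for g in ("HC", "PD-CN")]
        f_ref, p_ref = sstats.f_oneway(*by_group)
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_matches_rss_oracle_with_covariates(self, rng):
        for _ in range(25):
            design = _design([6, 6, 7], rng)
            w = _weights_for(design, rng, shift={"PD-MCI": 0.8})
            f, p = rm_anova_trait(w, design)
            # independent oracle: explicit RSS comparison via pseudo-inverse
            means = w.groupby(level=0).mean().loc[design.index].to_numpy()
            cov = np.column_stack(
                [
                    np.ones(len(design)),
                    design["age"].astype(float),
                    (design["gender"] == "male").astype(float),
                    design["tgm"].astype(float),
                ]
            )
            dummies = pd.get_dummies(design["group"]).to_numpy(dtype=float)[:, 1:]
            full = np.column_stack([cov, dummies])

            def rss(x):
                beta = np.linalg.pinv(x) @ means
                return ((means - x @ beta) ** 2).sum()

            df1, df2 = dummies.shape[1], len(design) - full.shape[1]
            f_ref = (rss(cov) - rss(full)) / df1 / (rss(full) / df2)
            assert f == pytest.approx(f_ref, abs=1e-8)
            assert p == pytest.approx(sstats.f.sf(f_ref, df1, df2), abs=1e-8)

    def test_null_rejection_rate_near_nominal(self):
        rejections = 0
        n_sims = 200
        rng = np.random.default_rng(7)
        design = _design([7, 7, 7], rng)
        for _ in range(n_sims):
            w = _weights_for(design, rng)
            _, p = rm_anova_trait(w, design)
            rejections += p < 0.05
        # binomial 99% envelope around 0.05 with n=200: [0.01, 0.10]
        assert 0.01 <= rejections / n_sims <= 0.10

    def test_constant_covariate_named_in_error(self, rng):
        design = _design([4, 4], rng, groups=("HC", "PD-CN"))
        design["tgm"] = 5.0
        with pytest.raises(ValueError, match="tgm"):
            rm_anova_trait(_weights_for(design, rng), design)


class TestPosthoc:
    def test_f_equals_squared_t_without_covariates(self, rng):
        design = _design([9, 8, 7], rng)
        w = _weights_for(design, rng, shift={"PD-MCI": 1.2})
        f, p = posthoc_pairwise(w, design, ("HC", "PD-MCI"), covariates=())
        means = w.groupby(level=0).mean()
        a = means[design.index[design["group"] == "HC"]]
        b = means[design.index[design["group"] == "PD-MCI"]]
        t, p_t = sstats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(p_t, abs=1e-10)

    def test_one_subject_per_group_never_a_silent_number(self, rng):
        design = _design([1, 1], rng, groups=("HC", "PD-CN"))
        with pytest.raises(ValueError):
            posthoc_pairwise(_weights_for(design, rng), design, ("HC", "PD-CN"))

    def test_permuted_labels_give_uniform_p(self, rng):
        design = _design([8, 8], rng, groups=("HC", "PD-CN"))
        w = _weights_for(design, rng)
        p_values = []
        labels = design["group"].to_numpy().copy()
        for _ in range(300):
            rng.shuffle(labels)
            d = design.copy()
            d["group"] = labels
            p_values.append(posthoc_pairwise(w, d, ("HC", "PD-CN"), covariates=())[1])
        assert sstats.kstest(p_values, "uniform").pvalue > 0.01

    def test_missing_group_rejected(self, rng):
        design = _design([4, 4], rng, groups=("HC", "PD-CN"))
        with pytest.raises(ValueError, match="present"):
            posthoc_pairwise(_weights_for(design, rng), design, ("HC", "PD-MCI"))


class TestFDR:
    def test_single_p_is_its_own_q(self):
        q, flags = fdr_adjust([0.03])
        assert q[0] == pytest.approx(0.03)
        assert flags[0]

    def test_step_up_worked_example(self):
        q, flags = fdr_adjust([0.001, 0.02, 0.03, 0.04, 0.2])
        assert flags.tolist() == [True, True, True, True, False]

    def test_matches_hand_coded_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            q, flags = fdr_adjust(p, q=0.05)
            # independent Benjamini-Hochberg step-up
            n = p.size
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * n / rank)
                adj[idx] = running
            assert np.allclose(q, adj, atol=1e-12)
            assert np.array_equal(flags, adj < 0.05)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestNestedModelF:
    def _baseline(self, n, rng):
        return pd.DataFrame(
            {
                "age": rng.normal(70, 5, n),
                "sequence": np.tile([0.0, 1.0], n // 2),
                "avg_enorm": rng.normal(0.1, 0.02, n),
                "tgm": rng.normal(600, 40, n),
                "etiv": rng.normal(1500, 120, n),
            }
        )

    def test_copy_of_baseline_variable_raises_collinearity(self, rng):
        base = self._baseline(40, rng)
        y = rng.normal(size=40)
        with pytest.raises(ValueError, match="collinear"):
            nested_model_f(y, base, base["age"])

    def test_partial_f_grows_as_noise_shrinks(self, rng):
        base = self._baseline(60, rng)
        y = rng.normal(size=60)
        f_values = []
        for noise in (2.0, 0.5, 0.1):
            x = y + rng.normal(0, noise, 60)
            f_values.append(nested_model_f(y, base, x)[0])
        assert f_values[0] < f_values[1] < f_values[2]
        assert nested_model_f(y, base, y + rng.normal(0, 1e-8, 60))[1] < 1e-30

    def test_both_f_variants_match_rss_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 40)) * 2
            base = self._baseline(n, rng)
            x = rng.normal(size=n)
            y = 0.4 * x + 0.01 * base["age"].to_numpy() + rng.normal(size=n)
            rep = nested_model_report(y, base, x)

            def rss(cols):
                m = np.column_stack([np.ones(n)] + cols)
                beta = np.linalg.pinv(m) @ y
                return ((y - m @ beta) ** 2).sum()

            cols_b = [base[c].to_numpy(dtype=float) for c in base.columns]
            rss_b, rss_a = rss(cols_b), rss(cols_b + [x])
            f_partial = (rss_b - rss_a) / 1 / (rss_a / (n - 7))
            rss_0 = ((y - y.mean()) ** 2).sum()
            f_overall = (rss_0 - rss_a) / 6 / (rss_a / (n - 7))
            assert rep["partial_f"] == pytest.approx(f_partial, abs=1e-8)
            assert rep["overall_f"] == pytest.approx(f_overall, abs=1e-8)
            assert rep["partial_df"] == (1, n - 7)
            assert rep["overall_df"] == (6, n - 7)
            assert rep["delta_r2"] == pytest.approx((rss_b - rss_a) / rss_0, abs=1e-10)

    def test_df_mirror_the_pooled_126_row_design(self, rng):
        base = self._baseline(126, rng)
        rep = nested_model_report(rng.normal(size=126), base, rng.normal(size=126))
        assert rep["overall_df"] == (6, 119)


class TestScreening:
    def test_planted_effect_trait_is_flagged(self):
        rng = np.random.default_rng(0)
        weights, groups = generate_weights(
            DEFAULT_GROUP_SIZES, n_traits=10, effect_trait=3, effect_size=1.5, seed=0
        )
        design = pd.DataFrame(
            {
                "group": groups,
                "age": rng.normal(70, 5, len(groups)),
                "gender": rng.choice(["male", "female"], len(groups)),
                "tgm": rng.normal(600, 40, len(groups)),
            },
            index=groups.index,
        ).rename_axis("subject")
        results = screen_traits(weights, design)
        assert results[3].significant
        assert results[3].posthoc  # follow-up ran for the flagged trait
        assert all(r.q_value >= r.p_value - 1e-15 for r in results)
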