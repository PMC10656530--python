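"""Synthetic-cohort generator: determinism, invariants, planted structure."""

import numpy as np
import pandas as pd
import pytest

from connica.connectome import SESSIONS, vectorize_fc
from connica.parcellation import make_parcellation
from connica.simulate import (
    DEFAULT_GROUP_SIZES,
    CohortConfig,
    generate_cohort,
    generate_trait_patterns,
    generate_weights,
    synthesize_clinical,
    synthesize_fc,
    synthesize_timeseries,
)

from conftest import SMALL_GROUPS


@pytest.fixture(scope="module")
def parc():
    return make_parcellation(40)


class TestTraitPatterns:
    def test_single_pattern_has_unit_norm(self, parc):
        patterns = generate_trait_patterns(parc, 1, seed=0)
        assert np.linalg.norm(patterns[0]) == pytest.approx(1.0)

    def test_pairwise_cosines_below_threshold(self):
        parc100 = make_parcellation(100)
        patterns = generate_trait_patterns(parc100, 5, seed=3)
        assert patterns.shape == (5, 4950)
        cos = patterns @ patterns.T
        off = cos[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.3)

    def test_deterministic_under_seed(self, parc):
        a = generate_trait_patterns(parc, 3, seed=11)
        b = generate_trait_patterns(parc, 3, seed=11)
        assert np.array_equal(a, b)

    def test_too_many_traits_fails_loudly(self):
        tiny = make_parcellation(30)
        with pytest.raises(RuntimeError, match="cosine"):
            generate_trait_patterns(tiny, 200, seed=0, max_redraws=3)


class TestWeights:
    def test_row_count_matches_the_emulated_cohort(self):
        weights, groups = generate_weights(DEFAULT_GROUP_SIZES, n_traits=5, seed=0)
        assert weights.shape == (126, 5)  # 63 subjects x 2 sequences
        assert groups.value_counts().to_dict() == DEFAULT_GROUP_SIZES

    def test_zero_jitter_copies_weights_across_sessions(self):
        weights, _ = generate_weights(
            SMALL_GROUPS, n_traits=4, effect_size=1.5, session_effect_sd=0.0, seed=2
        )
        mono = weights.xs(SESSIONS[0], level=1)
        multi = weights.xs(SESSIONS[1], level=1)
        assert np.array_equal(mono.to_numpy(), multi.to_numpy())

    def test_null_effect_groups_exchangeable(self):
        diffs = []
        for seed in range(100):
            weights, groups = generate_weights(
                {"HC": 10, "PD-MCI": 10}, n_traits=1, effect_size=0.0, seed=seed
            )
            means = weights.groupby(level=0).mean()[0]
            by = means.groupby(groups).mean()
            diffs.append(by["PD-MCI"] - by["HC"])
        # mean difference ~ N(0, 2/10), so the Monte-Carlo mean of 100
        # draws stays within ~3 standard errors of zero
        assert abs(np.mean(diffs)) < 3 * np.sqrt(2 / 10 / 100)

    def test_effect_shifts_only_the_designated_column(self):
        w0, g = generate_weights(SMALL_GROUPS, 3, effect_trait=1, effect_size=0.0, seed=5)
        w1, _ = generate_weights(SMALL_GROUPS, 3, effect_trait=1, effect_size=2.0, seed=5)
        delta = (w1 - w0).to_numpy()
        mci_rows = g.reindex(w0.index.get_level_values(0)).to_numpy() == "PD-MCI"
        assert np.allclose(delta[~mci_rows], 0)
        assert np.allclose(delta[mci_rows, 1], 2.0)
        assert np.allclose(delta[:, [0, 2]], 0)

    def test_unknown_group_key_rejected(self):
        with pytest.raises(KeyError):
            generate_weights({"HC": 5}, 2, effect_group="PD-MCI", seed=0)


class TestSynthesizeFC:
    def test_noiseless_single_trait_is_squashed_pattern(self, parc):
        patterns = generate_trait_patterns(parc, 1, seed=1)
        weights = pd.DataFrame(
            [[2.0], [2.0]],
            index=pd.MultiIndex.from_product([["s1"], SESSIONS]),
        )
        fcs, _ = synthesize_fc(patterns, weights, edge_noise_sd=0.0, seed=0)
        edge = vectorize_fc(fcs[("s1", "monoband")])
        assert np.allclose(edge, np.tanh(2.0 * patterns[0]), atol=1e-12)

    def test_output_matrices_are_valid_fc(self, small_cohort):
        for fc in small_cohort.fc_matrices.values():
            v = fc.values
            assert np.array_equal(v, v.T)
            assert np.all(np.diag(v) == 1.0)
            off = v[~np.eye(v.shape[0], dtype=bool)]
            assert np.all(np.abs(off) < 1.0)

    def test_signal_correlation_decreases_with_noise(self, parc):
        patterns = generate_trait_patterns(parc, 2, seed=2)
        weights, _ = generate_weights(SMALL_GROUPS, 2, seed=3)
        composite = weights.to_numpy() @ patterns
        cors = []
        for noise in (0.0, 0.05, 0.5):
            fcs, _ = synthesize_fc(patterns, weights, edge_noise_sd=noise, seed=4)
            stack = np.vstack([vectorize_fc(fc) for fc in fcs.values()])
            pre_squash = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
            cors.append(np.corrcoef(pre_squash.ravel(), composite.ravel())[0, 1])
        assert cors[0] == pytest.approx(1.0, abs=1e-9)
        assert cors[0] > cors[1] > cors[2]

    def test_auto_noise_calibration_targets_half_variance(self, parc):
        patterns = generate_trait_patterns(parc, 3, seed=6)
        weights, _ = generate_weights(SMALL_GROUPS, 3, seed=7)
        _, sd = synthesize_fc(patterns, weights, edge_noise_sd=None, seed=8)
        signal = weights.to_numpy() @ patterns
        assert sd == pytest.approx(np.sqrt((signal**2).mean()), rel=1e-12)


class TestSynthesizeTimeseries:
    def test_identity_target_gives_near_zero_correlations(self):
        ts, correction = synthesize_timeseries(np.eye(12), n_frames=2000, seed=0)
        assert correction == 0.0
        r = np.corrcoef(ts.values, rowvar=False)
        off = np.abs(r[~np.eye(12, dtype=bool)])
        assert np.quantile(off, 0.99) < 3 / np.sqrt(2000)

    def test_pd_target_recovered_at_large_t(self, rng):
        a = rng.normal(size=(8, 8))
        cov = a @ a.T + 8 * np.eye(8)
        d = np.sqrt(np.diag(cov))
        target = cov / np.outer(d, d)
        ts, correction = synthesize_timeseries(target, n_frames=10000, seed=1)
        assert correction < 1e-10
        emp = np.corrcoef(ts.values, rowvar=False)
        i, j = np.triu_indices(8, k=1)
        assert np.abs(emp[i, j] - target[i, j]).mean() <= 0.05

    def test_deterministic_under_seed(self):
        a, _ = synthesize_timeseries(np.eye(5), 100, seed=9)
        b, _ = synthesize_timeseries(np.eye(5), 100, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_non_square_target_rejected(self):
        with pytest.raises(ValueError):
            synthesize_timeseries(np.zeros((3, 4)), 10)


class TestSynthesizeClinical:
    def test_hc_subjects_carry_zero_updrs(self, small_cohort):
        for s in small_cohort.subjects:
            if s.group == "HC":
                assert s.clinical["MDS-UPDRS-III"] == 0.0

    def test_z_back_computation_through_control_stats(self):
        from connica.simulate import DEFAULT_CONTROL_STATS
        from connica.stats import compute_zscores

        weights, groups = generate_weights(SMALL_GROUPS, 2, seed=1)
        records = synthesize_clinical(weights, 0, groups, seed=1)
        raw = pd.DataFrame({s.subject_id: s.raw_tests for s in records}).T
        table = compute_zscores(raw, DEFAULT_CONTROL_STATS)
        # raw scores were built as mean + z * sd, so z-scoring must invert:
        # a raw score of mean - 1 sd lands exactly at z = -1
        probe = DEFAULT_CONTROL_STATS.loc["ravlt"]
        z = (probe["mean"] - probe["sd"] - probe["mean"]) / probe["sd"]
        assert z == -1.0
        assert np.isfinite(table.z.to_numpy()).all()

    def test_coefficients_link_scores_to_planted_weights(self):
        weights, groups = generate_weights(
            DEFAULT_GROUP_SIZES, 3, effect_trait=0, effect_size=0.0, seed=4
        )
        records = synthesize_clinical(
            weights, 0, groups, coeff_map={"memory": -0.8}, clinical_noise_sd=0.1, seed=4
        )
        mean_w = weights[0].groupby(level=0).mean()
        memory = pd.Series({s.subject_id: s.clinical["memory"] for s in records})
        r = np.corrcoef(mean_w[memory.index], memory)[0, 1]
        assert r < -0.8  # strong negative link as configured

    def test_missing_control_entry_rejected(self):
        weights, groups = generate_weights(SMALL_GROUPS, 1, seed=0)
        bad_stats = pd.DataFrame({"mean": [1.0], "sd": [1.0]}, index=["span_inverse"])
        with pytest.raises(ValueError, match="control_stats"):
            synthesize_clinical(weights, 0, groups, control_stats=bad_stats)


class TestCohort:
    def test_cohort_determinism_is_bitwise(self):
        cfg = CohortConfig(group_sizes=dict(SMALL_GROUPS), n_rois=30, n_traits=2, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(CohortConfig(group_sizes=dict(SMALL_GROUPS), n_rois=30, n_traits=2, seed=7))
        assert np.array_equal(a.ground_truth.trait_patterns, b.ground_truth.trait_patterns)
        for key in a.fc_matrices:
            assert np.array_equal(a.fc_matrices[key].values, b.fc_matrices[key].values)
        assert a.design_frame().equals(b.design_frame())

    def test_two_sessions_per_subject_and_group_sizes(self, small_cohort):
        sessions = pd.Series([k[1] for k in small_cohort.fc_matrices])
        assert sessions.value_counts().to_dict() == {
            "monoband": len(small_cohort.subjects),
            "multiband": len(small_cohort.subjects),
        }
        by_group = pd.Series([s.group for s in small_cohort.subjects]).value_counts()
        assert by_group.to_dict() == SMALL_GROUPS
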