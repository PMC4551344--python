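"""Screening, selection and decomposition behave like their definitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stromasig.datatypes import ExpressionCohort
from stromasig.discovery import (
    DiscoveryConfig,
    collapse_probes,
    evaluate_components_loocv,
    fast_statistic,
    local_fdr,
    pca_metagenes,
    permutation_pvalue,
    split_signature,
    variance_filter,
)
from stromasig.synthetic import CohortSpec, generate_survival_cohort
from conftest import brute_force_cox_score


def _cohort(matrix, time=None, event=None, probe_map=None):
    n = matrix.shape[1]
    samples = list(matrix.columns)
    if time is None:
        time = pd.Series(np.arange(1, n + 1, dtype=float), index=samples)
    if event is None:
        event = pd.Series(np.ones(n, dtype=int), index=samples)
    return ExpressionCohort(matrix=matrix, time=time, event=event,
                            probe_to_gene=probe_map)


class TestVarianceFilter:
    def test_keep_all_is_identity(self, tiny_cohort):
        out = variance_filter(tiny_cohort, 1.0)
        assert out.matrix.equals(tiny_cohort.matrix)

    def test_constant_row_never_survives(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(4, 6)),
                         index=list("abcd"), columns=[f"s{i}" for i in range(6)])
        m.loc["c"] = 3.0
        out = variance_filter(_cohort(m), 0.5)
        assert "c" not in out.matrix.index

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(rng.normal(size=(10, 5)) * rng.uniform(0.1, 3, (10, 1)),
                         index=[f"r{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(5)])
        out = variance_filter(_cohort(m), 0.5)
        expected = set(m.var(axis=1, ddof=1).nlargest(5).index)
        assert set(out.matrix.index) == expected
        # original order preserved
        assert list(out.matrix.index) == [r for r in m.index if r in expected]

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame([[1.0]], index=["g"], columns=["s0"])
        c = ExpressionCohort(matrix=m, time=pd.Series([1.0], index=["s0"]),
                             event=pd.Series([1], index=["s0"]))
        with pytest.raises(ValueError):
            variance_filter(c, 0.5)


class TestCollapseProbes:
    def test_highest_variance_probe_wins(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 5.0, 7.0]],
            index=["p1", "p2"], columns=[f"s{i}" for i in range(4)])
        out = collapse_probes(_cohort(m, probe_map={"p1": "X", "p2": "X"}))
        assert list(out.matrix.index) == ["X"]
        assert np.allclose(out.matrix.loc["X"], m.loc["p2"])

    def test_variance_tie_keeps_smallest_probe_id(self):
        m = pd.DataFrame(
            [[0.0, 1.0], [5.0, 6.0]],
            index=["pB", "pA"], columns=["s0", "s1"])
        out = collapse_probes(_cohort(m, probe_map={"pA": "X", "pB": "X"}))
        assert np.allclose(out.matrix.loc["X"], m.loc["pA"])

    def test_one_probe_per_gene_is_renaming(self):
        m = pd.DataFrame(np.arange(8.0).reshape(2, 4),
                         index=["p1", "p2"], columns=[f"s{i}" for i in range(4)])
        out = collapse_probes(_cohort(m, probe_map={"p1": "A", "p2": "B"}))
        assert list(out.matrix.index) == ["A", "B"]
        assert np.allclose(out.matrix.to_numpy(), m.to_numpy())

    def test_missing_map_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            collapse_probes(tiny_cohort)


class TestFastStatistic:
    def test_equals_cox_score_oracle_exhaustively(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            x = rng.normal(size=n)
            t = rng.exponential(size=n) + 0.1
            e = rng.integers(0, 2, size=n)
            if e.sum() == 0:
                e[int(rng.integers(n))] = 1
            z = (x - x.mean()) / x.std(ddof=1)
            expected = brute_force_cox_score(z, t, e)
            assert fast_statistic(x, t, e) == pytest.approx(expected, abs=1e-10)

    def test_reverse_ranked_expression_example(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        x = np.array([4.0, 3.0, 2.0, 1.0])
        z = (x - x.mean()) / x.std(ddof=1)
        assert fast_statistic(x, t, e) == pytest.approx(
            brute_force_cox_score(z, t, e), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        t = rng.exponential(size=10) + 0.1
        e = np.array([1, 0, 1, 1, 0, 1, 1, 1, 0, 1])
        assert fast_statistic(scale * x + shift, t, e) == pytest.approx(
            fast_statistic(x, t, e), rel=1e-9, abs=1e-12)

    def test_constant_expression_warns_zero(self):
        with pytest.warns(UserWarning):
            s = fast_statistic(np.ones(5), np.arange(1.0, 6.0), np.ones(5, int))
        assert s == 0.0

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            fast_statistic(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5, int))


class TestPermutationPvalue:
    def test_addone_floor_when_observed_extreme(self):
        n = 12
        t = np.arange(1, n + 1, dtype=float)
        e = np.ones(n, dtype=int)
        x = -t  # perfectly hazard-ordered covariate
        _, p = permutation_pvalue(x[None, :], t, e, n_perm=199, seed=0)
        assert p[0] == pytest.approx(1 / 200)

    def test_pvalues_live_on_addone_grid(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(30, 15))
        t = rng.exponential(size=15) + 0.1
        e = rng.integers(0, 2, size=15)
        e[0] = 1
        _, p = permutation_pvalue(m, t, e, n_perm=99, seed=1)
        assert np.all(p > 0)
        grid = np.arange(1, 101) / 100
        assert np.all(np.isin(np.round(p * 100), np.round(grid * 100)))

    def test_duplicate_rows_share_pvalues(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=20)
        m = np.vstack([row, row * 2 + 1, row])
        t = rng.exponential(size=20) + 0.1
        e = np.ones(20, dtype=int)
        _, p = permutation_pvalue(m, t, e, n_perm=200, seed=2)
        assert p[0] == p[1] == p[2]

    def test_null_pvalues_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(8)
        m = rng.normal(size=(500, 60))
        t = rng.exponential(size=60) + 0.1
        e = rng.integers(0, 2, size=60)
        e[0] = 1
        _, p = permutation_pvalue(m, t, e, n_perm=400, seed=3)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.ones((1, 4)), np.arange(1.0, 5.0),
                               np.ones(4, int), n_perm=0)


class TestLocalFdr:
    def test_uniform_pvalues_look_null(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=2000)
        lf = local_fdr(p)
        assert np.median(lf) >= 0.9

    def test_monotone_nondecreasing_in_p(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.beta(0.1, 1, size=100),
                            rng.uniform(size=900)])
        p = np.clip(p, 1e-12, 1.0)
        lf = local_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(lf[order]) >= -1e-12)

    def test_enriched_small_pvalues_get_low_lfdr(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(0, 1e-4, size=200),
                            rng.uniform(size=800)])
        lf = local_fdr(np.clip(p, 1e-12, 1))
        assert np.median(lf[:200]) < 0.15

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            local_fdr(np.full(49, 0.5))

    def test_out_of_range_rejected(self):
        bad = np.full(60, 0.5)
        bad[0] = 0.0
        with pytest.raises(ValueError):
            local_fdr(bad)


class TestPcaMetagenes:
    def test_rank_one_matrix_fully_explained(self):
        u = np.array([1.0, -2.0, 0.5])
        v = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame(np.outer(u, v), index=list("abc"),
                         columns=[f"s{i}" for i in range(4)])
        _, _, evr = pca_metagenes(m, 1)
        assert evr[0] == pytest.approx(1.0)

    def test_scores_equal_loadings_dot_centered_matrix(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(6, 5)),
                         index=[f"g{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(5)])
        loadings, scores, _ = pca_metagenes(m, 2)
        xc = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        assert np.allclose(scores.to_numpy(), (loadings.to_numpy().T @ xc).T)

    def test_component_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(6, 4)),
                         index=[f"g{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(4)])
        loadings, _, _ = pca_metagenes(m, 1)
        xc = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        u = np.linalg.svd(xc)[0][:, 0]
        got = loadings.iloc[:, 0].to_numpy()
        assert np.allclose(got, u) or np.allclose(got, -u)

    def test_components_beyond_rank_rejected(self):
        m = pd.DataFrame(np.outer([1.0, 2.0, 3.0], [1.0, 1.0, 2.0]),
                         index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValueError, match="rank"):
            pca_metagenes(m, 2)


class TestSplitSignature:
    def test_flip_swaps_sets_exactly(self):
        w = pd.Series([0.5, -0.3, 1.2, -0.1], index=list("abcd"))
        plus = split_signature(w, 1)
        minus = split_signature(w, -1)
        assert plus.hazardous_set == minus.protective_set
        assert plus.protective_set == minus.hazardous_set

    def test_all_positive_loadings_empty_protective(self):
        w = pd.Series([0.5, 0.3, 1.2], index=list("abc"))
        model = split_signature(w, 1)
        assert model.protective_set == frozenset()
        assert model.hazardous_set == frozenset("abc")

    def test_zero_loading_goes_protective_with_warning(self):
        w = pd.Series([0.5, 0.0], index=list("ab"))
        with pytest.warns(UserWarning):
            model = split_signature(w, 1)
        assert "b" in model.protective_set

    def test_unoriented_component_rejected(self):
        with pytest.raises(ValueError):
            split_signature(pd.Series([1.0], index=["a"]), 0)

    def test_planted_positive_loadings_recovered_as_hazardous(
            self, planted_cohort, fitted_signature):
        _, truth = planted_cohort
        model, _ = fitted_signature
        planted = truth["loadings"]
        pos = {g for g in model.transcript_ids
               if g in planted.index and planted[g] > 0}
        if pos:
            frac = len(pos & model.hazardous_set) / len(pos)
            assert frac >= 0.8


class TestLoocv:
    config = DiscoveryConfig(keep_fraction=0.5, n_perm=500, cv_n_perm=200,
                             seed=0)

    def test_out_of_fold_bookkeeping(self):
        cohort, _ = generate_survival_cohort(
            CohortSpec(n_samples=30, n_genes=200, n_signature_genes=40,
                       hazard_coefficient=1.5, seed=6))
        res = evaluate_components_loocv(cohort, self.config)
        assert res.scores["PC1"].notna().sum() == 30 - res.n_skipped

    def test_planted_factor_detected(self):
        cohort, _ = generate_survival_cohort(
            CohortSpec(n_samples=60, n_genes=300, n_signature_genes=60,
                       hazard_coefficient=1.5, seed=2))
        res = evaluate_components_loocv(cohort, self.config)
        assert res.p_value["PC1"] < 0.01

    def test_too_few_samples_rejected(self):
        cohort, _ = generate_survival_cohort(
            CohortSpec(n_samples=8, n_genes=60, n_signature_genes=10, seed=0))
        with pytest.raises(ValueError):
            evaluate_components_loocv(cohort, self.config)
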