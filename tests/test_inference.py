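"""Crossed random-effects LME, median split, multiplicity control, and the
median-ISC trait-rank post-hoc."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from narrsync import inference as inf
from narrsync.studies import simulate_pair_zmatrix

from _oracles import dense_reml_fit


def _zmat_from_pairs(n, pair_values):
    """Build a symmetric z-matrix from {(i, j): value} (defaults 0)."""
    m = np.zeros((n, n))
    for (i, j), v in pair_values.items():
        m[i, j] = m[j, i] = v
    return m


class TestMedianSplit:
    def test_hand_worked_example(self, small_traits):
        groups = inf.median_split(small_traits)
        assert groups["split_value"].iloc[0] == 18.5
        low = set(groups.loc[groups["group"] == "low", "subject_id"])
        assert low == {"sub-01", "sub-02", "sub-03", "sub-04"}

    def test_two_subject_split(self):
        t = pd.DataFrame({"subject_id": ["a", "b"], "trait_score": [16, 20]})
        groups = inf.median_split(t)
        assert (groups["group"] == ["low", "high"]).all()

    def test_balanced_eleven_eleven_split(self):
        # eleven scores at or below 18 and eleven at or above 19 split 11/11
        scores = [16] * 5 + [17, 17, 18, 18, 18, 18] + [19] * 6 + [20, 21, 22, 25, 40]
        t = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(22)], "trait_score": scores}
        )
        groups = inf.median_split(t)
        assert (groups["group"] == "low").sum() == 11
        assert (groups["group"] == "high").sum() == 11
        assert groups["split_value"].iloc[0] == 18.5

    def test_identical_scores_rejected(self):
        t = pd.DataFrame({"subject_id": list("abcd"), "trait_score": [20] * 4})
        with pytest.raises(ValueError, match="identical"):
            inf.median_split(t)


class TestOneGroupLME:
    def test_saturated_constant_data(self):
        zmat = _zmat_from_pairs(3, {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5})
        fit = inf.fit_one_group_lme(zmat)
        assert fit.fixed_effects["b0"] == pytest.approx(0.5, abs=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_dense_reml_oracle(self):
        rng = np.random.default_rng(42)
        zmat = simulate_pair_zmatrix(8, g11=0.3, tau2=0.02, sigma2=0.05, rng=rng)
        fit = inf.fit_one_group_lme(zmat)
        iu, ju = np.triu_indices(8, 1)
        beta, t2, s2 = dense_reml_fit(zmat[iu, ju], np.ones((len(iu), 1)), 8)
        assert fit.fixed_effects["b0"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.tau2 == pytest.approx(t2, abs=1e-6)
        assert fit.sigma2 == pytest.approx(s2, abs=1e-6)

    def test_estimator_is_unbiased_for_population_isc(self):
        rng = np.random.default_rng(3)
        est = [
            inf.fit_one_group_lme(
                simulate_pair_zmatrix(20, g11=0.3, rng=rng)
            ).fixed_effects["b0"]
            for _ in range(500)
        ]
        assert abs(np.mean(est) - 0.3) < 0.01

    def test_tau_zero_constraint_reduces_to_mean_and_t_test(self):
        rng = np.random.default_rng(8)
        zmat = simulate_pair_zmatrix(10, g11=0.2, rng=rng)
        fit = inf.fit_one_group_lme(zmat, constrain_tau_zero=True)
        iu, ju = np.triu_indices(10, 1)
        y = zmat[iu, ju]
        assert fit.fixed_effects["b0"] == pytest.approx(y.mean(), abs=1e-12)
        t_ref = stats.ttest_1samp(y, 0.0).statistic
        assert fit.contrasts["t"].iloc[0] == pytest.approx(t_ref, abs=1e-10)

    def test_nonfinite_pairs_rejected(self):
        zmat = _zmat_from_pairs(4, {(0, 1): np.nan})
        with pytest.raises(ValueError):
            inf.fit_one_group_lme(zmat)


class TestTwoGroupLME:
    def test_saturated_cell_means(self):
        labels = np.array(["low", "low", "high", "high"])
        zmat = _zmat_from_pairs(
            4,
            {
                (0, 1): 0.6,  # within-low
                (2, 3): 0.2,  # within-high
                (0, 2): 0.3, (0, 3): 0.3, (1, 2): 0.3, (1, 3): 0.3,
            },
        )
        fit = inf.fit_two_group_lme(zmat, labels)
        assert fit.fixed_effects["G11"] == pytest.approx(0.6, abs=1e-9)
        assert fit.fixed_effects["G22"] == pytest.approx(0.2, abs=1e-9)
        assert fit.fixed_effects["G12"] == pytest.approx(0.3, abs=1e-9)
        row = fit.contrasts.set_index("contrast").loc["G11-G22"]
        assert row["estimate"] == pytest.approx(0.4, abs=1e-9)

    def test_contrasts_equal_fixed_effect_differences(self):
        rng = np.random.default_rng(5)
        labels = np.array(["low"] * 5 + ["high"] * 5)
        zmat = simulate_pair_zmatrix(10, labels, 0.4, 0.2, 0.3, rng=rng)
        fit = inf.fit_two_group_lme(zmat, labels)
        fe = fit.fixed_effects
        c = fit.contrasts.set_index("contrast")
        assert c.loc["G11-G22", "estimate"] == pytest.approx(
            fe["G11"] - fe["G22"], abs=1e-10
        )
        assert c.loc["G22-G12", "estimate"] == pytest.approx(
            fe["G22"] - fe["G12"], abs=1e-10
        )

    def test_exchangeability_under_subject_relabeling(self):
        rng = np.random.default_rng(6)
        labels = np.array(["low"] * 4 + ["high"] * 4)
        zmat = simulate_pair_zmatrix(8, labels, 0.5, 0.3, 0.4, rng=rng)
        fit = inf.fit_two_group_lme(zmat, labels)
        perm = np.random.default_rng(7).permutation(8)
        fit_p = inf.fit_two_group_lme(zmat[np.ix_(perm, perm)], labels[perm])
        for name in ("G11", "G22", "G12"):
            assert fit_p.fixed_effects[name] == pytest.approx(
                fit.fixed_effects[name], abs=1e-7
            )

    def test_singleton_group_rejected(self):
        labels = np.array(["low", "high", "high", "high"])
        zmat = simulate_pair_zmatrix(4, rng=np.random.default_rng(1))
        with pytest.raises(ValueError, match="G11"):
            inf.fit_two_group_lme(zmat, labels)

    def test_map_fitter_agrees_with_scalar_fitter(self):
        rng = np.random.default_rng(12)
        labels = np.array(["low"] * 6 + ["high"] * 6)
        zstack = np.stack(
            [simulate_pair_zmatrix(12, labels, 0.4, 0.2, 0.3, rng=rng)
             for _ in range(5)]
        )
        grid = np.concatenate([[0.0], np.logspace(-6, 3, 200)])
        mapped = inf.fit_lme_map(zstack, labels, lam_grid=grid)
        for v in range(5):
            fit = inf.fit_two_group_lme(zstack[v], labels)
            for k, name in enumerate(("G11", "G22", "G12")):
                assert mapped["fixed_effects"][k, v] == pytest.approx(
                    fit.fixed_effects[name], abs=5e-3
                )
            p_map = mapped["pvalues"]["G11-G22"][v]
            p_ref = fit.contrasts.set_index("contrast").loc["G11-G22", "p"]
            assert p_map == pytest.approx(p_ref, abs=0.02)


class TestFDR:
    def test_hand_enumerated_step_up(self):
        res = inf.voxelwise_fdr(np.array([0.001, 0.01, 0.02, 0.04, 0.2]), q=0.05)
        assert res.n_rejected == 4

    def test_all_ones_reject_nothing(self):
        res = inf.voxelwise_fdr(np.ones(10), q=0.05)
        assert res.n_rejected == 0

    def test_single_pvalue_reduces_to_raw_threshold(self):
        assert inf.voxelwise_fdr(np.array([0.04]), q=0.05).n_rejected == 1

    def test_qvalues_monotone_in_pvalues(self, rng):
        p = rng.uniform(size=50)
        res = inf.voxelwise_fdr(p, q=0.1)
        order = np.argsort(p)
        assert np.all(np.diff(res.qvalues[order]) >= -1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            inf.voxelwise_fdr(np.array([]))


class TestClusterCorrection:
    def _blob_pmap(self, n_blob):
        pmap = np.ones((5, 5, 5))
        flat = pmap.reshape(-1)
        flat[:n_blob] = 0.0001  # C-order raveling keeps these face-connected
        return pmap

    def test_sixty_voxel_blob_survives_extent_fifty(self):
        res = inf.cluster_correct(self._blob_pmap(60), p_init=0.002, extent=50)
        assert res.n_surviving == 1

    def test_same_blob_fails_extent_sixty_one(self):
        res = inf.cluster_correct(self._blob_pmap(60), p_init=0.002, extent=61)
        assert res.n_surviving == 0

    def test_extent_or_null_required(self):
        with pytest.raises(ValueError):
            inf.cluster_correct(self._blob_pmap(10), p_init=0.002)

    def test_calibrated_extent_is_null_quantile(self):
        null = np.array([0, 1, 1, 2, 2, 2, 3, 3, 4, 10])
        # P(max >= 4) = 2/10 > 0.05; P(max >= 5) = 1/10 > 0.05; P(max >= 11) = 0
        assert inf.calibrate_extent(null, alpha=0.05) == 11
        assert inf.calibrate_extent(null, alpha=0.2) == 4


class TestRankPosthoc:
    def _tie_free_traits(self):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "trait_score": [16, 17, 18, 19, 20, 21, 38, 40],
            }
        )

    def test_monotone_medians_give_rho_one(self):
        med = np.linspace(0.1, 0.8, 8)
        rho, p = inf.isc_rank_posthoc(med, self._tie_free_traits())
        assert rho == pytest.approx(1.0)

    def test_reversed_medians_give_rho_minus_one(self):
        med = np.linspace(0.8, 0.1, 8)
        rho, _ = inf.isc_rank_posthoc(med, self._tie_free_traits())
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        med = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        ranks = np.array([1.0, 2, 3, 4, 5])
        rho, _ = inf.spearman_test(med, ranks)
        oracle = np.corrcoef(stats.rankdata(med), stats.rankdata(ranks))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_matches_enumeration(self):
        x = np.array([1.0, 3.0, 2.0, 4.0, 6.0, 5.0])
        y = np.arange(6.0)
        rho, p = inf.spearman_test(x, y)
        from itertools import permutations

        xr, yr = stats.rankdata(x), stats.rankdata(y)
        rhos = [
            np.corrcoef(np.asarray(perm, float), yr)[0, 1]
            for perm in permutations(xr)
        ]
        p_ref = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_constant_medians_reported_undefined(self, small_traits):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = inf.isc_rank_posthoc(np.full(8, 0.4), small_traits)
        assert np.isnan(rho) and np.isnan(p)
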