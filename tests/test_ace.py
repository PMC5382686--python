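"""Bivariate Cholesky twin model: covariance construction against a
hand-assembled oracle, FIML against per-pair density evaluation, component
standardisation, worked decomposition examples and parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import twinprs as tp
from twinprs import ace

from conftest import REPORTED


def make_params(vec):
    return ace.CholeskyParams.from_vector(np.asarray(vec, dtype=float))


def random_params(rng, e_floor=0.3):
    v = rng.normal(0, 0.6, size=11)
    v[[0, 2, 3, 5]] = np.abs(v[[0, 2, 3, 5]])
    v[[6, 8]] = np.abs(v[[6, 8]]) + e_floor
    return make_params(v)


def brute_force_sigma(params, zygosity, model="ACE"):
    """Independent block assembly: [[A+C+E, kA*A + kC*C], [.., A+C+E]]."""
    a, c, e = params.sigma_a, params.sigma_c, params.sigma_e
    ka, kc = {"MZ": (1.0, 1.0), "DZ": (0.5, 1.0)}[zygosity]
    if model == "ADE" and zygosity == "DZ":
        kc = 0.25
    top = np.hstack([a + c + e, ka * a + kc * c])
    bot = np.hstack([(ka * a + kc * c).T, a + c + e])
    return np.vstack([top, bot])


def brute_force_neg2ll(params, data, model="ACE"):
    """Per-pair multivariate-normal density evaluation (no grouping)."""
    total = 0.0
    mu4 = params.mu[[0, 1, 0, 1]]
    for _, row in data.iterrows():
        y = row[["trait1_t1", "trait2_t1", "trait1_t2", "trait2_t2"]].to_numpy(float)
        obs = np.isfinite(y)
        if not obs.any():
            continue
        sigma = ace.model_implied_covariance(params, row.zygosity, model)
        total += -2.0 * stats.multivariate_normal.logpdf(
            y[obs], mean=mu4[obs], cov=sigma[np.ix_(obs, obs)])
    return total


class TestModelImpliedCovariance:
    @pytest.mark.parametrize("zygosity", ["MZ", "DZ"])
    @pytest.mark.parametrize("model", ["ACE", "ADE"])
    def test_matches_hand_assembled_blocks(self, rng, zygosity, model):
        for _ in range(10):
            params = random_params(rng)
            got = ace.model_implied_covariance(params, zygosity, model)
            assert np.allclose(got, brute_force_sigma(params, zygosity, model),
                               atol=1e-12)

    def test_e_only_model_is_identity_with_zero_cross(self):
        params = make_params([0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0])
        for zyg in ("MZ", "DZ"):
            assert np.allclose(ace.model_implied_covariance(params, zyg),
                               np.eye(4))

    def test_pure_genetic_mz_cross_equals_within(self, rng):
        params = make_params([0.9, 0.2, 0.7, 0, 0, 0, 1e-8, 0, 1e-8, 0, 0])
        sigma = ace.model_implied_covariance(params, "MZ")
        assert np.allclose(sigma[:2, :2], sigma[:2, 2:], atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(v=st.lists(st.floats(-2, 2), min_size=11, max_size=11),
           zyg=st.sampled_from(["MZ", "DZ"]),
           model=st.sampled_from(["ACE", "ADE"]))
    def test_always_symmetric_psd(self, v, zyg, model):
        v = np.asarray(v)
        v[[0, 2, 3, 5, 6, 8]] = np.abs(v[[0, 2, 3, 5, 6, 8]])
        sigma = ace.model_implied_covariance(make_params(v), zyg, model)
        assert np.allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() > -1e-10


class TestNeg2Loglik:
    def test_single_standard_normal_pair_at_mean(self):
        params = make_params([0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0])
        data = pd.DataFrame({"pair_id": ["p1"], "zygosity": ["MZ"],
                             "trait1_t1": [0.0], "trait2_t1": [0.0],
                             "trait1_t2": [0.0], "trait2_t2": [0.0]})
        assert tp.neg2_loglik(params, data) == pytest.approx(
            4 * math.log(2 * math.pi), abs=1e-12)

    def test_matches_per_pair_density_oracle_with_missingness(self, reported_truth, rng):
        data = tp.simulate_twin_dataset(reported_truth, 5, 5, seed=17)
        # knock out a co-twin and a single trait value
        data.loc[1, ["trait1_t2", "trait2_t2"]] = np.nan
        data.loc[7, "trait2_t1"] = np.nan
        for model in ("ACE", "ADE"):
            for _ in range(5):
                params = random_params(rng)
                assert tp.neg2_loglik(params, data, model) == pytest.approx(
                    brute_force_neg2ll(params, data, model), abs=1e-8)

    def test_additive_over_datasets(self, reported_truth, rng):
        d1 = tp.simulate_twin_dataset(reported_truth, 4, 4, seed=1)
        d2 = tp.simulate_twin_dataset(reported_truth, 3, 3, seed=2)
        d2["pair_id"] = d2["pair_id"] + "_b"
        both = pd.concat([d1, d2], ignore_index=True)
        params = random_params(rng)
        assert tp.neg2_loglik(params, both) == pytest.approx(
            tp.neg2_loglik(params, d1) + tp.neg2_loglik(params, d2), rel=1e-12)


class TestStandardize:
    def test_matches_covariance_arithmetic(self, rng):
        for _ in range(10):
            params = random_params(rng)
            comps = tp.standardize_components(params)
            a, c, e = params.sigma_a, params.sigma_c, params.sigma_e
            tot0 = a[0, 0] + c[0, 0] + e[0, 0]
            assert comps.A1 == pytest.approx(a[0, 0] / tot0, abs=1e-12)
            assert comps.r_a == pytest.approx(
                a[0, 1] / math.sqrt(a[0, 0] * a[1, 1]), abs=1e-12)
            assert comps.A1 + comps.C1 + comps.E1 == pytest.approx(1, abs=1e-9)

    def test_diagonal_genetics_and_no_c_gives_zero_ra_missing_rc(self):
        params = make_params([0.8, 0, 0.6, 0, 0, 0, 0.5, 0, 0.5, 0, 0])
        comps = tp.standardize_components(params)
        assert comps.r_a == 0.0
        assert np.isnan(comps.r_c)

    def test_pure_genetic_identity_scaling(self):
        r = 0.37
        la = np.linalg.cholesky(np.array([[1, r], [r, 1]]))
        params = ace.CholeskyParams(la=la, lc=np.zeros((2, 2)),
                                    le=np.eye(2) * 1e-9, mu=np.zeros(2))
        comps = tp.standardize_components(params)
        assert comps.A1 == pytest.approx(1.0, abs=1e-9)
        assert comps.r_a == pytest.approx(r, abs=1e-9)


class TestDecompositionExamples:
    def test_shared_genetic_effect_from_published_components(self):
        shared = tp.shared_genetic_effect(0.85, REPORTED["r_a"], 0.47)
        assert shared == pytest.approx(-0.0904, abs=1e-4)
        # published estimate of the magnitude is 0.091 (unrounded inputs)
        assert abs(shared) == pytest.approx(0.091, abs=1e-3)

    def test_shared_effect_degenerate_forms(self):
        assert tp.shared_genetic_effect(0.5, 0.0, 0.9) == 0.0
        assert tp.shared_genetic_effect(1.0, -0.3, 1.0) == pytest.approx(-0.3)

    def test_proportion_of_rp_genetic(self):
        prop = tp.proportion_of_rp_genetic(0.091, 0.116)
        assert prop == pytest.approx(0.78, abs=0.01)
        assert tp.proportion_of_rp_genetic(0.0, -0.1) == 0.0
        assert tp.proportion_of_rp_genetic(-0.05, -0.05) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            tp.proportion_of_rp_genetic(0.1, 0.0)


class TestFit:
    def test_recovers_calibrated_truth(self, reported_truth, recovery_fit):
        c = recovery_fit.components
        assert recovery_fit.converged
        assert c.A1 == pytest.approx(reported_truth.A1, abs=0.03)
        assert c.A2 == pytest.approx(reported_truth.A2, abs=0.03)
        assert c.C2 == pytest.approx(reported_truth.C2, abs=0.03)
        assert c.E1 == pytest.approx(reported_truth.E1, abs=0.03)
        assert c.r_a == pytest.approx(reported_truth.r_a, abs=0.05)

    def test_fit_never_beaten_by_generating_parameters(self, reported_truth,
                                                       large_twin_data,
                                                       recovery_fit):
        x_true = np.concatenate([
            ace._tril(reported_truth.sigma_a), ace._tril(reported_truth.sigma_c),
            ace._tril(reported_truth.sigma_e), [0.0, 0.0]])
        truth_ll = tp.neg2_loglik(ace.CholeskyParams.from_vector(x_true),
                                  large_twin_data)
        assert recovery_fit.minus2ll <= truth_ll + 1e-6

    def test_decomposition_identity_holds_at_optimum(self, recovery_fit):
        c = recovery_fit.components
        within = (recovery_fit.params.sigma_a + recovery_fit.params.sigma_c
                  + recovery_fit.params.sigma_e)
        rp_model = within[0, 1] / math.sqrt(within[0, 0] * within[1, 1])
        assert c.implied_rp == pytest.approx(rp_model, abs=1e-10)

    def test_no_mz_dz_contrast_gives_zero_heritability(self):
        truth = tp.GeneratorTruth(0, 0.55, 0.45, 0, 0.55, 0.45,
                                  r_a=0, r_c=0.3, r_e=0.1)
        data = tp.simulate_twin_dataset(truth, 2000, 2000, seed=4)
        fit = tp.fit_bivariate_ace(data)
        assert fit.components.A1 < 0.08
        assert fit.components.A2 < 0.08

    def test_ml_estimate_matches_falconer_formula(self, reported_truth,
                                                  large_twin_data, recovery_fit):
        d = large_twin_data
        r = {z: np.corrcoef(d[d.zygosity == z].trait1_t1,
                            d[d.zygosity == z].trait1_t2)[0, 1]
             for z in ("MZ", "DZ")}
        falconer_a1 = 2 * (r["MZ"] - r["DZ"])
        assert recovery_fit.components.A1 == pytest.approx(falconer_a1, abs=0.04)

    def test_single_zygosity_rejected(self, reported_truth):
        data = tp.simulate_twin_dataset(reported_truth, 50, 0, seed=3)
        data = data[data.zygosity == "MZ"]
        with pytest.raises(ValueError, match="MZ and DZ"):
            tp.fit_bivariate_ace(data)

    def test_ade_fit_runs_and_standardizes(self, reported_truth):
        data = tp.simulate_twin_dataset(reported_truth, 800, 800, seed=12)
        fit = tp.fit_bivariate_ace(data, model="ADE")
        assert fit.model == "ADE"
        assert fit.components.A1 + fit.components.C1 + fit.components.E1 == \
            pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def medium(reported_truth):
    data = tp.simulate_twin_dataset(reported_truth, 1000, 1000, seed=77)
    return data, tp.fit_bivariate_ace(data)


class TestConfidenceIntervals:
    def test_profile_and_bootstrap_agree_for_a1(self, medium):
        data, fit = medium
        prof = tp.confidence_intervals(fit, data, "profile", quantities=["A1"])
        boot = tp.confidence_intervals(fit, data, "bootstrap",
                                       quantities=["A1"],
                                       options={"n_boot": 200, "seed": 1})
        for col in ("lower", "upper"):
            assert round(prof[col][0], 1) == round(boot[col][0], 1)
        for ci in (prof, boot):
            assert ci.lower[0] <= ci.estimate[0] <= ci.upper[0]

    def test_interval_width_shrinks_with_sample_size(self, reported_truth, medium):
        small_d = tp.simulate_twin_dataset(reported_truth, 120, 120, seed=78)
        small_fit = tp.fit_bivariate_ace(small_d)
        small = tp.confidence_intervals(small_fit, small_d, "profile",
                                        quantities=["A1"])
        _, fit = medium
        large = tp.confidence_intervals(fit, medium[0], "profile",
                                        quantities=["A1"])
        assert (large.upper[0] - large.lower[0]) < \
            (small.upper[0] - small.lower[0])


class TestPhenotypicCorrelation:
    def test_exact_and_null_cases(self, rng):
        n = 500
        t1 = rng.standard_normal(n)
        data = pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(n)], "zygosity": "MZ",
            "trait1_t1": t1, "trait2_t1": t1,
            "trait1_t2": t1, "trait2_t2": t1})
        assert tp.phenotypic_correlation(data) == pytest.approx(1.0)
        data["trait2_t1"] = rng.standard_normal(n)
        data["trait2_t2"] = rng.standard_normal(n)
        assert abs(tp.phenotypic_correlation(data)) < 0.1

    def test_one_twin_per_pair_variant_is_seeded(self, reported_truth):
        data = tp.simulate_twin_dataset(reported_truth, 400, 400, seed=21)
        a = tp.phenotypic_correlation(data, method="one_per_pair", seed=5)
        b = tp.phenotypic_correlation(data, method="one_per_pair", seed=5)
        assert a == b
        assert a == pytest.approx(tp.phenotypic_correlation(data), abs=0.1)

    def test_zero_variance_rejected(self):
        data = pd.DataFrame({
            "pair_id": ["a", "b", "c"], "zygosity": "MZ",
            "trait1_t1": 1.0, "trait2_t1": [1.0, 2.0, 3.0],
            "trait1_t2": 1.0, "trait2_t2": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            tp.phenotypic_correlation(data)
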