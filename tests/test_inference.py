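import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from chronophylo.inference import (
    PLSPathModel,
    fit_mixed,
    fit_plspm,
    r2_nakagawa,
    variance_partition,
)
from chronophylo.synthetic import simulate_path_data


def _stage_data(seed, beta_pd=1.0, sigma_stage=0.5, sigma_eps=0.5, n_stages=8,
                per_stage=6):
    rng = np.random.default_rng(seed)
    n = n_stages * per_stage
    stage = np.repeat(np.arange(n_stages), per_stage)
    X = rng.normal(size=(n, 5))
    y = (beta_pd * X[:, 0]
         + np.repeat(rng.normal(0, sigma_stage, n_stages), per_stage)
         + rng.normal(0, sigma_eps, n))
    cols = ["PD", "PSR", "PSE", "NRI", "NTI"]
    d = pd.DataFrame(X, columns=cols)
    d["agb"] = y
    d["stage_years"] = stage
    return d


class TestMixedModel:
    def test_zero_stage_variance_gives_near_equal_r2(self):
        gaps = []
        for seed in range(20):
            d = _stage_data(seed, sigma_stage=0.0)
            r = fit_mixed(d, "agb", ["PD", "PSR", "PSE", "NRI", "NTI"])
            gaps.append(r.r2_conditional - r.r2_marginal)
        assert np.median(gaps) < 0.05

    def test_true_predictor_detected_others_not(self):
        detected, false_hits = 0, []
        for seed in range(60):
            d = _stage_data(seed, beta_pd=1.0)
            r = fit_mixed(d, "agb", ["PD", "PSR", "PSE", "NRI", "NTI"])
            detected += r.significant["PD"]
            false_hits.append(np.mean([r.significant[k] for k in
                                       ("PSR", "PSE", "NRI", "NTI")]))
        assert detected >= 54  # >= 90% power
        assert np.mean(false_hits) <= 0.15

    def test_pure_noise_rarely_significant(self):
        quiet = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            d = _stage_data(seed, beta_pd=0.0, sigma_stage=0.0)
            r = fit_mixed(d, "agb", ["PD", "PSR", "PSE", "NRI", "NTI"])
            quiet += not any(r.significant.values())
        assert quiet >= 28  # most runs have no |t| > 2 anywhere

    def test_coefficient_recovery_unbiased(self):
        est = []
        for seed in range(120):
            d = _stage_data(seed, beta_pd=1.0)
            r = fit_mixed(d, "agb", ["PD"], standardize=False)
            est.append(r.coefficients["PD"])
        assert abs(np.mean(est) - 1.0) < 0.05

    def test_aic_prefers_true_model(self):
        wins = 0
        for seed in range(40):
            d = _stage_data(seed, beta_pd=1.0)
            small = fit_mixed(d, "agb", ["PD"])
            big = fit_mixed(d, "agb", ["PD", "NTI"])
            wins += small.aic < big.aic
        assert wins >= 28  # parsimony in >= 70% of runs

    def test_boundary_fit_flagged_not_error(self):
        d = _stage_data(3, sigma_stage=0.0)
        r = fit_mixed(d, "agb", ["PD"])
        assert isinstance(r.boundary_fit, bool)

    def test_too_few_rows_rejected(self):
        d = _stage_data(0).head(6)
        with pytest.raises(ValueError):
            fit_mixed(d, "agb", ["PD"])


class TestNakagawaR2:
    def test_identity_when_no_group_variance(self):
        x = np.random.default_rng(0).normal(size=100)
        r2m, r2c = r2_nakagawa(x, 0.0, np.var(x))
        assert r2m == pytest.approx(r2c)

    def test_closed_form_half_split(self):
        r2m, r2c = r2_nakagawa(np.zeros(10), 1.0, 1.0)
        assert r2m == 0.0 and r2c == pytest.approx(0.5)

    def test_recovers_known_variance_shares(self):
        vals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n_stages, per = 8, 6
            fixed = rng.normal(0, np.sqrt(0.4), n_stages * per)
            y = (fixed + np.repeat(rng.normal(0, np.sqrt(0.4), n_stages), per)
                 + rng.normal(0, np.sqrt(0.2), n_stages * per))
            d = pd.DataFrame({"agb": y, "x": fixed,
                              "stage_years": np.repeat(np.arange(n_stages), per)})
            r = fit_mixed(d, "agb", ["x"], standardize=False)
            vals.append((r.r2_marginal, r.r2_conditional))
        r2m, r2c = np.mean(vals, axis=0)
        assert r2m == pytest.approx(0.4, abs=0.1)
        assert r2c == pytest.approx(0.8, abs=0.1)

    def test_all_zero_variances_flagged(self):
        r2m, r2c = r2_nakagawa(np.zeros(5), 0.0, 0.0)
        assert np.isnan(r2m) and np.isnan(r2c)


class TestVariancePartition:
    def test_partition_identity_exact(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = pd.DataFrame(rng.normal(size=(60, 4)), columns=["y", "a", "b", "c"])
            v = variance_partition(d, "y", ["a", "b"], ["c"])
            assert v.unique1 + v.unique2 + v.shared == pytest.approx(
                v.adj_r2_full, abs=1e-8)

    def test_orthogonal_irrelevant_set_has_no_share(self):
        rng = np.random.default_rng(1)
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)  # orthogonal to x1 and to y
        y = x1 + 0.3 * rng.normal(size=n)
        d = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        v = variance_partition(d, "y", ["x1"], ["x2"])
        assert abs(v.unique2) < 0.05
        assert abs(v.shared) < 0.05
        assert v.unique1 > 0.7

    def test_noise_response_all_fractions_small(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(rng.normal(size=(200, 3)), columns=["y", "a", "b"])
        v = variance_partition(d, "y", ["a"], ["b"])
        for val in (v.unique1, v.unique2, v.shared):
            assert abs(val) < 0.05

    def test_correlated_predictors_share_variance(self):
        rng = np.random.default_rng(3)
        n = 500
        x1 = rng.normal(size=n)
        x2 = 0.7 * x1 + np.sqrt(1 - 0.49) * rng.normal(size=n)
        y = x1 + x2 + rng.normal(size=n)
        d = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        v = variance_partition(d, "y", ["x1"], ["x2"])
        assert v.shared > 0.1
        assert v.unique1 + v.unique2 + v.shared == pytest.approx(v.adj_r2_full, abs=1e-8)

    def test_duplicated_column_named_in_error(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        d = pd.DataFrame({"y": rng.normal(size=50), "a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            variance_partition(d, "y", ["a"], ["b"])


class TestPLSPathModel:
    BLOCKS = {"TVR": ["tvr"], "WPD": ["PD", "PSE"], "WPS": ["NRI"], "AGB": ["agb"]}
    PATHS = [("TVR", "WPD"), ("TVR", "WPS"), ("WPD", "AGB"), ("WPS", "AGB")]

    def test_single_indicator_blocks_reduce_to_path_analysis(self):
        """With one indicator per block, PLS-PM is standardized recursive OLS."""
        rng = np.random.default_rng(0)
        n = 48
        d = pd.DataFrame({
            "tvr": rng.normal(size=n),
        })
        d["x"] = 0.8 * d.tvr + 0.6 * rng.normal(size=n)
        d["y"] = 0.5 * d.x - 0.4 * d.tvr + 0.5 * rng.normal(size=n)
        blocks = {"TVR": ["tvr"], "X": ["x"], "Y": ["y"]}
        paths = [("TVR", "X"), ("TVR", "Y"), ("X", "Y")]
        m = PLSPathModel(blocks, paths).fit(d)
        z = (d - d.mean()) / d.std(ddof=1)
        ols_x = sm.OLS(z.x, z[["tvr"]]).fit().params
        ols_y = sm.OLS(z.y, z[["tvr", "x"]]).fit().params
        assert m.path_coefficients_.loc["X", "TVR"] == pytest.approx(ols_x["tvr"], abs=1e-6)
        assert m.path_coefficients_.loc["Y", "TVR"] == pytest.approx(ols_y["tvr"], abs=1e-6)
        assert m.path_coefficients_.loc["Y", "X"] == pytest.approx(ols_y["x"], abs=1e-6)
        assert all(c == pytest.approx(1.0) for c in m.communalities_.values())

    def test_gof_formula_closed_case(self):
        """Communalities 1 and a single endogenous R2 of 0.49 give GOF 0.7."""
        rng = np.random.default_rng(1)
        n = 4000
        x = rng.normal(size=n)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=n)
        d = pd.DataFrame({"x": x, "y": y})
        m = PLSPathModel({"X": ["x"], "Y": ["y"]}, [("X", "Y")]).fit(d)
        mean_comm = np.mean(list(m.communalities_.values()))
        assert m.gof_ == pytest.approx(np.sqrt(mean_comm * m.r2_["Y"]))
        assert m.gof_ == pytest.approx(0.7, abs=0.02)

    def test_recovers_generating_paths(self):
        truth = {("TVR", "WPD"): 0.7, ("TVR", "WPS"): -0.5,
                 ("WPD", "AGB"): 0.6, ("WPS", "AGB"): -0.35}
        hits = {k: 0 for k in truth}
        n_seeds = 50
        for seed in range(n_seeds):
            d = simulate_path_data(truth, n=48, seed=seed)
            m = PLSPathModel(self.BLOCKS, self.PATHS).fit(d)
            for (s, t), b in truth.items():
                hits[(s, t)] += abs(m.path_coefficients_.loc[t, s] - b) < 0.15
        # each structural path is recovered within +-0.15 in >= 80% of seeds
        for key, n_ok in hits.items():
            assert n_ok >= 0.78 * n_seeds, key

    def test_standardized_paths_bounded(self):
        d = simulate_path_data(n=48, seed=3)
        m = PLSPathModel(self.BLOCKS, self.PATHS).fit(d)
        coefs = m.path_coefficients_.to_numpy()
        assert np.nanmax(np.abs(coefs)) <= 1.0 + 1e-6

    def test_bootstrap_deterministic_given_seed(self):
        d = simulate_path_data(n=48, seed=4)
        r1 = fit_plspm(d, self.BLOCKS, self.PATHS, n_boot=50, seed=9)
        r2 = fit_plspm(d, self.BLOCKS, self.PATHS, n_boot=50, seed=9)
        pd.testing.assert_frame_equal(r1.boot_se, r2.boot_se)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PLSPathModel({"A": ["a"], "B": ["b"]}, [("A", "B"), ("B", "A")])

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PLSPathModel({"A": ["a"]}, [("A", "Z")])
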