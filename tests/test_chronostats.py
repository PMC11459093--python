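import numpy as np
import pytest
from scipy import stats

from chronophylo.chronostats import (
    anova_oneway,
    check_homogeneity,
    check_normality,
    duncan_letters,
    fit_trend,
    normalize_transform,
)


class TestDistributionChecks:
    def test_constant_vector_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            w, p = check_normality([3.0] * 10)
        assert np.isnan(w) and np.isnan(p)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            check_normality([1.0, 2.0])

    def test_normal_samples_mostly_pass(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=48)
            hits += check_normality(x)[1] > 0.05
        assert hits >= 90

    def test_lognormal_samples_mostly_fail(self):
        hits = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).normal(0, 1.2, size=48))
            hits += check_normality(x)[1] < 0.05
        assert hits >= 90

    def test_levene_detects_variance_ratio_100(self):
        # power of the mean-centered Levene test at n=6 per group is ~0.84
        # (measured over 400 simulations), so require a large majority
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            g1, g2 = rng.normal(0, 1, 6), rng.normal(0, 10, 6)
            hits += check_homogeneity([g1, g2])[1] < 0.05
        assert hits >= 40

    def test_levene_type_one_error_near_alpha(self):
        hits = 0
        n = 400
        for seed in range(n):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 8) for _ in range(4)]
            hits += check_homogeneity(groups)[1] < 0.05
        assert 0.01 < hits / n < 0.10

    def test_identical_groups_statistic_zero(self):
        g = [1.0, 2.0, 3.0]
        stat, _ = check_homogeneity([g, list(g)])
        assert stat == pytest.approx(0.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            check_homogeneity([[1, 2, 3]])


class TestNormalizeTransform:
    def test_normal_input_untouched(self):
        x = np.random.default_rng(1).normal(size=60)
        _, method, info = normalize_transform(x)
        assert method == "none" and info["passed"]

    def test_lognormal_input_log_transformed(self):
        x = np.exp(np.random.default_rng(2).normal(0, 1.5, size=60))
        out, method, info = normalize_transform(x)
        assert method == "log"
        assert check_normality(out)[1] > 0.05

    def test_nonpositive_values_shifted_before_log(self, caplog):
        x = np.exp(np.random.default_rng(3).normal(0, 1.5, size=60)) - 1.0
        with caplog.at_level("INFO"):
            _, method, info = normalize_transform(x)
        assert info.get("shift", 0) > 0

    def test_untransformable_flagged_best_effort(self):
        # strongly bimodal data no monotone transform can normalize
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.01, 40), rng.normal(100, 0.01, 40)])
        _, method, info = normalize_transform(x)
        assert info["passed"] is False


class TestTrendFit:
    def test_noise_free_quadratic_vertex(self):
        x = np.tile([0, 10, 20, 40, 70, 120, 135, 150], 6).astype(float)
        y = 10 + 2 * x - 0.01 * x**2
        tf = fit_trend(x, y)
        assert tf.r2 == pytest.approx(1.0)
        assert tf.peak_tvr == pytest.approx(100.0, abs=1e-6)

    def test_monotone_has_no_interior_peak(self):
        x = np.arange(20, dtype=float)
        tf = fit_trend(x, x.copy())
        assert tf.peak_tvr is None

    def test_convex_quadratic_has_no_peak(self):
        x = np.linspace(0, 10, 30)
        tf = fit_trend(x, (x - 5) ** 2)
        assert tf.peak_tvr is None

    def test_noisy_peak_recovery(self):
        stages = np.tile([0, 10, 20, 40, 70, 120, 135, 150], 6).astype(float)
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = 50 + 1.8 * stages - 0.01 * stages**2 + rng.normal(0, 8, stages.size)
            tf = fit_trend(stages, y)
            assert tf.peak_tvr is not None
            errors.append(abs(tf.peak_tvr - 90.0))
        assert np.median(errors) < 10.0

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_trend([1.0] * 10, np.arange(10.0))

    def test_confidence_band_contains_fit(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 100, 40)
        y = x + rng.normal(0, 5, 40)
        tf = fit_trend(x, y, degree=1)
        assert np.all(tf.ci_lower <= tf.fitted) and np.all(tf.fitted <= tf.ci_upper)


class TestAnova:
    def test_hand_decomposition(self):
        f, p, mse, df = anova_oneway({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert f == pytest.approx(13.5)
        assert df == (1, 4)
        assert mse == pytest.approx(1.0)

    def test_matches_scipy_and_t_squared(self):
        rng = np.random.default_rng(5)
        g1, g2 = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        f, p, _, _ = anova_oneway({"a": g1, "b": g2})
        f_ref, p_ref = stats.f_oneway(g1, g2)
        assert f == pytest.approx(f_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)
        t, _ = stats.ttest_ind(g1, g2)
        assert f == pytest.approx(t * t, rel=1e-10)

    def test_sum_of_squares_oracle(self):
        rng = np.random.default_rng(6)
        groups = {i: rng.normal(i * 0.3, 1.0, 6) for i in range(8)}
        f, _, mse, (dfb, dfw) = anova_oneway(groups)
        allv = np.concatenate(list(groups.values()))
        sst = ((allv - allv.mean()) ** 2).sum()
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_ref = ((sst - ssw) / dfb) / (ssw / dfw)
        assert f == pytest.approx(f_ref, rel=1e-10)

    def test_identical_means_small_f(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 10)
        f, p, _, _ = anova_oneway({"a": base, "b": base + 0.0})
        assert f == pytest.approx(0.0, abs=1e-20)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1, 2], "b": []})


class TestDuncanLetters:
    def test_well_separated_groups(self):
        rng = np.random.default_rng(8)
        gc = duncan_letters({"lo": rng.normal(0, 1, 6), "hi": rng.normal(100, 1, 6)})
        assert gc.letters["hi"] == "a" and gc.letters["lo"] == "b"

    def test_identical_groups_share_one_letter(self):
        gc = duncan_letters({k: [1.0, 1.1, 0.9] for k in "abcd"})
        assert set(gc.letters.values()) == {"a"}

    def test_letters_consistent_with_mean_ordering(self):
        """Simulated 8-stage biomass pattern: letters nest over sorted means."""
        rng = np.random.default_rng(9)
        means = [100, 300, 550, 1800, 5200, 17500, 24200, 15500]
        groups = {s: rng.normal(m, m * 0.2 + 10, 6) for s, m in zip(range(8), means)}
        gc = duncan_letters(groups)
        n_letters = len(set("".join(gc.letters.values())))
        assert 2 <= n_letters <= 8
        order = sorted(groups, key=lambda k: gc.means[k], reverse=True)
        # sharing is contiguous along the mean ordering (transitive spans)
        for letter in set("".join(gc.letters.values())):
            pos = [i for i, k in enumerate(order) if letter in gc.letters[k]]
            assert pos == list(range(min(pos), max(pos) + 1))

    def test_three_groups_middle_shares_both_letters(self):
        rng = np.random.default_rng(10)
        groups = {
            "low": rng.normal(0.0, 1.0, 6),
            "mid": rng.normal(1.9, 1.0, 6),
            "high": rng.normal(3.8, 1.0, 6),
        }
        gc = duncan_letters(groups)
        if gc.letters["mid"] == "ab":
            assert gc.letters["high"] == "a" and gc.letters["low"] == "b"
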