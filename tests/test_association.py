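"""Correlations, stepwise selection, Geodetector q and the RD check."""

import itertools

import numpy as np
import pandas as pd
import pytest

from urbwell.association import (
    FACTORS,
    CollinearityError,
    geodetector_q,
    importance_frequency,
    interaction_strata,
    level_factor_correlation,
    minmax_normalize,
    quantile_bins,
    rd_check,
    stepwise_fit,
)


def _random_panel(n, seed, beta=None, sigma=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.random((n, len(FACTORS))), columns=FACTORS)
    beta = beta or {}
    y = sum(b * X[f] for f, b in beta.items()) if beta else \
        pd.Series(np.zeros(n))
    y = y + rng.normal(0, sigma, size=n) if sigma > 0 else y
    return X, np.asarray(y, dtype=float)


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        X, _ = _random_panel(50, 0)
        panel = X.copy()
        panel["P1"] = panel["SE"]
        out = level_factor_correlation(panel, "P1").set_index("factor")
        assert out.loc["SE", "r"] == pytest.approx(1.0)
        panel["P1"] = -panel["NDVI"] + 2.0
        out = level_factor_correlation(panel, "P1").set_index("factor")
        assert out.loc["NDVI", "r"] == pytest.approx(-1.0)

    def test_planted_correlation_within_fisher_tolerance(self):
        rng = np.random.default_rng(1)
        n = 1000
        x = rng.standard_normal(n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        panel = pd.DataFrame({f: rng.random(n) for f in FACTORS})
        panel["SE"] = x
        panel["P1"] = y
        out = level_factor_correlation(panel, "P1").set_index("factor")
        assert out.loc["SE", "r"] == pytest.approx(0.6, abs=0.05)
        assert out.loc["SE", "significant"]

    def test_zero_variance_column_flagged_not_error(self):
        X, _ = _random_panel(30, 2)
        panel = X.copy()
        panel["AT"] = 0.5
        panel["P1"] = panel["SE"]
        out = level_factor_correlation(panel, "P1").set_index("factor")
        assert not out.loc["AT", "defined"]
        assert np.isnan(out.loc["AT", "r"])


class TestMinMax:
    def test_spans_unit_interval_and_idempotent(self):
        X, _ = _random_panel(40, 3)
        X = X * 7 + 3
        once = minmax_normalize(X)
        assert once.min().min() == pytest.approx(0.0)
        assert once.max().max() == pytest.approx(1.0)
        twice = minmax_normalize(once)
        pd.testing.assert_frame_equal(once, twice)


class TestStepwise:
    def test_noiseless_planted_model_recovered_exactly(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((200, 11)),
                         columns=[f"x{k}" for k in range(11)])
        y = 2.0 * X["x1"]
        res = stepwise_fit(y, X)
        assert res.retained == ["x1"]
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=1e-9)
        assert res.coefficients["const"] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_best_subset_oracle_on_strong_signal(self):
        # exhaustive minimum-BIC search over all subsets of 5 candidates
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        cols = ["a", "b", "c", "d", "e"]
        X = pd.DataFrame(rng.random((300, 5)), columns=cols)
        y = (1.0 * X["a"] - 0.8 * X["d"]).to_numpy() \
            + rng.normal(0, 1e-4, 300)
        best, best_bic = None, np.inf
        for k in range(len(cols) + 1):
            for sub in itertools.combinations(cols, k):
                design = sm.add_constant(X[list(sub)].to_numpy()) \
                    if sub else np.ones((300, 1))
                bic = sm.OLS(y, design).fit().bic
                if bic < best_bic:
                    best, best_bic = set(sub), bic
        res = stepwise_fit(y, X)
        assert set(res.retained) == best == {"a", "d"}

    def test_planted_two_factor_recovery_rate(self):
        hits = 0
        for seed in range(20):
            X, y = _random_panel(500, seed,
                                 beta={"SE": 0.5, "NDVI": 0.3}, sigma=0.05)
            res = stepwise_fit(y, X)
            hits += set(res.retained) == {"SE", "NDVI"}
        assert hits >= 19

    def test_pure_noise_mostly_retains_nothing(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.random((200, len(FACTORS))),
                             columns=FACTORS)
            y = rng.standard_normal(200)
            empty += stepwise_fit(y, X).retained == []
        assert empty >= 17  # ~ family-wise entry probability at 0.05

    def test_collinear_columns_prescreened(self):
        X, _ = _random_panel(100, 6)
        X["GY"] = 2 * X["GN"] + 1e-14
        with pytest.raises(CollinearityError) as err:
            stepwise_fit(np.zeros(100) + X["SE"], X)
        assert ("GN", "GY") in err.value.pairs

    def test_too_few_rows_rejected(self):
        X, y = _random_panel(12, 7)
        with pytest.raises(ValueError, match="candidate"):
            stepwise_fit(y, X)


class TestImportance:
    def test_counts_and_ordering(self):
        X, y = _random_panel(200, 8, beta={"SE": 1.0}, sigma=0.01)
        res = stepwise_fit(y, X)
        table = importance_frequency([res] * 3)
        assert table.iloc[0]["factor"] == "SE"
        assert table.iloc[0]["count"] == 3

    def test_planted_retention_frequencies_order(self):
        results = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            beta = {"NDVI": 0.8}
            if rng.random() < 0.6:
                beta["SE"] = 0.6
            X, y = _random_panel(300, 100 + seed, beta=beta, sigma=0.05)
            results.append(stepwise_fit(y, X))
        table = importance_frequency(results).set_index("factor")
        assert table.loc["NDVI", "count"] > table.loc["SE", "count"]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            importance_frequency([])


class TestGeodetector:
    def test_hand_cases(self):
        q0 = geodetector_q(np.array([1, 2, 1, 2.0]),
                           np.array(list("AABB")), n_permutations=0)
        assert q0.q == pytest.approx(0.0, abs=1e-12)
        q1 = geodetector_q(np.array([1, 1, 2, 2.0]),
                           np.array(list("AABB")), n_permutations=0)
        assert q1.q == pytest.approx(1.0, abs=1e-12)
        qm = geodetector_q(np.arange(1.0, 7.0),
                           np.array(list("AAABBB")), n_permutations=0)
        assert qm.q == pytest.approx(1 - 4 / 17.5, abs=1e-12)

    def test_q_bounded_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            n = rng.integers(6, 40)
            y = rng.standard_normal(n)
            labels = rng.integers(0, 3, size=n)
            q = geodetector_q(y, labels, n_permutations=0, min_stratum=1).q
            assert 0.0 <= q <= 1.0 + 1e-12

    def test_refinement_never_decreases_q(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            y = rng.standard_normal(30)
            coarse = rng.integers(0, 3, size=30)
            split = coarse.copy()
            which = coarse == 0
            split[which] = np.where(rng.random(which.sum()) < 0.5, 0, 9)
            qc = geodetector_q(y, coarse, n_permutations=0, min_stratum=1).q
            qf = geodetector_q(y, split, n_permutations=0, min_stratum=1).q
            assert qf >= qc - 1e-12

    def test_permutation_significance_detects_real_structure(self):
        rng = np.random.default_rng(11)
        y = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(3, 0.1, 50)])
        labels = np.repeat([0, 1], 50)
        res = geodetector_q(y, labels, n_permutations=199, rng=rng)
        assert res.significant
        noise = geodetector_q(rng.standard_normal(100), labels,
                              n_permutations=199, rng=rng)
        assert noise.p_value > 0.05

    def test_interaction_refines_both_margins(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(200)
        a = quantile_bins(rng.random(200), 4)
        b = quantile_bins(rng.random(200), 4)
        qa = geodetector_q(y, a, n_permutations=0, min_stratum=1).q
        qb = geodetector_q(y, b, n_permutations=0, min_stratum=1).q
        qab = geodetector_q(y, interaction_strata(a, b),
                            n_permutations=0, min_stratum=1).q
        assert qab >= max(qa, qb) - 1e-12

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            geodetector_q(np.ones(10), np.arange(10) % 2, n_permutations=0)


class TestRDCheck:
    def test_single_global_line_zero_delta(self):
        x = np.linspace(0, 1, 50)
        res = rd_check(2 * x, x, cutoff=0.5)
        assert res.delta < 1e-10
        assert res.linear  # passes the 0.05 criterion by construction

    def test_constructed_jump_recovered(self):
        x = np.linspace(0, 1, 100)
        y = x + 0.3 * (x >= 0.5)
        res = rd_check(y, x, cutoff=0.5)
        assert res.delta == pytest.approx(0.3, abs=1e-10)
        assert not res.linear

    def test_default_cutoff_is_midpoint(self):
        x = np.linspace(2, 4, 30)
        res = rd_check(x * 0.5, x)
        assert res.cutoff == pytest.approx(3.0)

    def test_one_sided_data_rejected(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            rd_check(x, x, cutoff=2.0)
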