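"""Score inference: posterior correctness, variance fitting, FWER calling,
and shuffle enrichment."""

import numpy as np
import pytest

from hidra.fragio import Fragment, GenomicInterval, SampleManifest
from hidra.grouping import TiledRegion
from hidra.sharprre import (
    NullCalibration,
    RegionDesign,
    ScoreTrack,
    VarianceParams,
    build_design,
    calibrate_null,
    call_drivers,
    design_from_rows,
    fit_variances,
    infer_scores,
    shuffle_enrichment,
)

REGION = GenomicInterval("chr1", 0, 2000)


def random_design(rng, T=300, M=30, region_len=None, standardize=True):
    region_len = region_len or T
    region = GenomicInterval("chr1", 0, region_len)
    starts = rng.integers(0, region_len - 20, size=M)
    lens = rng.integers(10, max(11, region_len // 2), size=M)
    ivs = [GenomicInterval("chr1", int(s), int(min(s + l, region_len))) for s, l in zip(starts, lens)]
    y = rng.standard_normal(M)
    return design_from_rows(region, ivs, y, standardize=standardize)


def dense_ridge_oracle(design, params):
    """argmin ||y - As||^2/sigma2 + ||s||^2/tau2, solved densely in T x T."""
    A = design.weights
    T = design.n_positions
    H = A.T @ A / params.sigma2 + np.eye(T) / params.tau2
    mu = np.linalg.solve(H, A.T @ design.y / params.sigma2)
    v = np.diag(np.linalg.inv(H))
    return mu, v


class TestDesign:
    def test_row_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = random_design(rng, T=2000, M=10, region_len=2000)
        W = d.weights
        assert W.shape == (d.n_rows, 2000)
        assert np.allclose(W.sum(axis=1), 1.0)

    def test_full_span_fragment_weight_is_uniform(self):
        d = design_from_rows(REGION, [GenomicInterval("chr1", 0, 2000),
                                      GenomicInterval("chr1", 0, 1000)], [1.0, 0.0])
        full = d.weights[np.flatnonzero(d.lengths == 2000)[0]]
        assert np.allclose(full, 1.0 / 2000)

    def test_activities_centered_after_standardization(self):
        rng = np.random.default_rng(1)
        d = random_design(rng)
        assert d.y.mean() == pytest.approx(0.0, abs=1e-12)
        assert d.y.std() == pytest.approx(1.0)

    def test_single_endpoint_pattern_not_dissectable(self):
        ivs = [GenomicInterval("chr1", 0, 500)] * 3
        with pytest.raises(ValueError, match="not dissectable"):
            design_from_rows(REGION, ivs, [1.0, 2.0, 3.0])

    def test_duplicate_patterns_collapse_with_weights(self):
        ivs = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 0, 500),
               GenomicInterval("chr1", 100, 700)]
        d = design_from_rows(REGION, ivs, [1.0, 3.0, 0.0], row_weights=[1.0, 3.0, 1.0],
                             standardize=False)
        assert d.n_rows == 2
        assert d.y[0] == pytest.approx(2.5)  # (1*1 + 3*3)/4

    def test_gram_matches_dense_product(self):
        rng = np.random.default_rng(2)
        d = random_design(rng, T=200, M=20, region_len=200)
        assert np.allclose(d.gram(), d.weights @ d.weights.T, atol=1e-12)

    def test_binning_coarser_than_nt(self):
        d = design_from_rows(REGION, [GenomicInterval("chr1", 0, 500),
                                      GenomicInterval("chr1", 250, 900)], [1.0, -1.0], bin_size=5)
        assert d.n_positions == 400
        assert d.lengths.tolist() == [100, 130]


class TestInferScores:
    def test_zero_observations_zero_posterior(self):
        ivs = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 200, 800)]
        d = design_from_rows(REGION, ivs, [0.0, 0.0], standardize=False)
        t = infer_scores(d, VarianceParams(1.0, 0.5))
        assert np.allclose(t.mean, 0.0)
        assert np.allclose(t.z, 0.0)
        assert (t.var > 0).all()

    def test_single_full_span_row_closed_form(self):
        """One row covering all T bins: flat posterior (tau2/T)y / (tau2/T + sigma2)."""
        T, tau2, sigma2, y1 = 100, 2.0, 0.5, 1.7
        d = RegionDesign(
            region=GenomicInterval("chr1", 0, T), bin_size=1,
            row_starts=np.array([0]), row_ends=np.array([T]), y=np.array([y1]),
        )
        t = infer_scores(d, VarianceParams(tau2, sigma2))
        expected = (tau2 / T) * y1 / (tau2 / T + sigma2)
        assert np.allclose(t.mean, expected)
        assert np.ptp(t.mean) < 1e-12  # flat

    def test_posterior_matches_dense_ridge_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            T = int(rng.integers(50, 301))
            M = int(rng.integers(5, 51))
            d = random_design(rng, T=T, M=M, region_len=T)
            params = VarianceParams(float(rng.uniform(0.2, 5)), float(rng.uniform(0.1, 2)))
            t = infer_scores(d, params)
            mu, v = dense_ridge_oracle(d, params)
            assert np.max(np.abs(t.mean - mu)) < 1e-8
            assert np.max(np.abs(t.var - v)) < 1e-8

    def test_infinite_noise_shrinks_to_prior_mean(self):
        rng = np.random.default_rng(4)
        d = random_design(rng, T=200, M=20, region_len=200)
        t = infer_scores(d, VarianceParams(1.0, 1e9))
        assert np.max(np.abs(t.mean)) < 1e-6

    def test_vanishing_noise_recovers_least_squares(self):
        """With single-bin rows forming an identity design, mu -> y."""
        T = 8
        region = GenomicInterval("chr1", 0, T)
        ivs = [GenomicInterval("chr1", i, i + 1) for i in range(T)]
        y = np.arange(T, dtype=float) - 3.0
        d = design_from_rows(region, ivs, y, standardize=False)
        t = infer_scores(d, VarianceParams(5.0, 1e-8))
        assert np.allclose(t.mean, y, atol=1e-5)


class TestFitVariances:
    def test_parameter_recovery_from_model_draws(self):
        """tau2/sigma2 are recovered from model draws when rows are short
        enough for the prior variance to be identifiable (a row of length L
        carries signal variance tau2/L, so very long rows wash tau2 out)."""
        tau2, sigma2 = 1.0, 0.25
        errs_t, errs_s = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            region = GenomicInterval("chr1", 0, 200)
            starts = rng.integers(0, 195, size=200)
            lens = rng.integers(5, 40, size=200)
            ivs = [GenomicInterval("chr1", int(s), int(min(s + l, 200))) for s, l in zip(starts, lens)]
            d = design_from_rows(region, ivs, np.zeros(len(ivs)), standardize=False)
            s = rng.normal(0, np.sqrt(tau2), d.n_positions)
            d.y = d.weights @ s + rng.normal(0, np.sqrt(sigma2), d.n_rows)
            fit = fit_variances(d)
            errs_t.append(fit.tau2 / tau2)
            errs_s.append(fit.sigma2 / sigma2)
        assert 0.5 < np.median(errs_t) < 1.5
        assert 0.5 < np.median(errs_s) < 1.5

    def test_flat_zero_signal_hits_lower_bound(self):
        rng = np.random.default_rng(5)
        d = random_design(rng, T=300, M=30, region_len=300, standardize=False)
        d.y = np.zeros(d.n_rows)
        fit = fit_variances(d)
        assert fit.tau2 == pytest.approx(1e-4, rel=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        d = random_design(rng, T=300, M=40, region_len=300, standardize=False)
        fit1 = fit_variances(d)
        d2 = random_design(np.random.default_rng(6), T=300, M=40, region_len=300, standardize=False)
        d2.y = 2.0 * d.y
        fit2 = fit_variances(d2)
        total1 = fit1.tau2 / 300 + fit1.sigma2  # rough marginal scale proxy
        assert (fit2.tau2 + 1e-4) / (fit1.tau2 + 1e-4) + fit2.sigma2 / fit1.sigma2 > 0
        # the fitted marginal variance of y quadruples
        G = d.gram()
        m1 = np.mean(np.diag(fit1.tau2 * G) + fit1.sigma2)
        m2 = np.mean(np.diag(fit2.tau2 * G) + fit2.sigma2)
        assert m2 / m1 == pytest.approx(4.0, rel=0.2)

    def test_requires_min_rows(self):
        d = design_from_rows(REGION, [GenomicInterval("chr1", 0, 100),
                                      GenomicInterval("chr1", 50, 200)], [1.0, -1.0])
        with pytest.raises(ValueError, match=">= 10 rows"):
            fit_variances(d)


class TestCalibration:
    def make(self, rng, M=20):
        return random_design(rng, T=500, M=M, region_len=500)

    def test_refuses_unstable_mc_size(self):
        rng = np.random.default_rng(7)
        d = self.make(rng)
        with pytest.raises(ValueError, match="n_mc"):
            calibrate_null(d, VarianceParams(1.0, 1.0), n_mc=50)

    def test_p_value_floor_is_smoothed(self):
        rng = np.random.default_rng(8)
        d = self.make(rng)
        c = calibrate_null(d, VarianceParams(1.0, 1.0), n_mc=200, seed=0)
        assert c.pvalue(np.inf) == pytest.approx(1 / 201)
        assert c.pvalue(-np.inf) == pytest.approx(1.0)

    def test_critical_monotone_in_confidence(self):
        rng = np.random.default_rng(9)
        d = self.make(rng)
        params = VarianceParams(1.0, 1.0)
        crits = [calibrate_null(d, params, alpha=a, n_mc=500, seed=1).critical
                 for a in (0.2, 0.05, 0.01)]
        assert crits[0] <= crits[1] <= crits[2]

    def test_null_regions_rarely_yield_drivers(self):
        """Small-scale FWER check; the full 500-region study runs in acceptance."""
        from hidra.calibration import fwer_null_study

        res = fwer_null_study(n_regions=100, n_mc=300, seed=3)
        se = np.sqrt(0.05 * 0.95 / 100)
        assert res["fraction"] <= 0.05 + 2 * se


class TestCallDrivers:
    def track(self, z):
        z = np.asarray(z, dtype=float)
        return ScoreTrack(region=GenomicInterval("chr1", 0, len(z)), bin_size=1,
                          mean=z.copy(), var=np.ones_like(z), z=z)

    def calib(self, critical=2.0):
        return NullCalibration(alpha=0.05, n_mc=999, seed=0, critical=critical,
                               max_sample=np.linspace(0, 4, 999))

    def test_no_exceedance_no_elements(self):
        assert call_drivers(self.track(np.zeros(100)), self.calib()) == []

    def test_single_run_extracted_with_length(self):
        z = np.zeros(100)
        z[40:67] = 3.0
        els = call_drivers(self.track(z), self.calib())
        assert len(els) == 1
        assert (els[0].interval.start, els[0].interval.end) == (40, 67)
        assert els[0].interval.length == 27
        assert els[0].peak_z == 3.0

    def test_runs_split_by_single_gap(self):
        z = np.zeros(50)
        z[10:20] = 3.0
        z[21:30] = 3.0
        els = call_drivers(self.track(z), self.calib())
        assert len(els) == 2

    def test_min_len_filters_short_runs(self):
        z = np.zeros(50)
        z[10:12] = 3.0
        assert call_drivers(self.track(z), self.calib(), min_len=3) == []

    def test_fwer_p_reflects_exceedance(self):
        z = np.zeros(50)
        z[10:20] = 3.9
        els = call_drivers(self.track(z), self.calib())
        n_ge = int((np.linspace(0, 4, 999) >= 3.9).sum())
        assert els[0].p_fwer == pytest.approx((1 + n_ge) / 1000)

    def test_driver_recovery_and_resolution(self):
        """Embedded-driver simulations: localization works and sharpens with
        coverage (reduced-scale mirror of the acceptance studies)."""
        from hidra.calibration import driver_recovery_study, resolution_study

        rec = driver_recovery_study(n_runs=10, n_mc=500, seed=1)
        assert rec["peak_hit_rate"] >= 0.8
        res = resolution_study(fragment_counts=(10, 40), n_regions=25, n_mc=500, seed=1)
        assert res[40]["n_called"] > res[10]["n_called"]


class TestBuildDesignFromRegion:
    def test_rows_are_unique_endpoint_patterns(self, small_manifest):
        frags = [
            Fragment(GenomicInterval("chr1", 0, 300), "AAAA", np.array([10, 10, 10, 10])),
            Fragment(GenomicInterval("chr1", 0, 300), "CCCC", np.array([10, 10, 30, 30])),
            Fragment(GenomicInterval("chr1", 100, 500), "GGGG", np.array([10, 10, 10, 10])),
        ]
        region = TiledRegion(GenomicInterval("chr1", 0, 500), frags)
        d = build_design(region, small_manifest)
        assert d.n_rows == 2  # identical endpoints collapsed by count summing

    def test_empty_region_rejected(self, small_manifest):
        region = TiledRegion(GenomicInterval("chr1", 0, 500), [])
        with pytest.raises(ValueError, match="no member fragments"):
            build_design(region, small_manifest)


class TestShuffleEnrichment:
    def test_degenerate_null_reports_p_one(self):
        uni = [GenomicInterval("chr1", 0, 1000)]
        elements = [GenomicInterval("chr1", 100, 150)]
        res = shuffle_enrichment(elements, features=uni, universe=uni, n_shuffles=100, seed=0)
        assert res["p"] == 1.0
        assert np.isnan(res["z"])

    def test_two_interval_toy_matches_enumeration(self):
        # 1 element, 2 equal universe intervals, feature covers exactly one:
        # each shuffle lands in the feature interval with probability 1/2
        uni = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 5000, 6000)]
        feature = [GenomicInterval("chr1", 0, 1000)]
        elements = [GenomicInterval("chr1", 100, 150)]
        res = shuffle_enrichment(elements, feature, uni, n_shuffles=2000, seed=1)
        assert res["observed"] == 1
        assert res["null_mean"] == pytest.approx(0.5, abs=0.05)

    def test_element_larger_than_universe_rejected(self):
        uni = [GenomicInterval("chr1", 0, 100)]
        with pytest.raises(ValueError, match="fits in no universe"):
            shuffle_enrichment([GenomicInterval("chr1", 0, 500)], [], uni, n_shuffles=10, seed=0)

    def test_shuffles_stay_inside_universe(self):
        rng = np.random.default_rng(2)
        uni = [GenomicInterval("chr1", 0, 500), GenomicInterval("chr2", 0, 300)]
        elements = [GenomicInterval("chr1", 10, 110)]
        # features outside the universe are never hit by shuffles
        outside = [GenomicInterval("chr1", 600, 700), GenomicInterval("chr3", 0, 1000)]
        res = shuffle_enrichment(elements, outside, uni, n_shuffles=500, seed=2)
        assert res["null_mean"] == 0.0
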