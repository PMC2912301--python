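"""Segmentation engine: DP posteriors, estimators, level calling."""

import numpy as np
import pytest

from gbpcr import (
    BreakpointPosterior,
    EmissionParamTable,
    EngineConfig,
    LOHTrack,
    PeakThresholdSpec,
    boundaries_binerr,
    compute_posteriors,
    estimate_k_01,
    find_peaks,
    map_segment_levels,
    resolve_thresholds,
    run_segmentation,
    segment_loglik,
    snp_outcome_prob,
)
from gbpcr.cn_prior import EventPriorTrack, event_prior_from_z
from gbpcr.errors import UnestimableLevelError, ValidationError

from conftest import (
    brute_force_class_posterior,
    brute_force_posteriors,
    random_instance,
)


def uniform_priors(n, classes=(-2, -1, 0, 2)):
    return EventPriorTrack(
        classes=classes,
        probs=np.full((n, len(classes)), 1.0 / len(classes)),
        model=1,
    )


def noiseless_params(e: float = 1e-6) -> EmissionParamTable:
    """Emission table with error rate e: loss always reads NHet, normal reads
    the true genotype, homozygous deletion reads NoCall."""
    cond = np.zeros((2, 4, 3))
    cond[0, 2] = (e, 1 - 2 * e, e)      # Het, w=0
    cond[1, 2] = (e, e, 1 - 2 * e)      # Hom, w=0
    cond[0, 1] = (e, e, 1 - 2 * e)      # w=-1
    cond[1, 1] = (e, e, 1 - 2 * e)
    cond[0, 0] = (1 - 2 * e, e, e)      # w=-2
    cond[1, 0] = (1 - 2 * e, e, e)
    cond[0, 3] = (e, 1 - 2 * e, e)      # w=2 behaves like normal for Het
    cond[1, 3] = (e, e, 1 - 2 * e)
    return EmissionParamTable(cond=cond, upd_row=(e, e, 1 - 2 * e))


class TestSegmentLoglik:
    def test_empty_segment_is_zero(self, default_params):
        loh = LOHTrack(y=[1, 2, 0], nu=[0.3, 0.3, 0.3])
        assert segment_loglik(loh, 2, 2, 0, default_params) == 0.0

    def test_additivity(self, default_params):
        loh = LOHTrack(y=[1, 2], nu=[0.2, 0.7])
        total = segment_loglik(loh, 0, 2, -1, default_params)
        parts = segment_loglik(loh, 0, 1, -1, default_params) + segment_loglik(
            loh, 1, 2, -1, default_params
        )
        assert total == pytest.approx(parts)

    def test_matches_explicit_genotype_marginalization(self, default_params):
        # 3-SNP segment: brute-force sum over the 2^3 normal-genotype configs
        y = [2, 1, 0]
        nu = [0.3, 0.6, 0.1]
        loh = LOHTrack(y=y, nu=nu)
        total = 0.0
        for bits in range(8):
            weight, lik = 1.0, 1.0
            for i in range(3):
                x = (bits >> i) & 1  # 0 = Het, 1 = Hom
                weight *= nu[i] if x == 0 else 1 - nu[i]
                lik *= default_params.cond[x, 1, y[i]]  # w = -1 rows
            total += weight * lik
        assert segment_loglik(loh, 0, 3, -1, default_params) == pytest.approx(
            np.log(total)
        )

    def test_out_of_range_rejected(self, default_params):
        loh = LOHTrack(y=[1], nu=[0.5])
        with pytest.raises(ValidationError):
            segment_loglik(loh, 0, 2, 0, default_params)


class TestComputePosteriors:
    def test_single_point(self, default_params):
        loh = LOHTrack(y=[1], nu=[0.5])
        bp = compute_posteriors(loh, uniform_priors(1), default_params, k_max=3)
        assert bp.p.size == 0
        np.testing.assert_allclose(bp.k_posterior, [1.0])

    def test_k_max_one_forces_single_segment(self, default_params):
        loh = LOHTrack(y=[1, 2, 2, 0, 1], nu=np.full(5, 0.4))
        bp = compute_posteriors(loh, uniform_priors(5), default_params, k_max=1)
        np.testing.assert_allclose(bp.k_posterior, [1.0])
        np.testing.assert_allclose(bp.p, 0.0)

    def test_flat_likelihood_reduces_to_k_prior(self, default_params):
        # single-class prior: every segmentation has the same total likelihood,
        # so P(K|y) is the normalized 1/k^2 prior: (36/49, 9/49, 4/49)
        n = 6
        priors = EventPriorTrack(classes=(0,), probs=np.ones((n, 1)), model=1)
        loh = LOHTrack(y=np.full(n, 1), nu=np.full(n, 0.5))
        bp = compute_posteriors(loh, priors, default_params, k_max=3)
        np.testing.assert_allclose(
            bp.k_posterior, [36 / 49, 9 / 49, 4 / 49], atol=1e-12
        )

    def test_matches_enumeration_n5(self, default_params):
        rng = np.random.default_rng(17)
        loh, priors, params = random_instance(rng, 5)
        bp = compute_posteriors(loh, priors, params, k_max=3)
        kp, p = brute_force_posteriors(loh, priors, params, 3)
        np.testing.assert_allclose(bp.k_posterior, kp, rtol=1e-10)
        np.testing.assert_allclose(bp.p, p, rtol=1e-10)

    def test_expected_boundary_count_identity(self, default_params):
        rng = np.random.default_rng(3)
        loh, priors, params = random_instance(rng, 30)
        bp = compute_posteriors(loh, priors, params, k_max=8)
        assert bp.p.sum() == pytest.approx(bp.expected_boundary_count(), abs=1e-8)

    def test_reversal_symmetry(self):
        # reversing data, priors and het priors reverses p, keeps P(K|y)
        rng = np.random.default_rng(8)
        loh, priors, params = random_instance(rng, 24)
        bp = compute_posteriors(loh, priors, params, k_max=6)
        loh_r = LOHTrack(y=loh.y[::-1].copy(), nu=loh.nu[::-1].copy())
        priors_r = EventPriorTrack(
            classes=priors.classes, probs=priors.probs[::-1].copy(),
            model=priors.model, p_upd=priors.p_upd,
        )
        bp_r = compute_posteriors(loh_r, priors_r, params, k_max=6)
        np.testing.assert_allclose(bp_r.k_posterior, bp.k_posterior, rtol=1e-9)
        np.testing.assert_allclose(bp_r.p, bp.p[::-1], rtol=1e-8)

    def test_k_max_capped_at_n(self, default_params):
        loh = LOHTrack(y=[1, 2, 1], nu=np.full(3, 0.4))
        bp = compute_posteriors(loh, uniform_priors(3), default_params, k_max=10)
        assert bp.k_posterior.size == 3

    def test_zero_probability_observations_handled(self):
        # an observation impossible under one class must veto that class
        # without poisoning the log-space DP with NaNs
        params = noiseless_params(0.0)
        loh = LOHTrack(y=[1, 1, 2, 2], nu=np.full(4, 0.5))
        priors = uniform_priors(4)
        bp = compute_posteriors(loh, priors, params, k_max=3)
        assert np.all(np.isfinite(bp.k_posterior))
        assert np.all(np.isfinite(bp.p))

    def test_log_space_stability_large_track(self, default_params):
        # products of 10^4 per-SNP probabilities underflow linear space; the
        # log-space DP must stay finite end to end
        rng = np.random.default_rng(1)
        n = 10**4
        loh = LOHTrack(y=rng.integers(0, 3, n), nu=rng.random(n))
        bp = compute_posteriors(loh, uniform_priors(n), default_params, k_max=2)
        assert np.isfinite(bp.log_evidence)
        assert np.all(np.isfinite(bp.k_posterior))
        assert np.all((bp.p >= 0) & (bp.p <= 1))


class TestKAndBoundaryEstimators:
    def test_k01_is_argmax(self):
        bp = BreakpointPosterior(
            p=np.zeros(9), k_posterior=[0.2, 0.5, 0.3], log_evidence=0.0, k_max=3
        )
        assert estimate_k_01(bp) == 2

    def test_k01_tie_prefers_smaller(self):
        bp = BreakpointPosterior(
            p=np.zeros(9), k_posterior=[0.4, 0.4, 0.2], log_evidence=0.0, k_max=3
        )
        assert estimate_k_01(bp) == 1

    def test_binerr_k1_empty(self):
        bp = BreakpointPosterior(
            p=np.array([0.1, 0.9]), k_posterior=[1.0], log_evidence=0.0, k_max=1
        )
        assert boundaries_binerr(bp, 1).size == 0

    def test_binerr_top_positions(self):
        bp = BreakpointPosterior(
            p=np.array([0.1, 0.9, 0.05, 0.6]), k_posterior=[1.0],
            log_evidence=0.0, k_max=1,
        )
        np.testing.assert_array_equal(boundaries_binerr(bp, 3), [2, 4])

    def test_binerr_duplicate_maxima_leftmost(self):
        bp = BreakpointPosterior(
            p=np.array([0.1, 0.7, 0.2, 0.3, 0.7]), k_posterior=[1.0],
            log_evidence=0.0, k_max=1,
        )
        np.testing.assert_array_equal(boundaries_binerr(bp, 2), [2])

    def test_binerr_too_many_boundaries_rejected(self):
        bp = BreakpointPosterior(
            p=np.array([0.5]), k_posterior=[1.0], log_evidence=0.0, k_max=1
        )
        with pytest.raises(ValidationError):
            boundaries_binerr(bp, 5)


class TestResolveThresholds:
    def test_mad_rule_direct_evaluation(self):
        # median 0.01 and mad 0.01 -> 0.01 + 3 * 0.01 = 0.04
        p = np.array([0.0, 0.0, 0.01, 0.02, 0.02])
        thr1, thr2 = resolve_thresholds(PeakThresholdSpec("mad", "mad"), p)
        assert thr1 == pytest.approx(0.04)

    def test_floor_dominates_on_zeros(self):
        thr1, _ = resolve_thresholds(PeakThresholdSpec("01", "01"), np.zeros(50))
        assert thr1 == 0.01

    def test_quantile_dominates_on_large_p(self):
        thr1, _ = resolve_thresholds(PeakThresholdSpec("005", "005"), np.full(40, 0.5))
        assert thr1 == 0.5

    def test_distinct_rules_allowed(self):
        p = np.linspace(0, 0.2, 100)
        thr1, thr2 = resolve_thresholds(PeakThresholdSpec("01_90", "mad"), p)
        assert thr1 == pytest.approx(max(0.01, np.quantile(p, 0.90)))
        assert thr2 == pytest.approx(np.median(p) + 3 * np.median(np.abs(p - np.median(p))))

    def test_explicit_values_pass_through(self):
        thr1, thr2 = resolve_thresholds(PeakThresholdSpec(0.2, 0.3), np.zeros(5))
        assert (thr1, thr2) == (0.2, 0.3)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValidationError):
            resolve_thresholds(PeakThresholdSpec("q99", "q99"), np.zeros(5))


class TestFindPeaks:
    def test_flat_input_single_segment(self):
        k, t = find_peaks(np.zeros(20), 0.1, 0.3, bandwidth=0)
        assert k == 1 and t.size == 0

    def test_two_threshold_hand_trace(self):
        p = np.array([0, 0, 0.9, 0.2, 0, 0, 0.5, 0])
        k, t = find_peaks(p, thr1=0.1, thr2=0.3, bandwidth=0)
        assert k == 3
        np.testing.assert_array_equal(t, [3, 7])

    def test_significance_threshold_drops_weak_peak(self):
        p = np.array([0, 0, 0.9, 0.2, 0, 0, 0.5, 0])
        k, t = find_peaks(p, thr1=0.1, thr2=0.6, bandwidth=0)
        assert k == 2
        np.testing.assert_array_equal(t, [3])

    def test_smoothing_merges_adjacent_points_into_one_peak(self):
        # two high values 2 apart: raw thresholding sees two peaks separated
        # by a sub-threshold gap; bandwidth-1 smoothing bridges the gap
        p = np.array([0, 0.8, 0.2, 0.8, 0, 0, 0, 0])
        k_raw, t_raw = find_peaks(p, 0.3, 0.3, bandwidth=0)
        k_sm, t_sm = find_peaks(p, 0.3, 0.3, bandwidth=1)
        assert k_raw == 3
        np.testing.assert_array_equal(t_raw, [2, 4])
        assert k_sm == 2
        np.testing.assert_array_equal(t_sm, [2])  # leftmost raw maximum

    def test_peak_position_is_raw_maximum(self):
        p = np.array([0, 0.2, 0.3, 0.9, 0.3, 0.2, 0, 0])
        _, t = find_peaks(p, 0.1, 0.1, bandwidth=2)
        np.testing.assert_array_equal(t, [4])


class TestMapSegmentLevels:
    def test_degenerate_prior_dominates(self, default_params):
        n = 12
        probs = np.zeros((n, 4))
        probs[:, 1] = 1.0  # all mass on w = -1
        priors = EventPriorTrack(classes=(-2, -1, 0, 2), probs=probs, model=1)
        loh = LOHTrack(y=np.full(n, 1), nu=np.full(n, 0.9))
        res = map_segment_levels(loh, np.array([5]), priors, default_params)
        assert [s.w for s in res.segments] == [-1, -1]
        for s in res.segments:
            assert s.map_prob == pytest.approx(1.0)

    def test_all_nhet_run_called_ibd_upd(self, default_params):
        # 50 NHet SNPs, normal CN prior, p_upd=1e-3: the IBD/UPD class wins by
        # a likelihood factor ~(0.96/0.69)^50 despite the 1e-3 prior
        n = 50
        z_rows = np.array([[0.0, 0.0, 1.0, 0.0]])
        priors = event_prior_from_z(z_rows, np.array([0, n]), model=2, p_upd=1e-3)
        loh = LOHTrack(y=np.full(n, 2), nu=np.full(n, 0.3))
        res = map_segment_levels(loh, np.array([], dtype=int), priors, default_params)
        assert res.segments[0].w == -3
        oracle = brute_force_class_posterior(loh, priors, default_params, 0, n)
        np.testing.assert_allclose(res.segments[0].posterior, oracle, rtol=1e-9)

    def test_matches_enumeration_per_segment(self):
        rng = np.random.default_rng(23)
        loh, priors, params = random_instance(rng, 10)
        res = map_segment_levels(loh, np.array([4, 7]), priors, params)
        for seg in res.segments:
            oracle = brute_force_class_posterior(
                loh, priors, params, seg.start, seg.end
            )
            np.testing.assert_allclose(seg.posterior, oracle, rtol=1e-9)

    def test_zero_normalizer_raises_named_error(self):
        params = noiseless_params(0.0)
        # prior allows only loss, but a Het call is impossible under loss
        probs = np.zeros((4, 4))
        probs[:, 1] = 1.0
        priors = EventPriorTrack(classes=(-2, -1, 0, 2), probs=probs, model=1)
        loh = LOHTrack(y=[2, 2, 1, 2], nu=np.full(4, 0.5))
        with pytest.raises(UnestimableLevelError, match=r"\(0, 4\]"):
            map_segment_levels(loh, np.array([], dtype=int), priors, params, chrom=None)


class TestRunSegmentation:
    def test_homogeneous_track_single_normal_segment(self, default_params):
        n = 60
        z_rows = np.array([[0.01, 0.04, 0.9, 0.05]])
        priors = event_prior_from_z(z_rows, np.array([0, n]), model=1)
        rng = np.random.default_rng(0)
        nu = np.full(n, 0.8)
        y = np.where(rng.random(n) < nu * 0.93, 1, 2)
        loh = LOHTrack(y=y, nu=nu)
        res = run_segmentation(loh, priors, default_params, EngineConfig(k_max=8))
        assert res.k == 1
        assert res.segments[0].w == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_likelihood_dominance_recovers_planted_profile(self, seed):
        # near-noiseless emissions with informative (Het) flanks: the planted
        # normal | loss | normal profile is recovered exactly
        params = noiseless_params(1e-6)
        b = np.array([0, 40, 70, 120])
        rows = np.array([[0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 1, 0]], dtype=float)
        rng = np.random.default_rng(seed)
        nu = rng.uniform(0.5, 0.99, 120)
        w = np.repeat([0, -1, 0], np.diff(b))
        y = np.where(w == -1, 2, 1)  # normal cells heterozygous throughout
        loh = LOHTrack(y=y, nu=nu)
        priors = event_prior_from_z(rows, b, model=1)
        res = run_segmentation(
            loh, priors, params, EngineConfig(k_max=10, estimator="binerr")
        )
        np.testing.assert_array_equal(res.interior_boundaries(), [40, 70])
        assert [s.w for s in res.segments] == [0, -1, 0]

    def test_merge_equal_levels_collapses_neighbors(self, default_params):
        n = 30
        priors = uniform_priors(n)
        loh = LOHTrack(y=np.full(n, 1), nu=np.full(n, 0.9))
        raw = map_segment_levels(loh, np.array([10, 20]), priors, default_params)
        assert raw.k == 3
        from gbpcr.segmentation_engine import merge_equal_levels

        merged = merge_equal_levels(raw, loh, priors, default_params)
        assert merged.k == 1
        assert merged.raw is raw
        assert merged.segments[0].w == raw.segments[0].w

    def test_numpy_fallback_matches_jit_kernels(self):
        # the pure-numpy DP path must agree with the compiled kernels
        import gbpcr.segmentation_engine as se

        rng = np.random.default_rng(4)
        loh, priors, params = random_instance(rng, 40)
        a_jit = se._log_evidence_matrix(loh, priors, params)
        had_numba = se._HAVE_NUMBA
        try:
            se._HAVE_NUMBA = False
            a_np = se._log_evidence_matrix(loh, priors, params)
            l_np = se._dp_forward(a_np, 5)
            r_np = se._dp_backward(a_np, 5)
        finally:
            se._HAVE_NUMBA = had_numba
        np.testing.assert_allclose(a_np, a_jit, rtol=1e-12)
        if had_numba:
            np.testing.assert_allclose(se._dp_forward(a_jit, 5), l_np, rtol=1e-10)
            np.testing.assert_allclose(se._dp_backward(a_jit, 5), r_np, rtol=1e-10)

    def test_estimators_share_dp(self, default_params):
        rng = np.random.default_rng(5)
        loh, priors, params = random_instance(rng, 40)
        bp = compute_posteriors(loh, priors, params, k_max=6)
        a = run_segmentation(loh, priors, params,
                             EngineConfig(k_max=6, estimator="binerr"), bp=bp)
        b = run_segmentation(loh, priors, params,
                             EngineConfig(k_max=6, estimator="binerr"))
        np.testing.assert_array_equal(a.boundaries, b.boundaries)
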