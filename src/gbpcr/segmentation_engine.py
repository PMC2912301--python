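"""Exact Bayesian segmentation of the LOH track into aberration classes.

The aberration profile is modeled as a piecewise-constant function of the SNP
index: ``K`` segments (prior proportional to 1/k^2 on {1..k_max}, chosen to
penalize spurious splits and so reduce the false discovery rate) with
boundaries ``T`` uniform over the ordered interior positions, and one latent
class per segment with the per-segment prior supplied by the CN-profile
module.  Conditional on the class, the observed calls inside a segment are
independent categorical draws from the emission model, marginalized over the
unknown normal-cell genotype.

Everything downstream of the single-segment evidence

    A(i, j) = sum_w  pi_(i,j](w) * prod_{l=i+1}^{j} P(y_l | w, nu_l)

is computed exactly by dynamic programming in log-space: the posterior of the
segment number P(K = k | y), the per-position breakpoint posterior p_i, and
the per-segment class posteriors for any fixed boundary set.  The prior of a
candidate segment is the arithmetic mean of the per-SNP priors it covers,
which keeps the evidence well-defined for candidate segments that straddle
CN-profile segments.

Two boundary-estimator families are provided: the 0-1-loss MAP estimate of K
combined with the top-probability positions of p (BinErr), and a peak finder
on the (optionally smoothed) breakpoint posterior that takes the number of
peaks and the locations of their maxima (PeakMax) — the latter avoids
harvesting several near-duplicate positions from the shoulder of one strong
peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp

from .cn_prior import EventPriorTrack
from .emission_model import EmissionParamTable, outcome_prob_track, snp_outcome_prob
from .errors import UnestimableLevelError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LOHTrack:
    """Per-SNP LOH observations: collapsed genotype calls plus het priors.

    ``y`` holds the observed-call codes (0 NoCall, 1 Het, 2 NHet), ``nu`` the
    population heterozygosity prior of each SNP.  ``chrom``/``pos``/``snp_id``
    are optional bookkeeping for genomic output.
    """

    y: np.ndarray
    nu: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    snp_id: np.ndarray | None = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=np.int8)
        nu = np.asarray(self.nu, dtype=float)
        if y.ndim != 1 or y.size < 1:
            raise ValidationError("LOH track needs at least one SNP")
        if np.any((y < 0) | (y > 2)):
            raise ValidationError("observed-call codes must be in {0, 1, 2}")
        if nu.shape != y.shape or np.any((nu < 0) | (nu > 1)):
            raise ValidationError("het priors must match y and lie in [0, 1]")
        for name in ("chrom", "pos", "snp_id"):
            a = getattr(self, name)
            if a is not None and np.asarray(a).shape != y.shape:
                raise ValidationError(f"{name} must have one entry per SNP")
        if self.pos is not None and self.chrom is not None:
            pos = np.asarray(self.pos)
            chrom = np.asarray(self.chrom)
            for c in np.unique(chrom):
                if np.any(np.diff(pos[chrom == c]) < 0):
                    raise ValidationError(f"positions decrease within chromosome {c}")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "nu", nu)

    @property
    def n(self) -> int:
        return self.y.size

    def slice(self, start: int, stop: int) -> "LOHTrack":
        take = lambda a: None if a is None else np.asarray(a)[start:stop]
        return LOHTrack(
            y=self.y[start:stop], nu=self.nu[start:stop],
            chrom=take(self.chrom), pos=take(self.pos), snp_id=take(self.snp_id),
        )


@dataclass(frozen=True)
class BreakpointPosterior:
    """Posterior summaries of the segmentation DP.

    ``p[i]`` (0-based entry ``i``) is the posterior probability of a boundary
    after SNP ``i+1`` (interior position ``i+1`` in 1..n-1);
    ``k_posterior[k-1]`` is P(K = k | y).
    """

    p: np.ndarray
    k_posterior: np.ndarray
    log_evidence: float
    k_max: int

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        kp = np.asarray(self.k_posterior, dtype=float)
        if np.any((p < -1e-12) | (p > 1 + 1e-12)):
            raise ValidationError("breakpoint posteriors must lie in [0, 1]")
        if abs(kp.sum() - 1.0) > 1e-10:
            raise ValidationError("P(K | y) must sum to 1")
        object.__setattr__(self, "p", np.clip(p, 0.0, 1.0))
        object.__setattr__(self, "k_posterior", kp)

    @property
    def n(self) -> int:
        return self.p.size + 1

    def expected_boundary_count(self) -> float:
        k = np.arange(1, self.k_posterior.size + 1)
        return float(np.sum((k - 1) * self.k_posterior))


@dataclass(frozen=True)
class PeakThresholdSpec:
    """Threshold rules and kernel bandwidth for the peak-based estimator.

    ``thr1``/``thr2`` are either rule names ("005", "01", "01_90", "mad") or
    explicit values in [0, 1]; ``bandwidth`` is the half-width (in SNPs) of
    the symmetric moving-average smoother (0 = no smoothing).
    """

    thr1: str | float = "01_90"
    thr2: str | float = "01_90"
    bandwidth: int = 3

    def __post_init__(self):
        if self.bandwidth < 0:
            raise ValidationError("bandwidth must be >= 0")


@dataclass(frozen=True)
class Segment:
    """One called segment: half-open SNP span (start, end], MAP class, posterior."""

    start: int
    end: int
    w: int
    posterior: np.ndarray
    classes: tuple[int, ...]

    @property
    def n_snps(self) -> int:
        return self.end - self.start

    @property
    def map_prob(self) -> float:
        return float(self.posterior[self.classes.index(self.w)])


@dataclass(frozen=True)
class SegmentationResult:
    """Estimated piecewise-constant aberration profile for one track.

    ``boundaries`` includes the outer 0 and n; ``segments`` carry the MAP
    class and the full class posterior of each span.  ``raw`` retains the
    pre-merge segmentation when adjacent equal-class segments were merged for
    reporting.
    """

    boundaries: np.ndarray
    segments: tuple[Segment, ...]
    classes: tuple[int, ...]
    chrom: str | None = None
    raw: "SegmentationResult | None" = None

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(b) <= 0):
            raise ValidationError("segment boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def k(self) -> int:
        return len(self.segments)

    @property
    def n(self) -> int:
        return int(self.boundaries[-1])

    def interior_boundaries(self) -> np.ndarray:
        return self.boundaries[1:-1]

    def per_snp_classes(self) -> np.ndarray:
        return np.repeat(
            [s.w for s in self.segments], np.diff(self.boundaries)
        )


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------

def segment_loglik(
    loh: LOHTrack, i: int, j: int, w: int, params: EmissionParamTable
) -> float:
    """Log-likelihood of the data slice (i, j] under a single class ``w``.

    Conditional independence across SNPs (given the class and the per-SNP
    het priors) makes this a plain sum of per-SNP log marginals; an empty
    slice contributes 0.
    """
    if not 0 <= i <= j <= loh.n:
        raise ValidationError(f"segment indices ({i}, {j}] out of range for n={loh.n}")
    if i == j:
        return 0.0
    probs = snp_outcome_prob(loh.y[i:j], w, loh.nu[i:j], params)
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(probs)))


def _log_binom(n: int, k: int) -> float:
    """log C(n, k); -inf outside the valid range."""
    if k < 0 or k > n:
        return -np.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


try:  # optional JIT acceleration of the O(n^2 k) inner loops
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=True)
def _evidence_kernel(cum_ll, n_zero, cum_pi):  # pragma: no cover - jitted
    n1 = cum_ll.shape[0]
    n_classes = cum_ll.shape[1]
    logA = np.full((n1, n1), -np.inf)
    for i in range(n1):
        for j in range(i + 1, n1):
            length = j - i
            m = -np.inf
            s = 0.0
            for c in range(n_classes):
                dpi = (cum_pi[j, c] - cum_pi[i, c]) / length
                if dpi <= 0.0 or n_zero[j, c] > n_zero[i, c]:
                    continue  # class excluded by prior or a zero-prob SNP
                v = np.log(dpi) + cum_ll[j, c] - cum_ll[i, c]
                if v <= m:
                    s += np.exp(v - m)
                else:
                    s = s * np.exp(m - v) + 1.0
                    m = v
            if m > -np.inf:
                logA[i, j] = m + np.log(s)
    return logA


@_njit(cache=True)
def _dp_forward_kernel(logA, k_max):  # pragma: no cover - jitted
    n1 = logA.shape[0]
    logL = np.full((k_max + 1, n1), -np.inf)
    for j in range(1, n1):
        logL[1, j] = logA[0, j]
    for h in range(2, k_max + 1):
        for j in range(h, n1):
            m = -np.inf
            s = 0.0
            for i in range(h - 1, j):
                v = logL[h - 1, i] + logA[i, j]
                if v == -np.inf:
                    continue
                if v <= m:
                    s += np.exp(v - m)
                else:
                    s = s * np.exp(m - v) + 1.0
                    m = v
            if m > -np.inf:
                logL[h, j] = m + np.log(s)
    return logL


@_njit(cache=True)
def _dp_backward_kernel(logA, k_max):  # pragma: no cover - jitted
    n1 = logA.shape[0]
    n = n1 - 1
    logR = np.full((k_max + 1, n1), -np.inf)
    for i in range(n):
        logR[1, i] = logA[i, n]
    for h in range(2, k_max + 1):
        for i in range(n - h + 1):
            m = -np.inf
            s = 0.0
            for j in range(i + 1, n - h + 2):
                v = logA[i, j] + logR[h - 1, j]
                if v == -np.inf:
                    continue
                if v <= m:
                    s += np.exp(v - m)
                else:
                    s = s * np.exp(m - v) + 1.0
                    m = v
            if m > -np.inf:
                logR[h, i] = m + np.log(s)
    return logR


def _cumulants(loh: LOHTrack, priors: EventPriorTrack, params: EmissionParamTable):
    """Cumulative log-likelihoods (with zero-probability bookkeeping) and priors."""
    probs = outcome_prob_track(loh.y, loh.nu, params, priors.classes)
    zero = probs <= 0.0
    with np.errstate(divide="ignore"):
        logp = np.where(zero, 0.0, np.log(np.where(zero, 1.0, probs)))
    pad = np.zeros((1, len(priors.classes)))
    cum_ll = np.vstack([pad, np.cumsum(logp, axis=0)])
    n_zero = np.vstack([pad, np.cumsum(zero, axis=0)])
    cum_pi = np.vstack([pad, np.cumsum(priors.probs, axis=0)])
    return cum_ll, n_zero, cum_pi


def _log_evidence_matrix(
    loh: LOHTrack, priors: EventPriorTrack, params: EmissionParamTable
) -> np.ndarray:
    """log A(i, j) for all 0 <= i < j <= n (single-segment evidence).

    Uses cumulative per-class log-likelihoods and cumulative priors so each
    entry costs O(#classes); the candidate-segment prior is the arithmetic
    mean of the per-SNP priors over (i, j].  SNPs with zero probability under
    a class veto that class for every segment containing them (tracked with a
    cumulative count, since -inf cumulants cannot be differenced).
    """
    cum_ll, n_zero, cum_pi = _cumulants(loh, priors, params)
    if _HAVE_NUMBA:
        return _evidence_kernel(cum_ll, n_zero, cum_pi)
    n = loh.n
    idx = np.arange(n + 1)
    seglen = idx[None, :] - idx[:, None]  # j - i
    log_len = np.zeros(seglen.shape)
    np.log(seglen, out=log_len, where=seglen > 0)
    logA = np.full((n + 1, n + 1), -np.inf)
    for c in range(len(priors.classes)):
        dll = cum_ll[None, :, c] - cum_ll[:, None, c]
        dpi = cum_pi[None, :, c] - cum_pi[:, None, c]
        vetoed = (n_zero[None, :, c] - n_zero[:, None, c]) > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.log(np.maximum(dpi, 0.0)) - log_len + dll
        term = np.where((seglen > 0) & ~vetoed, term, -np.inf)
        np.logaddexp(logA, term, out=logA)
    return logA


def _dp_forward(logA: np.ndarray, k_max: int) -> np.ndarray:
    if _HAVE_NUMBA:
        return _dp_forward_kernel(logA, k_max)
    n1 = logA.shape[0]
    logL = np.full((k_max + 1, n1), -np.inf)
    logL[1] = logA[0]
    for h in range(2, k_max + 1):
        logL[h] = logsumexp(logL[h - 1][:, None] + logA, axis=0)
    return logL


def _dp_backward(logA: np.ndarray, k_max: int) -> np.ndarray:
    if _HAVE_NUMBA:
        return _dp_backward_kernel(logA, k_max)
    n1 = logA.shape[0]
    logR = np.full((k_max + 1, n1), -np.inf)
    logR[1] = logA[:, n1 - 1]
    for h in range(2, k_max + 1):
        logR[h] = logsumexp(logA + logR[h - 1][None, :], axis=1)
    return logR


# ---------------------------------------------------------------------------
# Dynamic programming
# ---------------------------------------------------------------------------

def compute_posteriors(
    loh: LOHTrack,
    priors: EventPriorTrack,
    params: EmissionParamTable,
    k_max: int = 50,
) -> BreakpointPosterior:
    """Exact posteriors P(K | y) and breakpoint probabilities p by DP.

    Forward sums L_h(j) (evidence of splitting (0, j] into h segments) and
    backward sums R_h(i) give, with the 1/k^2 prior on K and the uniform
    prior on ordered boundary sets, both the segment-number posterior and the
    marginal probability of a boundary at each interior position.  All sums
    run in log-space (log-sum-exp), so products of thousands of per-SNP
    probabilities cannot underflow.
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if priors.n != loh.n:
        raise ValidationError(
            f"prior track covers {priors.n} SNPs but LOH track has {loh.n}"
        )
    n = loh.n
    if k_max > n:
        logger.info("k_max=%d exceeds n=%d; capped", k_max, n)
        k_max = n

    logA = _log_evidence_matrix(loh, priors, params)
    logL = _dp_forward(logA, k_max)
    logR = _dp_backward(logA, k_max)

    ks = np.arange(1, k_max + 1)
    log_joint = np.array(
        [
            -2.0 * np.log(k) - _log_binom(n - 1, k - 1) + logL[k, n]
            for k in ks
        ]
    )
    log_Z = logsumexp(log_joint)
    if not np.isfinite(log_Z):
        raise ValidationError("zero total evidence: no class explains the data")
    k_post = np.exp(log_joint - log_Z)

    # Breakpoint posterior: p_i = sum_k P(K=k|y) * P(boundary at i | K=k, y).
    p = np.zeros(n - 1) if n > 1 else np.zeros(0)
    for k in range(2, k_max + 1):
        if k_post[k - 1] == 0.0 or not np.isfinite(logL[k, n]):
            continue
        h = np.arange(1, k)
        # interior positions 1..n-1 are columns 1..n-1 of logL/logR
        terms = logL[h][:, 1:n] + logR[k - h][:, 1:n]
        log_num = logsumexp(terms, axis=0)
        p += k_post[k - 1] * np.exp(log_num - logL[k, n])

    return BreakpointPosterior(
        p=p, k_posterior=k_post, log_evidence=float(log_Z), k_max=k_max
    )


# ---------------------------------------------------------------------------
# Estimators of K and the boundaries
# ---------------------------------------------------------------------------

def estimate_k_01(bp: BreakpointPosterior) -> int:
    """0-1-loss (MAP) estimate of the segment number; ties go to the smallest k."""
    return int(np.argmax(bp.k_posterior)) + 1


def boundaries_binerr(bp: BreakpointPosterior, k: int) -> np.ndarray:
    """The k-1 interior positions with the highest breakpoint posterior.

    Returns sorted 1-based positions (a boundary after SNP ``t`` closes the
    segment at index ``t``); ties are broken leftmost.
    """
    if not 1 <= k <= bp.n:
        raise ValidationError(f"k={k} out of range for n={bp.n}")
    if k - 1 > bp.p.size:
        raise ValidationError(f"cannot place {k - 1} boundaries among {bp.p.size} positions")
    if k == 1:
        return np.array([], dtype=int)
    order = np.argsort(-bp.p, kind="stable")  # stable: leftmost wins ties
    chosen = np.sort(order[: k - 1]) + 1
    return chosen


def resolve_thresholds(
    spec: PeakThresholdSpec, p: np.ndarray
) -> tuple[float, float]:
    """Resolve the (thr1, thr2) pair of the peak estimator on a given p vector.

    Rules: "005" = max(0.005, 95% quantile of p); "01" = max(0.01, 95%
    quantile); "01_90" = max(0.01, 90% quantile); "mad" = median(p) +
    3 * median absolute deviation.  thr1 groups positions into peaks, thr2
    decides which peak maxima count as significant breakpoints.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot resolve thresholds on an empty p vector")

    def one(rule) -> float:
        if isinstance(rule, (int, float)):
            v = float(rule)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"explicit threshold {v} outside [0, 1]")
            return v
        if rule == "005":
            return max(0.005, float(np.quantile(p, 0.95)))
        if rule == "01":
            return max(0.01, float(np.quantile(p, 0.95)))
        if rule == "01_90":
            return max(0.01, float(np.quantile(p, 0.90)))
        if rule == "mad":
            med = float(np.median(p))
            mad = float(np.median(np.abs(p - med)))
            return med + 3.0 * mad
        raise ValidationError(f"unknown threshold rule {rule!r}")

    return one(spec.thr1), one(spec.thr2)


def _smooth(p: np.ndarray, bandwidth: int) -> np.ndarray:
    """Symmetric moving average with half-width ``bandwidth`` (truncated at edges)."""
    if bandwidth == 0:
        return p
    win = np.ones(2 * bandwidth + 1)
    num = np.convolve(p, win, mode="same")
    den = np.convolve(np.ones_like(p), win, mode="same")
    return num / den


def find_peaks(
    p: np.ndarray, thr1: float, thr2: float, bandwidth: int = 3
) -> tuple[int, np.ndarray]:
    """Peak-based estimate of the segment number and boundary positions.

    The smoothed posterior is cut at ``thr1``: maximal runs of consecutive
    positions above it form peaks (thr1 decides which points belong to the
    same peak).  Each peak contributes the position of the maximum of the
    raw p inside it (leftmost on ties); peaks whose raw maximum falls below
    ``thr2`` are discarded as not significantly different from zero.
    Returns (k_hat, sorted 1-based positions) with k_hat = #peaks + 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return 1, np.array([], dtype=int)
    sm = _smooth(p, bandwidth)
    above = sm > thr1
    positions = []
    i = 0
    n = p.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            run = p[i:j]
            peak_pos = i + int(np.argmax(run))  # argmax is leftmost on ties
            if p[peak_pos] >= thr2:
                positions.append(peak_pos + 1)  # 1-based boundary position
            i = j
        else:
            i += 1
    t = np.array(positions, dtype=int)
    return t.size + 1, t


# ---------------------------------------------------------------------------
# Level calling
# ---------------------------------------------------------------------------

def _tie_break_key(w: int) -> tuple:
    # closest to 0 first, negative before positive on equal distance
    return (abs(w), 0 if w <= 0 else 1)


def map_segment_levels(
    loh: LOHTrack,
    boundaries: np.ndarray,
    priors: EventPriorTrack,
    params: EmissionParamTable,
    chrom: str | None = None,
) -> SegmentationResult:
    """MAP class call per segment for a fixed boundary set.

    The posterior of each segment's class is proportional to the averaged
    per-SNP prior times the single-class segment likelihood.  A numerically
    zero normalizer (all classes ruled out — typically a missed boundary
    pooling incompatible data) raises :class:`UnestimableLevelError` naming
    the segment.
    """
    interior = np.asarray(boundaries, dtype=int)
    n = loh.n
    if interior.size and (
        np.any(interior <= 0) or np.any(interior >= n) or np.any(np.diff(interior) <= 0)
    ):
        raise ValidationError(f"invalid interior boundaries {interior} for n={n}")
    full = np.concatenate(([0], interior, [n]))
    classes = priors.classes
    segments = []
    for a, b in zip(full[:-1], full[1:]):
        pi_bar = priors.probs[a:b].mean(axis=0)
        logpost = np.full(len(classes), -np.inf)
        for ci, w in enumerate(classes):
            if pi_bar[ci] > 0.0:
                logpost[ci] = np.log(pi_bar[ci]) + segment_loglik(loh, a, b, w, params)
        mx = logpost.max()
        if not np.isfinite(mx):
            raise UnestimableLevelError(chrom, int(a), int(b))
        post = np.exp(logpost - mx)
        post /= post.sum()
        candidates = [ci for ci in range(len(classes)) if logpost[ci] == mx]
        best = min(candidates, key=lambda ci: _tie_break_key(classes[ci]))
        segments.append(
            Segment(start=int(a), end=int(b), w=classes[best], posterior=post,
                    classes=classes)
        )
    return SegmentationResult(
        boundaries=full, segments=segments, classes=classes, chrom=chrom
    )


def merge_equal_levels(
    result: SegmentationResult,
    loh: LOHTrack,
    priors: EventPriorTrack,
    params: EmissionParamTable,
) -> SegmentationResult:
    """Merge adjacent segments with equal MAP class, re-deriving posteriors.

    The merged segmentation is what is reported; the raw one is retained on
    the ``raw`` attribute of the returned result.
    """
    if result.k <= 1:
        return replace(result, raw=result)
    # keep a boundary only where the MAP class changes
    ws = [s.w for s in result.segments]
    interior = [
        int(result.boundaries[i + 1])
        for i in range(len(ws) - 1)
        if ws[i] != ws[i + 1]
    ]
    merged = map_segment_levels(
        loh, np.array(interior, dtype=int), priors, params, chrom=result.chrom
    )
    return replace(merged, raw=result)


@dataclass(frozen=True)
class EngineConfig:
    """Settings of the segmentation engine."""

    k_max: int = 50
    estimator: str = "peaks"  # "binerr" | "peaks"
    thresholds: PeakThresholdSpec = field(default_factory=PeakThresholdSpec)
    merge_equal_levels: bool = True

    def __post_init__(self):
        if self.estimator not in ("binerr", "peaks"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")


def run_segmentation(
    loh: LOHTrack,
    priors: EventPriorTrack,
    params: EmissionParamTable,
    config: EngineConfig = EngineConfig(),
    chrom: str | None = None,
    bp: BreakpointPosterior | None = None,
) -> SegmentationResult:
    """Full engine pass: DP posteriors, K/boundary estimation, level calls.

    With ``estimator="binerr"`` the segment number is the 0-1-loss MAP and
    the boundaries the top-probability positions; with ``"peaks"`` both come
    from the peak finder.  A precomputed :class:`BreakpointPosterior` can be
    passed to reuse one DP across several estimators.
    """
    if bp is None:
        bp = compute_posteriors(loh, priors, params, k_max=config.k_max)
    if config.estimator == "binerr":
        k = estimate_k_01(bp)
        t = boundaries_binerr(bp, k)
    else:
        thr1, thr2 = resolve_thresholds(config.thresholds, bp.p)
        _, t = find_peaks(bp.p, thr1, thr2, config.thresholds.bandwidth)
    result = map_segment_levels(loh, t, priors, params, chrom=chrom)
    if config.merge_equal_levels:
        result = merge_equal_levels(result, loh, priors, params)
    return result
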