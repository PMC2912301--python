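"""Synthetic LOH/CN samples and error measures for benchmarking the caller.

Two generator families are provided.

* :func:`simulate_dataset` draws whole samples from the generative model
  itself: a fixed CN-profile boundary layout, per-segment priors over the
  copy-number event codes, per-SNP heterozygosity priors, and the emission
  table.  Two designs ship on a common 15-segment profile layout over
  n = 2520 SNPs (one chromosome's worth of a 250K array): peaked
  per-segment priors ("dataset A style", easy profiles) and diffuse ones
  ("dataset B style", hard boundary estimation).

* :func:`simulate_lohcn_sample` plants copy-neutral LOH and loss regions in a
  diploid background at a controlled signal-to-noise ratio — the spike-in
  design used to benchmark LOH callers.  SNR is defined as the loss-to-normal
  level shift divided by the per-SNP log2ratio noise sd.

The error measures cover the segment number (0-1, absolute, squared error),
the boundaries (binary error, sensitivity, FDR on the interior boundary
sets), the per-SNP class profile (sum 0-1 error, SSQ on the numeric codes,
per-class sensitivity/FDR) and LOH-region detection (TPR/FPR, stratified by
informative = called vs non-informative = NoCall SNPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .cn_prior import CNSegmentProfile, LevelMixtureModel, EventPriorTrack, event_prior_from_z
from .emission_model import (
    NOCALL,
    X_HET,
    X_HOM,
    EmissionParamTable,
)
from .errors import ValidationError
from .segmentation_engine import (
    EngineConfig,
    LOHTrack,
    SegmentationResult,
    compute_posteriors,
    run_segmentation,
)

logger = logging.getLogger(__name__)

#: Fixed CN-profile boundaries of the two-dataset simulation design
#: (15 segments over n = 2520 SNPs, one chromosome).
DATASET_BOUNDARIES = (
    0, 27, 31, 161, 273, 585, 633, 1006, 1050, 1054, 1309, 1607, 1754, 2100, 2432, 2520,
)

#: Per-segment prior over the copy-number event codes (-2, -1, 0, 2) of the
#: diffuse design ("dataset B"): every segment leaves substantial mass on
#: several classes, which makes the boundary estimation genuinely hard.
DATASET_B_Z_PRIORS = np.array(
    [
        # (-2,  -1,   0,   2)
        [0.3, 0.6, 0.1, 0.0],  # I
        [0.0, 0.3, 0.6, 0.1],  # II
        [0.3, 0.6, 0.1, 0.0],  # III
        [0.0, 0.3, 0.6, 0.1],  # IV
        [0.0, 0.1, 0.4, 0.5],  # V
        [0.0, 0.3, 0.6, 0.1],  # VI
        [0.3, 0.6, 0.1, 0.0],  # VII
        [0.5, 0.4, 0.1, 0.0],  # VIII
        [0.0, 0.3, 0.6, 0.1],  # IX
        [0.0, 0.1, 0.4, 0.5],  # X
        [0.3, 0.6, 0.1, 0.0],  # XI
        [0.0, 0.3, 0.6, 0.1],  # XII
        [0.0, 0.1, 0.4, 0.5],  # XIII
        [0.0, 0.3, 0.6, 0.1],  # XIV
        [0.3, 0.6, 0.1, 0.0],  # XV
    ]
)

#: Peaked design ("dataset A style"): each segment concentrates 0.9 of its
#: prior on one class (the dominant class of the corresponding diffuse-design
#: segment), so profiles are easy to recover.  This is a synthetic design
#: built for that qualitative property.
_A_DOMINANT = (-1, 0, -1, 0, 2, 0, -1, -2, 0, 2, -1, 0, 2, 0, -1)
_Z_CODES4 = (-2, -1, 0, 2)


def _peaked_priors() -> np.ndarray:
    rows = np.full((len(_A_DOMINANT), 4), 0.1 / 3)
    for i, w in enumerate(_A_DOMINANT):
        rows[i, _Z_CODES4.index(w)] = 0.9
    return rows


DATASET_A_Z_PRIORS = _peaked_priors()

#: Mapping from event code to the mixture component giving its level mean.
_CODE_TO_GROUP = {-2: "cn0", -1: "cn1", 0: "cn2", 1: "cn34", 2: "amp"}


def default_het_priors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP heterozygosity priors drawn i.i.d. from Beta(1.5, 3.5).

    A stand-in for array-annotation het frequencies (mean ~0.3, with a tail
    of nearly monomorphic SNPs); the real annotation is external data.
    """
    return rng.beta(1.5, 3.5, size=n)


def scaled_boundaries(n: int, boundaries=DATASET_BOUNDARIES) -> np.ndarray:
    """Rescale a boundary layout to ``n`` SNPs, keeping segments non-empty."""
    b = np.asarray(boundaries, dtype=float)
    out = np.round(b * n / b[-1]).astype(int)
    out[0], out[-1] = 0, n
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + 1
    if out[-1] != n:
        raise ValidationError(f"cannot fit {b.size - 1} segments into n={n}")
    return out


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated sample."""

    k0: int
    boundaries: np.ndarray  # (k0+1,) including 0 and n
    w: np.ndarray  # per-SNP true class codes
    x_normal: np.ndarray  # per-SNP normal-cell genotype codes
    seed: int
    design: str = ""

    @property
    def n(self) -> int:
        return int(self.boundaries[-1])

    def interior_boundaries(self) -> np.ndarray:
        return self.boundaries[1:-1]


def _merge_truth(per_segment_w: np.ndarray, boundaries: np.ndarray):
    """Join consecutive segments that drew the same class."""
    keep = [0]
    ws = [per_segment_w[0]]
    for i in range(1, per_segment_w.size):
        if per_segment_w[i] != ws[-1]:
            keep.append(i)
            ws.append(per_segment_w[i])
    t = [boundaries[0]] + [boundaries[i] for i in keep[1:]] + [boundaries[-1]]
    return np.array(ws), np.array(t, dtype=int)


def _emit_calls(
    rng: np.random.Generator,
    x_normal: np.ndarray,
    w: np.ndarray,
    params: EmissionParamTable,
) -> np.ndarray:
    """Draw observed calls given per-SNP genotype and class."""
    n = x_normal.size
    rows = np.empty((n, 3))
    for x, wv in {(int(a), int(b)) for a, b in zip(x_normal, w)}:
        mask = (x_normal == x) & (w == wv)
        rows[mask] = params.row(x, wv)
    cum = np.cumsum(rows, axis=1)
    u = rng.random(n)
    y = (u[:, None] >= cum).sum(axis=1)
    return np.minimum(y, 2).astype(np.int8)


def simulate_dataset(
    boundaries=DATASET_BOUNDARIES,
    z_priors: np.ndarray = DATASET_B_Z_PRIORS,
    nu: np.ndarray | None = None,
    params: EmissionParamTable | None = None,
    seed: int = 0,
    mixture: LevelMixtureModel | None = None,
    level_jitter_sd: float = 0.05,
    profile_var: float = 0.01,
    design: str = "datasetB",
):
    """Draw one sample of the two-dataset design.

    Steps: (1) normal-cell genotypes from the het priors; (2) one event code
    per profile segment from its prior, with consecutive equal draws merged
    into the truth; (3) observed calls from the emission table given genotype
    and class.  The returned CN profile keeps the fixed boundaries, with
    segment means at the mixture mean of the drawn class plus a small jitter
    (guarding against degenerate exact-threshold placement) and posterior
    variance ``profile_var``.
    """
    rng = np.random.default_rng(seed)
    b = np.asarray(boundaries, dtype=int)
    rows = np.asarray(z_priors, dtype=float)
    if rows.shape != (b.size - 1, 4):
        raise ValidationError("need one z-prior row over (-2,-1,0,2) per segment")
    if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("z-prior rows must sum to 1")
    params = params or EmissionParamTable.default()
    mixture = mixture or LevelMixtureModel.reference()
    n = int(b[-1])
    nu = default_het_priors(n, rng) if nu is None else np.asarray(nu, dtype=float)
    if nu.shape != (n,):
        raise ValidationError(f"need {n} het priors, got {nu.shape}")

    x_normal = np.where(rng.random(n) < nu, X_HET, X_HOM).astype(np.int8)
    seg_w = np.array(
        [rng.choice(_Z_CODES4, p=row) for row in rows], dtype=int
    )
    w_true = np.repeat(seg_w, np.diff(b))
    ws_merged, t_merged = _merge_truth(seg_w, b)
    y = _emit_calls(rng, x_normal, w_true, params)

    level = {c: mixture.component(g)[1] for c, g in _CODE_TO_GROUP.items() if mixture.has(g)}
    means = np.array([level[int(wseg)] for wseg in seg_w])
    means = means + rng.normal(0.0, level_jitter_sd, size=means.size)
    profile = CNSegmentProfile(
        boundaries=b, mean=means, var=np.full(means.size, profile_var)
    )
    truth = SimTruth(
        k0=ws_merged.size, boundaries=t_merged, w=w_true, x_normal=x_normal,
        seed=seed, design=design,
    )
    loh = LOHTrack(y=y, nu=nu)
    return truth, loh, profile


def simulate_lohcn_sample(
    n: int,
    regions,
    snr: float,
    nu: np.ndarray | None = None,
    params: EmissionParamTable | None = None,
    seed: int = 0,
    eps: float = 0.02,
    mixture: LevelMixtureModel | None = None,
    profile_mode: str = "noisy",
):
    """Spike-in sample: planted LOH/CN regions in a diploid background.

    ``regions`` is a list of ``(start, end, kind)`` half-open SNP spans with
    kind in {"cnloh", "loss", "gain"}.  Copy-neutral LOH regions force the
    underlying genotype to Hom with residual Het rate ``eps`` at an unchanged
    CN level; loss (gain) regions shift the level to the loss (gain) mixture
    mean.  Per-SNP raw log2ratios get Gaussian noise with
    ``sd = |loss level - normal level| / snr``.  The profile uses the true
    region boundaries, with segment means either the true levels
    (``profile_mode="oracle"``) or the empirical means of the noisy raw
    values (``"noisy"``); a full re-segmentation of the raw values is the job
    of an upstream CN segmenter and is not attempted here.
    """
    if snr <= 0:
        raise ValidationError("snr must be > 0")
    if profile_mode not in ("oracle", "noisy"):
        raise ValidationError(f"unknown profile_mode {profile_mode!r}")
    rng = np.random.default_rng(seed)
    params = params or EmissionParamTable.default()
    mixture = mixture or LevelMixtureModel.reference()
    nu = default_het_priors(n, rng) if nu is None else np.asarray(nu, dtype=float)

    spans = sorted((int(s), int(e), kind) for s, e, kind in regions)
    last = 0
    for s, e, kind in spans:
        if s < last or e > n or e <= s:
            raise ValidationError(f"invalid/overlapping region ({s}, {e}] {kind!r}")
        if kind not in ("cnloh", "loss", "gain"):
            raise ValidationError(f"unknown region kind {kind!r}")
        last = e

    normal_level = mixture.component("cn2")[1]
    loss_level = mixture.component("cn1")[1]
    gain_level = mixture.component("cn34")[1]
    noise_sd = abs(loss_level - normal_level) / snr

    x_normal = np.where(rng.random(n) < nu, X_HET, X_HOM).astype(np.int8)
    w_true = np.zeros(n, dtype=int)
    level = np.full(n, normal_level)
    genotype = x_normal.copy()
    for s, e, kind in spans:
        if kind == "cnloh":
            w_true[s:e] = -3
            genotype[s:e] = np.where(rng.random(e - s) < eps, X_HET, X_HOM)
        elif kind == "loss":
            w_true[s:e] = -1
            level[s:e] = loss_level
        else:
            w_true[s:e] = 1
            level[s:e] = gain_level

    # cnloh emits via the normal-CN rows of the forced genotype; loss/gain via
    # their class rows given the normal-cell genotype.
    w_emit = np.where(w_true == -3, 0, w_true)
    y = _emit_calls(rng, np.where(w_true == -3, genotype, x_normal), w_emit, params)

    raw = level + rng.normal(0.0, noise_sd, size=n)
    cuts = sorted({0, n, *[s for s, _, _ in spans], *[e for _, e, _ in spans]})
    b = np.array(cuts, dtype=int)
    seg_means = []
    seg_vars = []
    for a, c in zip(b[:-1], b[1:]):
        if profile_mode == "oracle":
            seg_means.append(level[a])
        else:
            seg_means.append(float(np.mean(raw[a:c])))
        seg_vars.append(noise_sd**2 / (c - a))
    profile = CNSegmentProfile(
        boundaries=b, mean=np.array(seg_means), var=np.array(seg_vars), raw=raw
    )

    seg_w = np.array([w_true[a] for a in b[:-1]])
    ws_merged, t_merged = _merge_truth(seg_w, b)
    truth = SimTruth(
        k0=ws_merged.size, boundaries=t_merged, w=w_true, x_normal=x_normal,
        seed=seed, design=f"spikein-snr{snr}",
    )
    return truth, LOHTrack(y=y, nu=nu), profile


# ---------------------------------------------------------------------------
# Error measures
# ---------------------------------------------------------------------------

#: Classes counted as LOH for the TPR/FPR convention (physical loss,
#: homozygous deletion, and copy-neutral LOH all abolish heterozygosity).
LOH_CLASSES = (-3, -2, -1)


@dataclass(frozen=True)
class MetricsReport:
    """Error measures comparing an estimated profile with the truth."""

    k_err_01: int
    k_err_abs: int
    k_err_sq: int
    boundary_binary_error: float
    boundary_sensitivity: float
    boundary_fdr: float
    sum_01_error: int
    ssq: float
    class_sensitivity: dict = field(default_factory=dict)
    class_fdr: dict = field(default_factory=dict)
    loh_tpr: float = float("nan")
    loh_fpr: float = float("nan")
    loh_tpr_informative: float = float("nan")
    loh_fpr_informative: float = float("nan")
    loh_tpr_noninformative: float = float("nan")
    loh_fpr_noninformative: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def _boundary_match(est: np.ndarray, true: np.ndarray, window: int):
    """Count matched estimated boundaries (greedy nearest within +/- window)."""
    if window == 0:
        hits = np.intersect1d(est, true)
        return hits.size
    true_left = list(true)
    matched = 0
    for t in est:
        if not true_left:
            break
        dists = [abs(t - u) for u in true_left]
        j = int(np.argmin(dists))
        if dists[j] <= window:
            matched += 1
            true_left.pop(j)
    return matched


def evaluate_estimation(
    truth: SimTruth,
    result: SegmentationResult,
    loh: LOHTrack | None = None,
    boundary_window: int = 0,
) -> MetricsReport:
    """All error measures for one (truth, estimate) pair.

    Boundary sensitivity is the fraction of true interior boundaries that
    were found, FDR the fraction of estimated ones that are false; matching
    is exact by default (``boundary_window`` allows a +/- tolerance).  The
    boundary binary error is the normalized Hamming distance between the
    interior-boundary indicator vectors.  Profile errors compare per-SNP
    numeric class codes.  LOH TPR/FPR need the observed track to stratify
    SNPs into informative (called) and non-informative (NoCall).
    """
    if truth.n != result.n:
        raise ValidationError(
            f"truth covers {truth.n} SNPs, result covers {result.n}"
        )
    k_hat, k0 = result.k, truth.k0
    est_t = result.interior_boundaries()
    true_t = truth.interior_boundaries()

    matched = _boundary_match(est_t, true_t, boundary_window)
    n = truth.n
    ind_est = np.zeros(n - 1, dtype=bool)
    ind_true = np.zeros(n - 1, dtype=bool)
    ind_est[est_t - 1] = True
    ind_true[true_t - 1] = True
    binary_err = float(np.mean(ind_est != ind_true)) if n > 1 else 0.0

    w_hat = result.per_snp_classes()
    w_true = truth.w
    sum01 = int(np.sum(w_hat != w_true))
    ssq = float(np.sum((w_hat.astype(float) - w_true.astype(float)) ** 2))

    class_sens: dict[int, float] = {}
    class_fdr: dict[int, float] = {}
    for c in sorted(set(np.unique(w_true)) | set(np.unique(w_hat))):
        tp = int(np.sum((w_true == c) & (w_hat == c)))
        class_sens[int(c)] = _rate(tp, int(np.sum(w_true == c)))
        class_fdr[int(c)] = _rate(int(np.sum((w_hat == c) & (w_true != c))),
                                  int(np.sum(w_hat == c)))

    loh_kwargs: dict[str, float] = {}
    true_loh = np.isin(w_true, LOH_CLASSES)
    est_loh = np.isin(w_hat, LOH_CLASSES)
    loh_kwargs["loh_tpr"] = _rate(int(np.sum(true_loh & est_loh)), int(true_loh.sum()))
    loh_kwargs["loh_fpr"] = _rate(int(np.sum(~true_loh & est_loh)), int((~true_loh).sum()))
    if loh is not None:
        informative = loh.y != NOCALL
        for name, stratum in (("informative", informative), ("noninformative", ~informative)):
            tl, el = true_loh[stratum], est_loh[stratum]
            loh_kwargs[f"loh_tpr_{name}"] = _rate(int(np.sum(tl & el)), int(tl.sum()))
            loh_kwargs[f"loh_fpr_{name}"] = _rate(int(np.sum(~tl & el)), int((~tl).sum()))

    return MetricsReport(
        k_err_01=int(k_hat != k0),
        k_err_abs=abs(k_hat - k0),
        k_err_sq=(k_hat - k0) ** 2,
        boundary_binary_error=binary_err,
        boundary_sensitivity=_rate(matched, true_t.size),
        boundary_fdr=_rate(est_t.size - matched, est_t.size),
        sum_01_error=sum01,
        ssq=ssq,
        class_sensitivity=class_sens,
        class_fdr=class_fdr,
        **loh_kwargs,
    )


# ---------------------------------------------------------------------------
# Study harnesses
# ---------------------------------------------------------------------------

def estimator_comparison_study(
    n_samples: int = 50,
    n: int = 2520,
    seed: int = 0,
    k_max: int = 50,
    z_priors: np.ndarray = DATASET_B_Z_PRIORS,
    thresholds=None,
    params: EmissionParamTable | None = None,
):
    """Compare the BinErr and PeakMax estimator pairs on dataset-B-style draws.

    Each sample is generated and then segmented with both estimator pairs
    from a single DP pass (the Z priors used for inference are the generating
    per-segment priors, the design's stated convention).  Returns a
    dict of per-estimator mean metrics plus the per-sample reports.
    """
    from .segmentation_engine import PeakThresholdSpec

    params = params or EmissionParamTable.default()
    thresholds = thresholds or PeakThresholdSpec()
    boundaries = scaled_boundaries(n) if n != DATASET_BOUNDARIES[-1] else np.asarray(
        DATASET_BOUNDARIES
    )
    priors = event_prior_from_z(z_priors, boundaries, model=1)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_samples)

    reports: dict[str, list[MetricsReport]] = {"binerr": [], "peaks": []}
    for s in seeds:
        truth, loh, _ = simulate_dataset(
            boundaries=boundaries, z_priors=z_priors, params=params, seed=int(s)
        )
        bp = compute_posteriors(loh, priors, params, k_max=k_max)
        for est in ("binerr", "peaks"):
            cfg = EngineConfig(k_max=k_max, estimator=est, thresholds=thresholds)
            result = run_segmentation(loh, priors, params, cfg, bp=bp)
            reports[est].append(evaluate_estimation(truth, result, loh))

    def _mean(est, attr):
        vals = [getattr(r, attr) for r in reports[est]]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    summary = {
        est: {
            attr: _mean(est, attr)
            for attr in (
                "boundary_sensitivity", "boundary_fdr", "boundary_binary_error",
                "sum_01_error", "ssq", "k_err_abs",
            )
        }
        for est in ("binerr", "peaks")
    }
    return summary, reports


def discrimination_study(
    n_reps: int = 100,
    seed: int = 0,
    n: int = 200,
    region: tuple[int, int] = (75, 125),
    snr: float = 5.0,
    p_upd: float = 1e-4,
    k_max: int = 20,
    eps: float = 0.0,
    params: EmissionParamTable | None = None,
):
    """Copy-neutral LOH vs loss discrimination on planted homozygous runs.

    Each replicate plants one all-Hom run (underlying genotype homozygous at
    every SNP; the observed calls still carry the normal genotyping error
    and NoCall rate) whose CN level sits either at the normal mixture mean
    or at the loss mean, and asks the model-2 caller for the class of the
    run's SNPs.  A replicate is correct if the majority of the
    run is called IBD/UPD (-3) at the normal level and loss (-1) at the loss
    level.  Returns the fraction of correct replicates (both conditions must
    hold) and the per-condition fractions.
    """
    from .cn_prior import build_event_prior_track

    params = params or EmissionParamTable.default()
    mixture = LevelMixtureModel.reference()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    s0, s1 = region
    cfg = EngineConfig(k_max=k_max, estimator="peaks")

    correct_upd = 0
    correct_loss = 0
    both = 0
    for s in seeds:
        ok = []
        for kind, target in (("cnloh", -3), ("loss", -1)):
            truth, loh, profile = simulate_lohcn_sample(
                n, [(s0, s1, "cnloh")], snr=snr, seed=int(s), params=params,
                mixture=mixture, eps=eps,
            )
            if kind == "loss":
                # same homozygous-run observation model, CN level moved to
                # the loss mean.
                mean = profile.mean.copy()
                loss_shift = mixture.component("cn1")[1] - mixture.component("cn2")[1]
                seg = np.searchsorted(profile.boundaries, s0, side="right") - 1
                mean[seg] += loss_shift
                profile = CNSegmentProfile(
                    boundaries=profile.boundaries, mean=mean, var=profile.var
                )
            priors = build_event_prior_track(profile, mixture, model=2, p_upd=p_upd)
            result = run_segmentation(loh, priors, params, cfg)
            called = result.per_snp_classes()[s0:s1]
            ok.append(np.mean(called == target) > 0.5)
        correct_upd += ok[0]
        correct_loss += ok[1]
        both += ok[0] and ok[1]
    return {
        "fraction_correct": both / n_reps,
        "fraction_correct_upd": correct_upd / n_reps,
        "fraction_correct_loss": correct_loss / n_reps,
        "n_reps": n_reps,
    }
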