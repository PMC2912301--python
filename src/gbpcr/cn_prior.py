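"""Aberration-class priors derived from the segmented copy-number profile.

The segmented log2ratio profile (an mBPCR-style output: segment boundaries
plus the posterior mean and variance of each segment's level) is turned into
a per-SNP prior over discrete aberration classes in three steps:

1. the estimated segment levels, pooled over a dataset and weighted by
   segment length, are fitted with a mixture of normal components whose modes
   correspond to copy-number groups (CN=1, CN=2, CN=3-4, optionally CN=0 and
   CN>4);
2. the component parameters induce a partition of the log2ratio axis into
   intervals, one per copy-number event code (-2, -1, 0, 1, 2) — the
   continuous-to-discrete map;
3. for each profile segment, the level is treated as a normal random variable
   with the profile's posterior mean and variance, and the prior mass of each
   event code is the Gaussian mass of its interval.  Model 2 then splits the
   normal-CN mass between "normal" and "IBD/UPD" using the prior IBD/UPD
   probability ``p_upd``; Model 3 additionally keeps the gain code separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Canonical class sets.  Model 1 works on copy-number events only; Model 2
#: adds the IBD/UPD class (-3); Model 3 splits normal (0) and gain (1).
MODEL1_CLASSES = (-2, -1, 0, 2)
MODEL2_CLASSES = (-3, -2, -1, 0, 2)
MODEL3_CLASSES = (-3, -2, -1, 0, 1, 2)

#: Event codes of the continuous-to-discrete interval map, in level order.
MAP_CODES = (-2, -1, 0, 1, 2)

#: Mixture component labels in copy-number order.
CN_GROUP_ORDER = ("cn0", "cn1", "cn2", "cn34", "amp")


@dataclass(frozen=True)
class CNSegmentProfile:
    """A segmented log2ratio profile over ``n`` SNPs of one chromosome.

    Segments are half-open spans ``(boundaries[p-1], boundaries[p]]`` in
    SNP-index space, with ``boundaries[0] = 0`` and ``boundaries[-1] = n``.
    ``mean``/``var`` are the posterior mean and variance of each segment's
    level, as produced by the upstream copy-number segmentation.
    """

    boundaries: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    chrom: str | None = None
    raw: np.ndarray | None = None  # optional per-SNP raw log2ratios

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=int)
        m = np.asarray(self.mean, dtype=float)
        v = np.asarray(self.var, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValidationError("profile needs at least one segment")
        if b[0] != 0:
            raise ValidationError(f"profile boundaries must start at 0, got {b[0]}")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("profile boundaries must be strictly increasing")
        k = b.size - 1
        if m.shape != (k,) or v.shape != (k,):
            raise ValidationError(
                f"profile with {k} segments needs {k} means/variances, "
                f"got {m.shape}/{v.shape}"
            )
        if np.any(v < 0):
            raise ValidationError("segment level variances must be >= 0")
        if self.raw is not None and np.asarray(self.raw).shape != (b[-1],):
            raise ValidationError("raw log2ratios must have one value per SNP")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "var", v)

    @property
    def n(self) -> int:
        return int(self.boundaries[-1])

    @property
    def n_segments(self) -> int:
        return self.boundaries.size - 1

    def segment_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def snp_segment_index(self) -> np.ndarray:
        """Per-SNP index of the containing segment."""
        return np.repeat(np.arange(self.n_segments), self.segment_lengths())

    def snp_means(self) -> np.ndarray:
        """Per-SNP segment level (the CN-only view of the profile)."""
        return np.repeat(self.mean, self.segment_lengths())


@dataclass(frozen=True)
class LevelMixtureModel:
    """Normal-mixture model of estimated log2ratio levels.

    Components are stored sorted by mean and labeled with their copy-number
    group.  The component with the largest weight is anchored to ``cn2``
    (normal copy number dominates a genome); neighbours take the adjacent
    group labels by rank.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    fitted_on: str = "unspecified"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (len(self.labels) == w.size == m.size == s.size):
            raise ValidationError("mixture fields must have equal length")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must be >= 0 and sum to 1")
        if np.any(s <= 0):
            raise ValidationError("mixture sds must be > 0")
        if np.any(np.diff(m) <= 0):
            raise ValidationError("component means must be strictly increasing")
        order = [CN_GROUP_ORDER.index(l) for l in self.labels]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValidationError(
                f"labels must be distinct and in copy-number order, got {self.labels}"
            )
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    def has(self, label: str) -> bool:
        return label in self.labels

    def component(self, label: str) -> tuple[float, float, float]:
        """(weight, mean, sd) of the named copy-number group."""
        try:
            i = self.labels.index(label)
        except ValueError:
            raise ValidationError(f"mixture has no {label!r} component") from None
        return float(self.weights[i]), float(self.means[i]), float(self.sds[i])

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LevelMixtureModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        comps = sorted(doc["components"], key=lambda c: c["mean"])
        return cls(
            labels=tuple(c["label"] for c in comps),
            weights=np.array([c["weight"] for c in comps], dtype=float),
            means=np.array([c["mean"] for c in comps], dtype=float),
            sds=np.array([c["sd"] for c in comps], dtype=float),
            fitted_on=str(doc.get("fitted_on", "unspecified")),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "fitted_on": self.fitted_on,
            "components": [
                {"label": l, "weight": float(w), "mean": float(m), "sd": float(s)}
                for l, w, m, s in zip(self.labels, self.weights, self.means, self.sds)
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def reference(cls) -> "LevelMixtureModel":
        """The packaged reference mixture (idealized log2(CN/2) positions)."""
        with resources.as_file(
            resources.files("gbpcr.data") / "reference_mixture.yaml"
        ) as p:
            return cls.from_yaml(p)


def fit_level_mixture(
    levels,
    lengths=None,
    n_components: int = 3,
    init_means=None,
    max_iter: int = 500,
    tol: float = 1e-10,
    fitted_on: str = "unspecified",
) -> LevelMixtureModel:
    """Weighted EM fit of a 1-D normal mixture to estimated segment levels.

    ``lengths`` weight each level by its segment length (pooling a dataset's
    levels is the intended use).  The fit is deterministic given
    ``init_means``; when omitted, components are initialized on weighted
    quantiles of the levels.  Degenerate components have their sd floored at
    1e-3 with a warning.
    """
    x = np.asarray(levels, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 levels to fit a mixture")
    if not 2 <= n_components <= 5:
        raise ValidationError("component count must be between 2 and 5")
    if np.unique(x).size < n_components:
        raise ValidationError(
            f"only {np.unique(x).size} distinct levels for {n_components} components"
        )
    obs_w = np.ones_like(x) if lengths is None else np.asarray(lengths, dtype=float)
    if obs_w.shape != x.shape or np.any(obs_w <= 0):
        raise ValidationError("lengths must be positive and match levels")
    obs_w = obs_w / obs_w.sum()

    if init_means is None:
        qs = np.linspace(0.1, 0.9, n_components)
        order = np.argsort(x)
        cum = np.cumsum(obs_w[order])
        mu = np.interp(qs, cum / cum[-1], x[order])
        # nudge coincident initial means apart
        for i in range(1, n_components):
            if mu[i] <= mu[i - 1]:
                mu[i] = mu[i - 1] + 1e-6
    else:
        mu = np.sort(np.asarray(init_means, dtype=float))
        if mu.size != n_components:
            raise ValidationError("init_means length must equal n_components")
    pi = np.full(n_components, 1.0 / n_components)
    spread = max(np.sqrt(np.average((x - np.average(x, weights=obs_w)) ** 2, weights=obs_w)), 1e-3)
    sd = np.full(n_components, spread)

    sd_floor = 1e-3
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        logp = norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(pi[None, :])
        mx = logp.max(axis=1, keepdims=True)
        resp = np.exp(logp - mx)
        tot = resp.sum(axis=1, keepdims=True)
        resp /= tot
        ll = float(np.sum(obs_w * (np.log(tot[:, 0]) + mx[:, 0])))
        # M step (observation-weighted)
        r = resp * obs_w[:, None]
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        pi = nk / nk.sum()
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if np.any(sd < sd_floor):
            logger.warning("EM produced near-degenerate component sd; flooring at %g", sd_floor)
            sd = np.maximum(sd, sd_floor)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll

    order = np.argsort(mu)
    pi, mu, sd = pi[order], mu[order], sd[order]
    labels = _assign_labels(pi, n_components)
    return LevelMixtureModel(
        labels=labels, weights=pi, means=mu, sds=sd, fitted_on=fitted_on
    )


def _assign_labels(weights: np.ndarray, n_components: int) -> tuple[str, ...]:
    """Label mean-sorted components by rank around the heaviest one (= cn2)."""
    anchor = int(np.argmax(weights))
    below = anchor            # components below cn2
    above = n_components - anchor - 1
    if below > 2 or above > 2:
        raise ValidationError(
            "cannot label mixture: more than two components on one side of "
            "the dominant (normal-CN) component"
        )
    lower = ["cn1", "cn0"][:below][::-1]
    upper = ["cn34", "amp"][:above]
    return tuple(lower + ["cn2"] + upper)


@dataclass(frozen=True)
class EventIntervalMap:
    """Partition of the log2ratio axis into intervals for codes (-2,-1,0,1,2).

    ``thresholds`` are the 4 strictly increasing cut points; a level ``m``
    classifies as the code of the interval containing it (intervals are
    half-open to the left: code jumps at ``m > threshold``).
    """

    thresholds: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.shape != (4,) or np.any(np.diff(t) <= 0):
            raise ValidationError("need 4 strictly increasing thresholds")
        object.__setattr__(self, "thresholds", t)

    def classify(self, m):
        """Event code(s) of level value(s) ``m``."""
        idx = np.searchsorted(self.thresholds, np.asarray(m, dtype=float), side="left")
        codes = np.asarray(MAP_CODES)[idx]
        return codes if codes.ndim else int(codes)


def _crossing(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Equal-Mahalanobis point between two adjacent components."""
    return (mu1 * sd2 + mu2 * sd1) / (sd1 + sd2)


def event_interval_map(mix: LevelMixtureModel) -> EventIntervalMap:
    """Build the continuous-to-discrete map from a fitted level mixture.

    Interior thresholds sit at the equal-Mahalanobis intersection of adjacent
    components.  Without a fitted cn0 (homozygous-deletion) component the
    -2/-1 threshold falls back to ``mean(cn1) - 3 sd(cn1)``; without an amp
    component the 1/2 threshold falls back to ``mean(cn34) + 3 sd(cn34)``.
    """
    for needed in ("cn1", "cn2", "cn34"):
        if not mix.has(needed):
            raise ValidationError(f"interval map requires a {needed!r} component")
    _, mu1, s1 = mix.component("cn1")
    _, mu2, s2 = mix.component("cn2")
    _, mu34, s34 = mix.component("cn34")
    if mix.has("cn0"):
        _, mu0, s0 = mix.component("cn0")
        thr_minus2 = _crossing(mu0, s0, mu1, s1)
    else:
        thr_minus2 = mu1 - 3.0 * s1
    if mix.has("amp"):
        _, mua, sa = mix.component("amp")
        thr_plus2 = _crossing(mu34, s34, mua, sa)
    else:
        thr_plus2 = mu34 + 3.0 * s34
    thresholds = np.array(
        [thr_minus2, _crossing(mu1, s1, mu2, s2), _crossing(mu2, s2, mu34, s34), thr_plus2]
    )
    return EventIntervalMap(thresholds=thresholds)


def z_prior_for_segment(
    mix: LevelMixtureModel, mu: float, rho: float, merge_gain: bool = False
) -> np.ndarray:
    """Prior over copy-number event codes for a segment with level N(mu, rho).

    Each code's probability is the Gaussian mass of its interval under the
    posterior law of the segment level; ``rho = 0`` degenerates to a point
    mass on the classified mean.  With ``merge_gain`` the normal and gain
    codes are pooled (Model 1/2 view), returning a vector over (-2,-1,0,2).
    """
    if rho < 0:
        raise ValidationError("segment level variance must be >= 0")
    imap = event_interval_map(mix)
    if rho == 0.0:
        probs = np.zeros(len(MAP_CODES))
        probs[MAP_CODES.index(imap.classify(mu))] = 1.0
    else:
        sd = np.sqrt(rho)
        cdf = norm.cdf(imap.thresholds, loc=mu, scale=sd)
        edges = np.concatenate(([0.0], cdf, [1.0]))
        probs = np.diff(edges)
    if merge_gain:
        merged = np.array([probs[0], probs[1], probs[2] + probs[3], probs[4]])
        return merged
    return probs


@dataclass(frozen=True)
class EventPriorTrack:
    """Per-SNP prior over aberration classes for one chromosome.

    ``classes`` is the active class set of the model level; ``probs`` has one
    row per SNP, each summing to 1, with the IBD/UPD mass bounded by
    ``p_upd``.
    """

    classes: tuple[int, ...]
    probs: np.ndarray
    model: int = 1
    p_upd: float = 0.0

    def __post_init__(self):
        pr = np.asarray(self.probs, dtype=float)
        if pr.ndim != 2 or pr.shape[1] != len(self.classes):
            raise ValidationError("probs must be (n_snps, n_classes)")
        if np.any(pr < 0):
            raise ValidationError("prior probabilities must be >= 0")
        if np.any(np.abs(pr.sum(axis=1) - 1.0) > 1e-12):
            raise ValidationError("per-SNP priors must sum to 1 within 1e-12")
        if -3 in self.classes:
            upd = pr[:, self.classes.index(-3)]
            if np.any(upd > self.p_upd + 1e-12):
                raise ValidationError("IBD/UPD prior mass exceeds p_upd")
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "probs", pr)

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def slice(self, start: int, stop: int) -> "EventPriorTrack":
        return EventPriorTrack(
            classes=self.classes, probs=self.probs[start:stop],
            model=self.model, p_upd=self.p_upd,
        )


def _model_classes(model: int) -> tuple[int, ...]:
    if model == 1:
        return MODEL1_CLASSES
    if model == 2:
        return MODEL2_CLASSES
    if model == 3:
        return MODEL3_CLASSES
    raise ValidationError(f"model must be 1, 2 or 3, got {model}")


def event_prior_from_z(
    z_prior_rows: np.ndarray,
    boundaries: np.ndarray,
    model: int,
    p_upd: float = 0.0,
    n: int | None = None,
) -> EventPriorTrack:
    """Expand per-segment copy-number-event priors into a per-SNP class prior.

    ``z_prior_rows`` has one row per profile segment: over (-2,-1,0,2) with
    the normal and gain codes merged for Models 1-2, or over (-2,-1,0,1,2)
    for Model 3.  Model 2 splits the normal mass into IBD/UPD (``p_upd``
    fraction) and normal; Model 3 applies the split to the normal code only,
    leaving the gain mass untouched (an IBD/UPD event exists only at normal
    copy number).
    """
    if not 0.0 <= p_upd <= 1.0:
        raise ValidationError("p_upd must lie in [0, 1]")
    rows = np.asarray(z_prior_rows, dtype=float)
    b = np.asarray(boundaries, dtype=int)
    if rows.ndim != 2 or rows.shape[0] != b.size - 1:
        raise ValidationError("need one z-prior row per profile segment")
    if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("z-prior rows must sum to 1")
    n_total = int(b[-1]) if n is None else n
    if int(b[-1]) != n_total:
        raise ValidationError(
            f"profile covers {int(b[-1])} SNPs but the track has {n_total}"
        )
    classes = _model_classes(model)

    if model in (1, 2):
        if rows.shape[1] == 5:  # unmerged rows: pool normal and gain
            rows = np.column_stack(
                [rows[:, 0], rows[:, 1], rows[:, 2] + rows[:, 3], rows[:, 4]]
            )
        if rows.shape[1] != 4:
            raise ValidationError("models 1-2 need z-priors over (-2,-1,0,2)")
    else:
        if rows.shape[1] != 5:
            raise ValidationError("model 3 needs z-priors over (-2,-1,0,1,2)")

    if model == 1:
        seg = rows
    elif model == 2:
        seg = np.column_stack(
            [p_upd * rows[:, 2], rows[:, 0], rows[:, 1], (1.0 - p_upd) * rows[:, 2], rows[:, 3]]
        )
    else:
        seg = np.column_stack(
            [
                p_upd * rows[:, 2],
                rows[:, 0],
                rows[:, 1],
                (1.0 - p_upd) * rows[:, 2],
                rows[:, 3],
                rows[:, 4],
            ]
        )
    # exact renormalization guard (rows already sum to 1 up to fp error)
    seg = seg / seg.sum(axis=1, keepdims=True)
    per_snp = np.repeat(seg, np.diff(b), axis=0)
    return EventPriorTrack(classes=classes, probs=per_snp, model=model, p_upd=p_upd)


def build_event_prior_track(
    profile: CNSegmentProfile,
    mix: LevelMixtureModel,
    model: int = 3,
    p_upd: float = 1e-4,
) -> EventPriorTrack:
    """Per-SNP aberration-class prior from a segmented CN profile.

    Each SNP inherits the prior of its containing profile segment, computed
    from the Gaussian posterior of the segment level through the interval
    map, then split across classes according to the model level.
    """
    merge = model in (1, 2)
    rows = np.array(
        [
            z_prior_for_segment(mix, m, r, merge_gain=merge)
            for m, r in zip(profile.mean, profile.var)
        ]
    )
    return event_prior_from_z(rows, profile.boundaries, model=model, p_upd=p_upd)
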