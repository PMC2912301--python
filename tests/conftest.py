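"""Shared fixtures and the brute-force enumeration oracle for the DP engine."""

from itertools import combinations
from math import comb, exp

import numpy as np
import pytest

from gbpcr import EmissionParamTable, LOHTrack
from gbpcr.cn_prior import EventPriorTrack
from gbpcr.segmentation_engine import segment_loglik


@pytest.fixture(scope="session")
def default_params() -> EmissionParamTable:
    return EmissionParamTable.default()


def random_emission_table(rng: np.random.Generator) -> EmissionParamTable:
    """A valid random emission table (Dirichlet rows)."""
    return EmissionParamTable(
        cond=rng.dirichlet(np.ones(3), size=(2, 4)),
        upd_row=rng.dirichlet(np.ones(3)),
    )


def random_instance(rng: np.random.Generator, n: int, classes=(-3, -2, -1, 0, 2)):
    """Random (track, priors, params) triple for oracle comparisons."""
    params = random_emission_table(rng)
    probs = rng.dirichlet(np.ones(len(classes)), size=n)
    priors = EventPriorTrack(
        classes=classes, probs=probs, model=2, p_upd=1.0
    )
    loh = LOHTrack(y=rng.integers(0, 3, n), nu=rng.random(n))
    return loh, priors, params


def brute_force_posteriors(loh, priors, params, k_max):
    """Exhaustive enumeration over all segmentations (oracle for the DP).

    Sums the joint probability of every (k, boundary set) pair directly,
    returning P(K | y) and the per-position breakpoint posterior.
    """
    n = loh.n

    def evidence(i, j):
        pi = priors.probs[i:j].mean(axis=0)
        return sum(
            pi[ci] * exp(segment_loglik(loh, i, j, w, params))
            for ci, w in enumerate(priors.classes)
        )

    kmax = min(k_max, n)
    joint = np.zeros(kmax)
    pmass = np.zeros(max(n - 1, 0))
    for k in range(1, kmax + 1):
        w_k = 1.0 / k**2 / comb(n - 1, k - 1)
        for bounds in combinations(range(1, n), k - 1):
            full = (0,) + bounds + (n,)
            prob = w_k
            for a, b in zip(full[:-1], full[1:]):
                prob *= evidence(a, b)
            joint[k - 1] += prob
            for t in bounds:
                pmass[t - 1] += prob
    total = joint.sum()
    return joint / total, pmass / total


def brute_force_class_posterior(loh, priors, params, a, b):
    """Direct class posterior of the single segment (a, b]."""
    pi = priors.probs[a:b].mean(axis=0)
    post = np.array(
        [
            pi[ci] * exp(segment_loglik(loh, a, b, w, params))
            for ci, w in enumerate(priors.classes)
        ]
    )
    return post / post.sum()
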