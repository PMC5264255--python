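"""One-dimensional weighted Gaussian-mixture fitting by EM.

Used for two things: insert-size estimation from same-contig read pairs and
the sequencing-depth model of seed contigs (where observations are weighted
by contig length). The number of components K is chosen among {1, 2, 3} by
BIC; initialization is deterministic (means at quantiles), so fits are
reproducible without any random source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureModel:
    """Fitted 1-D Gaussian mixture; ``dominant_index`` is the max-weight component."""

    components: list  # of (weight, mean, sd)
    dominant_index: int
    log_likelihood: float
    bic: float
    n_components: int

    @property
    def dominant(self):
        return self.components[self.dominant_index]


def _em_fit(x, w, k, sd_floor, max_iter, tol):
    n = len(x)
    wsum = w.sum()
    # deterministic init: means at evenly spaced weighted quantiles
    order = np.argsort(x)
    cw = np.cumsum(w[order]) / wsum
    qs = (np.arange(k) + 0.5) / k
    means = np.array([x[order][np.searchsorted(cw, q)] for q in qs], dtype=float)
    overall_sd = max(np.sqrt(np.average((x - np.average(x, weights=w)) ** 2, weights=w)), sd_floor)
    # start components narrow so well-separated modes are not merged
    sds = np.full(k, max(overall_sd / (2 * k), sd_floor))
    pis = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        logp = (
            np.log(pis)[None, :]
            - 0.5 * _LOG_2PI
            - np.log(sds)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        resp = np.exp(logp - lse[:, None])
        ll = float(np.sum(w * lse))
        # M step (weighted)
        rw = resp * w[:, None]
        nk = rw.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        pis = nk / wsum
        means = (rw * x[:, None]).sum(axis=0) / nk
        var = (rw * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll

    n_params = 3 * k - 1
    bic = -2.0 * prev_ll + n_params * np.log(n)
    comps = [(float(pis[i]), float(means[i]), float(sds[i])) for i in range(k)]
    return comps, prev_ll, bic


def fit_mixture(
    values,
    weights=None,
    max_k: int = 3,
    sd_floor: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MixtureModel:
    """Fit Gaussian mixtures with K = 1..max_k and keep the best-BIC model."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit a mixture to zero observations")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match values")
    # normalize to mean 1 so the log-likelihood (and hence BIC) stays on the
    # per-observation scale regardless of the weight units
    w = w * (len(w) / w.sum())

    best = None
    for k in range(1, max_k + 1):
        if k > len(np.unique(x)):
            break
        comps, ll, bic = _em_fit(x, w, k, sd_floor, max_iter, tol)
        if best is None or bic < best[2]:
            best = (comps, ll, bic, k)
    comps, ll, bic, k = best
    dominant = int(np.argmax([c[0] for c in comps]))
    return MixtureModel(comps, dominant, ll, bic, k)
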