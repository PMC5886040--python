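"""Samplers for orthant-truncated multivariate normals.

The half-ridge posterior is a Gaussian restricted to the orthant fixed by
the known cue directions.  The workhorse here is a component-wise Gibbs
sampler whose full conditionals are exact univariate truncated normals;
the inner loop is numba-compiled because a prior-strength sweep fits
thousands of posteriors.  A plain rejection sampler (draw from the
untruncated Gaussian, keep draws inside the orthant) is provided as an
independent oracle for low-dimensional cross-checks.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["gibbs_orthant_normal", "rejection_orthant_normal", "split_rhat"]


@njit(cache=False)
def _rtnorm_lower(a: float) -> float:
    """Draw Z ~ N(0,1) conditional on Z >= a.

    Naive resampling for a below ~0.3 (acceptance >= 0.38); for larger a,
    the translated-exponential rejection scheme, which stays efficient
    arbitrarily far into the tail.
    """
    if a < 0.3:
        while True:
            z = np.random.normal()
            if z >= a:
                return z
    lam = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        z = a - math.log(np.random.random()) / lam
        d = z - lam
        if math.log(np.random.random()) <= -0.5 * d * d:
            return z


@njit(cache=False)
def _gibbs_kernel(mu, prec, directions, n_total, seed, w0):
    np.random.seed(seed)
    m = mu.shape[0]
    w = w0.copy()
    out = np.empty((n_total, m))
    for t in range(n_total):
        for j in range(m):
            cvar = 1.0 / prec[j, j]
            csd = math.sqrt(cvar)
            r = 0.0
            for k in range(m):
                if k != j:
                    r += prec[j, k] * (w[k] - mu[k])
            cmean = mu[j] - cvar * r
            d = directions[j]
            # u = d*w_j ~ N(d*cmean, cvar) conditioned on u >= 0
            a = -(d * cmean) / csd
            u = d * cmean + csd * _rtnorm_lower(a)
            w[j] = d * u
        out[t] = w
    return out


def gibbs_orthant_normal(mu, cov, directions, n_draws: int, burn_in: int,
                         seed: int, thin: int = 1) -> np.ndarray:
    """Gibbs-sample N(mu, cov) restricted to {w : direction_j * w_j >= 0}.

    Returns the retained draws, shape (n_draws, m); ``burn_in`` initial
    sweeps are discarded and every ``thin``-th draw kept thereafter.
    """
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    directions = np.asarray(directions, dtype=float)
    prec = np.linalg.inv(cov)
    w0 = directions * np.abs(mu)          # a point inside the orthant
    total = burn_in + n_draws * thin
    draws = _gibbs_kernel(mu, prec, directions, total, int(seed) % (2**31 - 1), w0)
    return draws[burn_in::thin][:n_draws]


def rejection_orthant_normal(mu, cov, directions, n_draws: int, seed: int,
                             max_batches: int = 4000) -> np.ndarray:
    """Rejection-sample the same law: keep untruncated draws in the orthant.

    Exact but exponentially slow in m; intended as a low-m oracle.
    """
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float)
    directions = np.asarray(directions, dtype=float)
    kept = []
    n_kept = 0
    for _ in range(max_batches):
        cand = rng.multivariate_normal(mu, cov, size=2048, method="cholesky")
        ok = (cand * directions >= 0).all(axis=1)
        kept.append(cand[ok])
        n_kept += int(ok.sum())
        if n_kept >= n_draws:
            break
    if n_kept < n_draws:
        raise RuntimeError(
            f"rejection sampler kept only {n_kept}/{n_draws} draws; "
            "orthant probability too small for this oracle"
        )
    return np.concatenate(kept)[:n_draws]


def split_rhat(samples: np.ndarray) -> np.ndarray:
    """Split-chain potential-scale-reduction for a single chain per coordinate.

    The chain is cut in half; values near 1 indicate the two halves agree in
    mean and variance.
    """
    n = samples.shape[0] // 2
    a, b = samples[:n], samples[n:2 * n]
    means = np.stack([a.mean(axis=0), b.mean(axis=0)])
    vars_ = np.stack([a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)])
    w = vars_.mean(axis=0)
    bvar = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + bvar / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    return np.where(w > 0, rhat, 1.0)
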