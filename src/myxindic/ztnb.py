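"""Zero-truncated count distributions (NB2 and Poisson).

The record-count frame contains only observed country x substrate x species
combinations, so zeros are structurally absent and the natural sampling model
is the negative binomial conditioned on y >= 1.  The NB is parameterised as
NB2: mean mu, size (dispersion) k, variance mu + mu^2/k; the zero-truncation
subtracts log(1 - p0) with p0 = (k / (k + mu))^k.  As k -> infinity the
distribution converges to the zero-truncated Poisson.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln


def nb_logpmf(y, mu, k):
    """NB2 log pmf at y with mean mu and size k."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    log_ratio = np.log1p(mu / k)  # log((k + mu)/k), stable for small mu/k
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1)
        - k * log_ratio
        + y * (np.log(mu) - np.log(k + mu))
    )


def log_p0(mu, k):
    """log P(Y = 0) for NB2: k * (log k - log(k + mu))."""
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    return -k * np.log1p(mu / k)


def ztnb_logpmf(y, mu, k):
    """Zero-truncated NB2 log pmf: NB log pmf minus log(1 - p0); y >= 1."""
    y = np.asarray(y, dtype=float)
    if (y < 1).any():
        raise ValueError("zero-truncated support is y >= 1 (zeros are structurally absent)")
    lp0 = log_p0(mu, k)
    # log(1 - exp(lp0)) computed stably
    log1m = np.log1p(-np.exp(lp0))
    return nb_logpmf(y, mu, k) - log1m


def ztnb_mean(mu, k):
    """Mean of the zero-truncated NB2: mu / (1 - p0)."""
    return np.asarray(mu, dtype=float) / -np.expm1(log_p0(mu, k))


def ztnb_rvs(mu, k, rng: np.random.Generator):
    """Draw zero-truncated NB2 variates by inverse-CDF restricted to y >= 1.

    u ~ Uniform(P(Y=0), 1) mapped through the untruncated NB quantile
    function; exact and fully vectorised.
    """
    mu = np.asarray(mu, dtype=float)
    k = np.broadcast_to(np.asarray(k, dtype=float), mu.shape)
    p = k / (k + mu)
    p0 = np.exp(log_p0(mu, k))
    u = p0 + (1.0 - p0) * rng.random(mu.shape)
    # guard against u numerically at or below p0
    u = np.clip(u, np.nextafter(p0, 1.0), np.nextafter(1.0, 0.0))
    y = stats.nbinom.ppf(u, k, p)
    return np.maximum(y, 1.0).astype(np.int64)


def ztpoisson_logpmf(y, mu):
    """Zero-truncated Poisson log pmf (the k -> infinity limit of the ZTNB)."""
    y = np.asarray(y, dtype=float)
    if (y < 1).any():
        raise ValueError("zero-truncated support is y >= 1")
    mu = np.asarray(mu, dtype=float)
    # log(1 - exp(-mu)) via log(-expm1(-mu))
    return y * np.log(mu) - mu - gammaln(y + 1) - np.log(-np.expm1(-mu))


def ztnb_eta_derivatives(y, eta, k):
    """First and second derivatives of the ZTNB log pmf w.r.t. eta = log mu.

    Used by the Laplace/Newton machinery of the mixed model.  Returns
    (loglik, d1, d2) as arrays aligned with y.
    """
    y = np.asarray(y, dtype=float)
    # clip the linear predictor: beyond +-30 the likelihood is flat to double
    # precision and unguarded exp/log under- or overflows
    eta = np.clip(np.asarray(eta, dtype=float), -30.0, 30.0)
    mu = np.exp(eta)
    kk = np.asarray(k, dtype=float)

    denom = kk + mu
    lp0 = -kk * np.log1p(mu / kk)
    p0 = np.exp(lp0)
    om = np.maximum(-np.expm1(lp0), 1e-300)  # 1 - p0

    ll = nb_logpmf(y, mu, kk) - np.log(om)

    # NB part: dl/dmu = y/mu - (y+k)/(k+mu)
    # truncation part: d/dmu[-log(1 - p0)] = -p0 k / ((k+mu)(1-p0))
    Q = p0 / om
    d1 = y - mu * (y + kk) / denom - kk * mu * Q / denom

    # d/deta of A = mu (y+k)/(k+mu):  mu * k (y+k)/(k+mu)^2
    dA = mu * kk * (y + kk) / denom**2
    # B = k r Q with r = mu/(k+mu); dB/deta = mu * dB/dmu
    # dr/dmu = k/(k+mu)^2 ; dQ/dmu = -p0 k/((k+mu)(1-p0)^2)
    r = mu / denom
    drdmu = kk / denom**2
    dQdmu = -p0 * kk / (denom * om**2)
    dB = mu * kk * (drdmu * Q + r * dQdmu)
    d2 = -dA - dB
    return ll, d1, d2
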