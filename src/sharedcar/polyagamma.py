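"""Exact sampling from the Pólya–Gamma distribution PG(1, z).

PG(b, z) arises as the data-augmentation variable that renders Bernoulli
logistic likelihoods conditionally Gaussian: for y ~ Bernoulli(logit^-1(psi)),

    p(y | psi) proportional to exp(kappa * psi) * E_omega[exp(-omega psi^2 / 2)],

with kappa = y - 1/2 and omega ~ PG(1, 0).  Conditional on the data,
omega | psi ~ PG(1, psi), and the draw here uses the exact alternating-series
rejection sampler of Devroye for the Jacobi-type density (the J*(1, c)
distribution), with PG(1, z) = J*(1, |z|/2) / 4.

The implementation is fully vectorised over the input array; every rejection
loop operates on the still-pending subset.  Useful identities for testing:

    E[PG(1, z)]   = tanh(z/2) / (2 z)          (= 1/4 at z = 0)
    Var[PG(1, 0)] = 1/24
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

__all__ = ["sample_pg"]

_T = 0.64  # Devroye's series crossover point
_MAX_ROUNDS = 2000


def _log_pigauss_cdf(t: float, z: np.ndarray) -> np.ndarray:
    """log CDF at t of the inverse-Gaussian(mu=1/z, lambda=1); z >= 0 allowed."""
    rt = 1.0 / np.sqrt(t)
    a = log_ndtr(rt * (t * z - 1.0))
    b = 2.0 * z + log_ndtr(-rt * (t * z + 1.0))
    return np.logaddexp(a, b)


def _coef(n: np.ndarray | int, x: np.ndarray) -> np.ndarray:
    """Series coefficient a_n(x) of the J*(1) density."""
    np12 = n + 0.5
    small = x <= _T
    with np.errstate(divide="ignore", over="ignore"):
        left = np.pi * np12 * (2.0 / (np.pi * x)) ** 1.5 * np.exp(-2.0 * np12**2 / x)
        right = np.pi * np12 * np.exp(-0.5 * np12**2 * np.pi**2 * x)
    return np.where(small, left, right)


def _rtigauss(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Gaussian(mu=1/c, lambda=1) truncated to (0, _T]; c >= 0."""
    out = np.empty_like(c)
    big_mu = c < 1.0 / _T  # mu > t, includes c == 0 (Levy limit)

    # mu > t: truncated Levy proposal, accept with exp(-c^2 X / 2)
    idx = np.flatnonzero(big_mu)
    pend = idx.copy()
    rounds = 0
    while pend.size:
        m = pend.size
        e1 = rng.standard_exponential(m)
        e2 = rng.standard_exponential(m)
        ok = e1 * e1 <= 2.0 * e2 / _T
        x = _T / (1.0 + _T * e1) ** 2
        acc = ok & (rng.random(m) < np.exp(-0.5 * c[pend] ** 2 * x))
        out[pend[acc]] = x[acc]
        pend = pend[~acc]
        rounds += 1
        if rounds > _MAX_ROUNDS:
            raise RuntimeError("truncated inverse-Gaussian sampler failed to accept")

    # mu <= t: plain inverse-Gaussian draws until within the truncation
    idx = np.flatnonzero(~big_mu)
    pend = idx.copy()
    rounds = 0
    while pend.size:
        m = pend.size
        mu = 1.0 / c[pend]
        y = rng.standard_normal(m) ** 2
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * np.sqrt(4.0 * mu * y + (mu * y) ** 2)
        flip = rng.random(m) > mu / (mu + x)
        x = np.where(flip, mu * mu / x, x)
        acc = x <= _T
        out[pend[acc]] = x[acc]
        pend = pend[~acc]
        rounds += 1
        if rounds > _MAX_ROUNDS:
            raise RuntimeError("truncated inverse-Gaussian sampler failed to accept")
    return out


def _sample_jstar(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """J*(1, c) draws for c >= 0 (tilted Jacobi), vectorised Devroye sampler."""
    k = np.pi**2 / 8.0 + 0.5 * c * c
    with np.errstate(over="ignore", under="ignore"):
        p = (np.pi / (2.0 * k)) * np.exp(-k * _T)
        q = 2.0 * np.exp(-c + _log_pigauss_cdf(_T, c))
    denom = p + q
    ratio = np.divide(p, denom, out=np.zeros_like(p), where=denom > 0)

    out = np.empty_like(c)
    pend = np.arange(c.size)
    rounds = 0
    while pend.size:
        m = pend.size
        right = rng.random(m) < ratio[pend]
        x = np.empty(m)
        x[right] = _T + rng.standard_exponential(int(right.sum())) / k[pend[right]]
        x[~right] = _rtigauss(c[pend[~right]], rng)

        # alternating-series accept/reject
        s = _coef(0, x)
        y = rng.random(m) * s
        undecided = np.ones(m, dtype=bool)
        accepted = np.zeros(m, dtype=bool)
        n = 0
        while undecided.any():
            n += 1
            u = undecided
            if n % 2 == 1:
                s[u] -= _coef(n, x[u])
                newly = u & (y <= s)
                accepted |= newly
                undecided &= ~newly
            else:
                s[u] += _coef(n, x[u])
                undecided &= ~(u & (y > s))  # y > s => reject this proposal
            if n > _MAX_ROUNDS:
                raise RuntimeError("series evaluation failed to terminate")
        out[pend[accepted]] = x[accepted]
        pend = pend[~accepted]
        rounds += 1
        if rounds > _MAX_ROUNDS:
            raise RuntimeError("J* sampler failed to accept")
    return out


def sample_pg(z, rng: np.random.Generator) -> np.ndarray:
    """Draw PG(1, z) variates, one per element of ``z``.

    Parameters
    ----------
    z : array_like
        Tilting parameters (any sign; the distribution depends on ``|z|``).
    rng : numpy.random.Generator
        Source of randomness.
    """
    z = np.asarray(z, dtype=float)
    c = np.abs(z).ravel() / 2.0
    draws = _sample_jstar(c, rng) / 4.0
    return draws.reshape(z.shape)
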