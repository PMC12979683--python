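"""Compound Poisson-gamma sampling for Tweedie-distributed catches.

For power parameter ``1 < p < 2`` the Tweedie distribution with mean ``mu``
and variance ``phi * mu**p`` is exactly a Poisson sum of gamma variates:

    N ~ Poisson(lambda),          lambda = mu**(2 - p) / (phi * (2 - p))
    Y | N ~ Gamma(N * alpha, s),  alpha  = (2 - p) / (p - 1)
                                  s      = phi * (p - 1) * mu**(p - 1)

with an atom at zero, ``P(Y = 0) = exp(-lambda)``.  This is the natural
model for zero-inflated, overdispersed catch counts: most gillnet sets
catch nothing, and positive catches are clumped.
"""

from __future__ import annotations

import numpy as np


def tweedie_zero_mass(mu: np.ndarray, p: float, phi: float) -> np.ndarray:
    """Exact probability of a zero draw, exp(-mu^(2-p) / (phi (2-p)))."""
    mu = np.asarray(mu, dtype=float)
    return np.exp(-(mu ** (2.0 - p)) / (phi * (2.0 - p)))


def rng_from_seed(seed) -> np.random.Generator:
    """Normalize an int seed / SeedSequence / Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_tweedie(
    mu: np.ndarray, p: float, phi: float, seed
) -> np.ndarray:
    """Draw Tweedie(mu, p, phi) variates via the compound Poisson-gamma
    representation (exact for 1 < p < 2).

    Parameters
    ----------
    mu : array-like of positive means.
    p : power parameter, strictly inside (1, 2).
    phi : dispersion, > 0.
    seed : int seed or ``numpy.random.Generator``.
    """
    if not 1.0 < p < 2.0:
        raise ValueError(f"Tweedie power must lie in (1, 2); got {p}")
    if phi <= 0:
        raise ValueError(f"dispersion must be positive; got {phi}")
    mu = np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite Tweedie mean")
    if np.any(mu <= 0):
        raise ValueError("Tweedie means must be positive")

    rng = rng_from_seed(seed)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)

    n = rng.poisson(lam)
    out = np.zeros_like(mu, dtype=float)
    pos = n > 0
    if np.any(pos):
        out[pos] = rng.gamma(shape=alpha * n[pos], scale=scale[pos])
    return out
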