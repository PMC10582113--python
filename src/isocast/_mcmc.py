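"""Small shared utilities for the adaptive random-walk samplers."""

from __future__ import annotations

import numpy as np

#: target acceptance rate for scalar random-walk updates
TARGET_ACCEPT = 0.44
#: Robbins–Monro adaptation gain during burn-in
ADAPT_GAIN = 0.05


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Parameters
    ----------
    chains
        Array of shape (n_chains, n_draws).

    Returns
    -------
    float
        The split-R̂ statistic; values near 1 indicate convergence.
    """
    chains = np.asarray(chains, float)
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def adapt_scales(scales: np.ndarray, accepted: np.ndarray) -> None:
    """In-place Robbins–Monro scale update toward :data:`TARGET_ACCEPT`."""
    scales *= np.exp(ADAPT_GAIN * (accepted - TARGET_ACCEPT))


def normal_suffstats(values: np.ndarray) -> tuple[int, float, float]:
    """(n, Σx, Σx²) sufficient statistics for a univariate normal."""
    values = np.asarray(values, float)
    return len(values), float(values.sum()), float((values**2).sum())


def normal_loglik_from_stats(
    n: int, sx: float, sxx: float, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Gaussian log-likelihood of n iid points via sufficient statistics.

    ``mu`` and ``sigma`` may be arrays (vectorized over chains); the
    additive −n/2·log(2π) constant is included so likelihoods are
    comparable across σ values.
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    rss = sxx - 2.0 * mu * sx + n * mu**2
    return -n * np.log(sigma) - 0.5 * rss / sigma**2 - 0.5 * n * np.log(2 * np.pi)
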