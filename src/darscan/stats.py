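"""Log-space tail probabilities shared by every enrichment test in the pipeline.

The central DAR statistic is a one-sided binomial survival probability that
routinely drops far below the smallest normal IEEE double (the flagship
LTR7 example sits near log10 p = -1276), so both kernels here sum the exact
tail in log space with ``gammaln`` + ``logsumexp`` and hand back log10
p-values.  Linear-scale convenience wrappers are provided for the many
places where the p-value is representable.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp

_LN10 = math.log(10.0)


def binom_sf_log10(k: int, n: int, p0: float) -> float:
    """log10 of P(X >= k) for X ~ Binomial(n, p0), exact in log space.

    Parameters
    ----------
    k, n : int
        Observed successes and number of trials, ``0 <= k <= n``.
    p0 : float
        Success probability, ``0 <= p0 <= 1``.

    Returns
    -------
    float
        log10 of the upper tail; 0.0 when ``k <= 0`` (the tail is 1) and
        ``-inf`` when the tail is exactly zero (``p0 == 0`` with ``k > 0``).
    """
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"require 0 <= p0 <= 1, got p0={p0}")
    if k <= 0:
        return 0.0
    if p0 == 0.0:
        return -math.inf
    if p0 == 1.0:
        return 0.0
    ks = np.arange(k, n + 1, dtype=np.float64)
    log_pmf = (
        gammaln(n + 1.0)
        - gammaln(ks + 1.0)
        - gammaln(n - ks + 1.0)
        + ks * math.log(p0)
        + (n - ks) * math.log1p(-p0)
    )
    return float(logsumexp(log_pmf) / _LN10)


def binom_sf(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0); underflows to 0.0 below ~1e-308."""
    return 10.0 ** binom_sf_log10(k, n, p0)


def hypergeom_sf_log10(k: int, N: int, K: int, n: int) -> float:
    """log10 of P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the population size, ``K`` the number of successes in the
    population and ``n`` the sample size (drawn without replacement).
    """
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N, got N={N}, K={K}, n={n}")
    if min(N, K, n) < 0:
        raise ValueError("hypergeometric parameters must be non-negative")
    upper = min(K, n)
    if k > upper + 1:
        raise ValueError(f"k={k} exceeds min(K, n) + 1 = {upper + 1}")
    if k <= max(0, n + K - N):
        return 0.0  # the tail includes the whole support
    if k > upper:
        return -math.inf
    ks = np.arange(k, upper + 1, dtype=np.float64)
    log_pmf = (
        gammaln(K + 1.0)
        - gammaln(ks + 1.0)
        - gammaln(K - ks + 1.0)
        + gammaln(N - K + 1.0)
        - gammaln(n - ks + 1.0)
        - gammaln(N - K - n + ks + 1.0)
        - (gammaln(N + 1.0) - gammaln(n + 1.0) - gammaln(N - n + 1.0))
    )
    return float(logsumexp(log_pmf) / _LN10)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), linear scale."""
    return 10.0 ** hypergeom_sf_log10(k, N, K, n)


def zscore(observed: float, mean: float, sd: float) -> float:
    """(observed - mean) / sd with an infinite sentinel at sd == 0."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        if observed == mean:
            return 0.0
        return math.inf if observed > mean else -math.inf
    return (observed - mean) / sd
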