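"""Kolmogorov–Smirnov uniformity test on genomic positions.

The positional hypothesis: positions of a functionless symbol sequence are
uniform over the strand; a functional element clusters.  For a sample of
occupied positions x_(1) <= ... <= x_(n) on a strand of length L, the
reference CDF is F(x) = x / L (continuous uniform on (0, L]) and

    D_n = max_i max( i/n - F(x_(i)),  F(x_(i)) - (i-1)/n )

The p-value is the asymptotic Kolmogorov tail probability at lambda =
sqrt(n) * D_n,

    Q(lambda) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2)

with the series truncated once a term falls below 1e-10.  No small-sample
correction is applied: the extraction algorithm only ever tests samples with
n > 100, where the asymptotic law is adequate.  A different KS backend can
be substituted as long as it agrees with this contract to 1e-6.

The uniform reference always spans the full strand length — including after
the integrity filter removes positions — because net positions are tested
against the same uniform law as raw positions, with no renormalization of
the support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

DEFAULT_MIN_DN = 0.1
DEFAULT_MIN_COUNT = 100
_SERIES_TOL = 1e-10


@dataclass(frozen=True)
class KSResult:
    """KS distance and tail probability for one positional sample."""

    n: int
    dn: float
    p_value: float


def kolmogorov_sf(lam: float) -> float:
    """Asymptotic Kolmogorov survival function Q(lambda), clipped to [0, 1]."""
    if lam <= 0.0:
        return 1.0
    total = 0.0
    k = 1
    while True:
        term = 2.0 * math.exp(-2.0 * k * k * lam * lam)
        if term < _SERIES_TOL:
            break
        total += term if k % 2 == 1 else -term
        k += 1
    return min(1.0, max(0.0, total))


def ks_uniform(positions: Iterable[int], total_length: int) -> KSResult:
    """Test 1-based positions against the uniform distribution on [1, L].

    ``positions`` must be non-empty distinct integers within range; they come
    from occupied-position sets, so ties cannot occur and are rejected rather
    than silently tolerated.  Order of the input is irrelevant.
    """
    x = np.asarray(sorted(positions), dtype=np.float64)
    n = x.size
    if n == 0:
        raise ValueError("positions must be non-empty")
    if x[0] < 1 or x[-1] > total_length:
        raise ValueError("positions must lie in [1, total_length]")
    if np.any(np.diff(x) == 0):
        raise ValueError("positions must be distinct")
    f = x / float(total_length)
    i = np.arange(1, n + 1, dtype=np.float64)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1.0) / n)
    dn = float(max(d_plus, d_minus))
    return KSResult(n=int(n), dn=dn, p_value=kolmogorov_sf(math.sqrt(n) * dn))


def adjusted_alpha(n_class: int, family_conf: float = 0.95) -> float:
    """Per-class significance level alpha = 1 - conf^(1/n_class).

    Controls the family-wise confidence over the n_class candidates tested
    in one length class; strictly decreasing in n_class, equal to
    1 - family_conf at n_class = 1.
    """
    if n_class < 1:
        raise ValueError("n_class must be >= 1")
    return 1.0 - family_conf ** (1.0 / n_class)


def passes_word_criteria(
    res: KSResult,
    alpha: float,
    min_dn: float = DEFAULT_MIN_DN,
    min_count: int = DEFAULT_MIN_COUNT,
) -> bool:
    """Acceptance test for one candidate: all three criteria, all strict.

    n > min_count, p < alpha and D_n > min_dn.
    """
    return res.n > min_count and res.p_value < alpha and res.dn > min_dn
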