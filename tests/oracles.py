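"""Independent brute-force oracles used to cross-check the implementation.

Each oracle follows the defining formula directly (exact rationals,
exhaustive enumeration, or Monte Carlo) and shares no code with the path it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import special


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational probability-mass two-sided Fisher p for [[a,b],[c,d]].

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than observed.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, total))


def bh_step_up_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p by the literal step-up definition.

    For each sorted position i, q_(i) = min over j >= i of p_(j) * m / j,
    computed with an explicit double loop.
    """
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(ps[j] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def trigamma_inverse_bisect(y: float, lo: float = 1e-12, hi: float = 1e14,
                            iters: int = 200) -> float:
    """Solve psi'(x) = y by bisection (psi' is strictly decreasing)."""
    for _ in range(iters):
        mid = np.sqrt(lo * hi)  # geometric bisection over many decades
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def chi2_gof_mc_p(observed: np.ndarray, probs: np.ndarray, n_draws: int,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo multinomial goodness-of-fit p-value and its standard error."""
    observed = np.asarray(observed, float)
    probs = np.asarray(probs, float)
    n = int(observed.sum())
    expected = probs * n
    stat_obs = ((observed - expected) ** 2 / expected).sum()
    sims = rng.multinomial(n, probs, size=n_draws)
    stats = ((sims - expected) ** 2 / expected).sum(axis=1)
    p = float(np.mean(stats >= stat_obs - 1e-12))
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws))
    return p, se
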