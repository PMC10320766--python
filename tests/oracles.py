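"""Independent brute-force oracles used to check closed-form implementations.

Each oracle deliberately takes a different computational route from the
code it validates: the cascade probability is summed over all 2^7
replicate-outcome vectors, the hypergeometric tail over exact integer
binomial coefficients, and the rank-sum p-value over pair counts rather
than ranks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def enumerate_cascade(p_primary: float, p_retest: float, p_photo: float) -> float:
    """P(final hit) by summing over all 2^7 replicate outcome vectors.

    Success requires >= 2 of 3 primary detections (candidacy through the
    pair itself), primary + retest >= 3 of 5, and >= 1 of 2 photo
    detections.  Tiers never reached are marginalised over.
    """
    total = 0.0
    for bits in itertools.product((0, 1), repeat=7):
        prim, ret, photo = bits[:3], bits[3:5], bits[5:]
        prob = 1.0
        for b in prim:
            prob *= p_primary if b else (1.0 - p_primary)
        for b in ret:
            prob *= p_retest if b else (1.0 - p_retest)
        for b in photo:
            prob *= p_photo if b else (1.0 - p_photo)
        a = sum(prim)
        if a >= 2 and a + sum(ret) >= 3 and sum(photo) >= 1:
            total += prob
    return total


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) as an exact rational: sum C(K,i) C(N-K,n-i) / C(N,n)."""
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return float(Fraction(numerator, comb(N, n)))


def ranksum_exact_p(group_a, group_b) -> float:
    """Two-sided exact Mann-Whitney p-value by pair-count enumeration.

    U for an assignment is the number of (a, b) pairs with a > b plus half
    the ties; the permutation distribution is enumerated over all ways to
    choose which values form group A.  Two-sided p is twice the smaller
    tail, capped at 1.
    """
    values = list(group_a) + list(group_b)
    n_a = len(group_a)

    def u_stat(a_vals, b_vals) -> float:
        u = 0.0
        for x in a_vals:
            for y in b_vals:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(values[:n_a], values[n_a:])
    us = []
    idx = range(len(values))
    for combo in itertools.combinations(idx, n_a):
        in_a = set(combo)
        a_vals = [values[i] for i in combo]
        b_vals = [values[i] for i in idx if i not in in_a]
        us.append(u_stat(a_vals, b_vals))
    eps = 1e-9
    p_ge = sum(1 for u in us if u >= u_obs - eps) / len(us)
    p_le = sum(1 for u in us if u <= u_obs + eps) / len(us)
    return min(1.0, 2.0 * min(p_ge, p_le))
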