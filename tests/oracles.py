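"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or a textbook
estimator, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def ls_posteriors_by_enumeration(
    obs: np.ndarray,
    ref: np.ndarray,
    rho: np.ndarray,
    err: float,
) -> np.ndarray:
    """Li-Stephens copying posteriors by summation over all state paths.

    ``obs`` is one target haplotype over S typed sites, ``ref`` is (H, S),
    ``rho`` the per-interval switch probabilities.  Complexity H**S.
    """
    n_h, n_s = ref.shape
    post = np.zeros((n_s, n_h))
    total = 0.0
    for path in itertools.product(range(n_h), repeat=n_s):
        p = 1.0 / n_h
        for s, h in enumerate(path):
            if s > 0:
                prev = path[s - 1]
                stay = (1.0 - rho[s - 1]) + rho[s - 1] / n_h
                p *= stay if h == prev else rho[s - 1] / n_h
            p *= (1.0 - err) if ref[h, s] == obs[s] else err
        total += p
        for s, h in enumerate(path):
            post[s, h] += p
    return post / total


def meta_weights_by_enumeration(
    obs: np.ndarray,
    loo: np.ndarray,
    switch_prob: float,
    weight_floor: float,
) -> np.ndarray:
    """Panel-selection posteriors by summation over all panel paths.

    ``loo`` is (S, K); emission for panel k at site s is loo[s, k] if
    obs[s] == 1 else 1 - loo[s, k], floored at ``weight_floor``.
    """
    n_s, k = loo.shape
    emit = np.where(obs[:, None] == 1, loo, 1.0 - loo)
    emit = np.maximum(emit, weight_floor)
    post = np.zeros((n_s, k))
    total = 0.0
    for path in itertools.product(range(k), repeat=n_s):
        p = 1.0 / k
        for s, h in enumerate(path):
            if s > 0:
                p *= (1.0 - switch_prob) if h == path[s - 1] else switch_prob / (k - 1)
            p *= emit[s, h]
        total += p
        for s, h in enumerate(path):
            post[s, h] += p
    return post / total


def hwe_p_by_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value from first principles with rational arithmetic.

    Conditional on allele counts, P(het = h) is proportional to
    n! / (hom_r! h! hom_c!) * 2**h; the two-sided p sums probabilities of
    all heterozygote counts at most as likely as the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    weights: dict[int, Fraction] = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        w = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c),
        )
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Hudson's Fst estimator, averaged as a ratio of sums over sites.

    ``p1``/``p2`` are alt-allele frequencies per site, ``n1``/``n2`` the
    haplotype sample sizes.
    """
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    if not keep.any():
        return 0.0
    return float(num[keep].sum() / den[keep].sum())
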