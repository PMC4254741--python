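"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own implementations: direct
nested-loop convolution, two-pass variance, exact rational hypergeometric
enumeration, and a hand-stepped backlash simulator.
"""
from fractions import Fraction
from math import comb

import numpy as np


def direct_log_convolution(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D convolution with symmetric (reflect) padding, nested loops."""
    kh, kw = kernel.shape
    pad_r, pad_c = kh // 2, kw // 2
    padded = np.pad(image, ((pad_r, pad_r), (pad_c, pad_c)), mode="symmetric")
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(padded[i:i + kh, j:j + kw] * kernel)
    return out


def two_pass_variance(image: np.ndarray) -> float:
    """Textbook two-pass population variance."""
    flat = np.asarray(image, dtype=float).ravel()
    mean = sum(flat) / len(flat)
    return sum((v - mean) ** 2 for v in flat) / len(flat)


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full rational enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= the observed one (exact arithmetic,
    so ties are handled without floating-point ambiguity).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, n - c1):
        return 1.0
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def backlash_hand_simulation(deltas, deadband: float, step: float = 0.025):
    """Step-by-step single-axis piezo oracle; returns (positions, last_dir)."""
    pos = 0.0
    last = 0.0
    out = []
    for d in deltas:
        if d != 0.0:
            s = 1.0 if d > 0 else -1.0
            achieved = d
            if s != last:
                achieved -= s * min(deadband, abs(d))
            achieved = round(achieved / step) * step
            pos += achieved
            last = s
        out.append(pos)
    return out, last


def proportional_loop_hand_simulation(e0_px: float, kp: float,
                                      n_iter: int = 10,
                                      tol_px: float = 1.0) -> list:
    """Noiseless, zero-backlash error sequence e_{k+1} = (1 - Kp) e_k."""
    errors = [e0_px]
    for _ in range(n_iter):
        if abs(errors[-1]) <= tol_px:
            break
        errors.append((1.0 - kp) * errors[-1])
    return errors


def binomial_ci(n: int, p: float, level: float = 0.99):
    """Exact binomial central interval on the count scale."""
    from scipy.stats import binom
    alpha = 1.0 - level
    return int(binom.ppf(alpha / 2, n, p)), int(binom.isf(alpha / 2, n, p))
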