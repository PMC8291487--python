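"""Independent brute-force reference implementations used as test oracles.

Everything here recomputes quantities from first principles (explicit
pairwise loops, direct textbook constants, linear scans) without
touching the package's own code paths, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def brute_pi(matrix) -> float:
    """Mean pairwise Hamming distance over all unordered haplotype pairs."""
    m = np.asarray(matrix)
    n = m.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((m[i] != m[j]).sum())
            pairs += 1
    return total / pairs


def brute_tajima_d(matrix):
    m = np.asarray(matrix)
    n = m.shape[0]
    counts = m.sum(axis=0)
    seg = [c for c in counts if 0 < c < n]
    S = len(seg)
    if S == 0:
        return None
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    keep = [j for j, c in enumerate(counts) if 0 < c < n]
    pi = brute_pi(m[:, keep]) if keep else 0.0
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def brute_fu_li_d(matrix):
    """Polarized Fu & Li's D with constants written out directly."""
    m = np.asarray(matrix)
    n = m.shape[0]
    counts = m.sum(axis=0)
    seg = [c for c in counts if 0 < c < n]
    eta = len(seg)
    if eta == 0:
        return None
    eta_e = sum(1 for c in seg if c == 1)
    a = harmonic(n)
    b = harmonic(n, 2)
    if n == 2:
        c = 1.0
    else:
        c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v = 1 + (a**2 / (b + a**2)) * (c - (n + 1) / (n - 1))
    u = a - 1 - v
    return (eta - a * eta_e) / math.sqrt(u * eta + v * eta**2)


def brute_fu_li_dstar(matrix):
    """Unpolarized D* with the corrected variance constants."""
    m = np.asarray(matrix)
    n = m.shape[0]
    counts = m.sum(axis=0)
    seg = [c for c in counts if 0 < c < n]
    eta = len(seg)
    if eta == 0:
        return None
    eta_s = sum(1 for c in seg if c == 1 or c == n - 1)
    a = harmonic(n)
    b = harmonic(n, 2)
    c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    an1 = a + 1.0 / n
    d = (
        c
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1 / n)
    )
    v = ((n / (n - 1)) ** 2 * b + a**2 * d - 2 * n * a * (a + 1) / (n - 1) ** 2) / (
        a**2 + b
    )
    u = (n / (n - 1)) * (a - n / (n - 1)) - v
    return ((n / (n - 1)) * eta - a * eta_s) / math.sqrt(u * eta + v * eta**2)


def brute_hudson_fst(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return None if den == 0 else num / den


def brute_window_members(positions_1based, start, end):
    """Variant 1-based positions falling in the 0-based window [start, end)."""
    return [p for p in positions_1based if start <= p - 1 < end]


def brute_ssn_z(ref: np.ndarray, xi: float, xj: float, i: int, j: int):
    """SSN edge z from first principles with numpy's corrcoef."""
    n = ref.shape[1]
    r0 = float(np.corrcoef(ref[i], ref[j])[0, 1])
    r1 = float(
        np.corrcoef(np.append(ref[i], xi), np.append(ref[j], xj))[0, 1]
    )
    return (r1 - r0) / ((1 - r0**2) / (n - 1))


def random_segsites_matrix(rng: np.random.Generator, n: int, S: int) -> np.ndarray:
    """A 0/1 matrix where every column is segregating."""
    m = np.zeros((n, S), dtype=np.int8)
    for j in range(S):
        k = int(rng.integers(1, n))
        rows = rng.choice(n, size=k, replace=False)
        m[rows, j] = 1
    return m
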