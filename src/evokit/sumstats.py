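"""Classical neutrality and diversity statistics on 0/1 haplotype matrices.

Implements Watterson's theta, the mean number of pairwise nucleotide
differences (pi), Tajima's D, and Fu & Li's D (polarized, requiring a
known ancestral state) and D* (outgroup-free).  All statistics are
computed from a haplotype-by-site 0/1 matrix in which 0 denotes the
ancestral allele (for simulator output) or an arbitrary reference allele
(for VCF-derived data, where only the unpolarized statistics are
meaningful).

Statistics that are undefined (no segregating sites, or a degenerate
variance) return ``None`` rather than raising, so that replicate
pipelines keep running; callers count the undefined replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NeutralityConstants",
    "SummaryStats",
    "neutrality_constants",
    "watterson_theta",
    "mean_pairwise_diff",
    "tajimas_d",
    "fu_li_d",
    "fu_li_dstar",
    "summarize_matrix",
    "empirical_distribution",
]


@dataclass(frozen=True)
class NeutralityConstants:
    """Sample-size-dependent constants of the neutrality tests.

    ``a1``/``a2`` are the harmonic and generalized harmonic numbers
    H_{n-1} and sum 1/i^2; ``b1..e2`` are Tajima's (1989) variance
    constants; ``c_n``/``d_n`` and the (starred) ``u``/``v`` pairs are
    Fu & Li's (1993) constants, with the later variance corrections.
    """

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    c_n: float
    d_n: float
    u_d: float
    v_d: float
    u_dstar: float
    v_dstar: float


@lru_cache(maxsize=512)
def neutrality_constants(n: int) -> NeutralityConstants:
    """Compute all sample-size constants for ``n`` haplotypes (n >= 2)."""
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got n={n}")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))

    # Tajima 1989
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)

    # Fu & Li 1993 (c_n; v_D/u_D for the polarized D)
    if n == 2:
        c_n = 1.0
    else:
        c_n = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + (a1 * a1 / (a2 + a1 * a1)) * (c_n - (n + 1) / (n - 1))
    u_d = a1 - 1.0 - v_d

    # D* constants with the standard corrected d_n (as used in common
    # implementations); d_n needs n >= 3.
    if n == 2:
        d_n = 2.0
    else:
        a1n1 = a1 + 1.0 / n  # harmonic number H_n
        d_n = (
            c_n
            + (n - 2) / ((n - 1) ** 2)
            + (2.0 / (n - 1)) * (1.5 - (2 * a1n1 - 3) / (n - 2) - 1.0 / n)
        )
    nn = n / (n - 1.0)
    v_dstar = (nn * nn * a2 + a1 * a1 * d_n - 2 * n * a1 * (a1 + 1) / ((n - 1) ** 2)) / (
        a1 * a1 + a2
    )
    u_dstar = nn * (a1 - nn) - v_dstar
    return NeutralityConstants(
        n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
        c_n=c_n, d_n=d_n, u_d=u_d, v_d=v_d, u_dstar=u_dstar, v_dstar=v_dstar,
    )


@dataclass
class SummaryStats:
    """Per-sample summary of a haplotype matrix.

    ``None`` marks an undefined statistic (e.g. any D with S = 0).
    Under the infinite-sites model ``eta`` (total mutations) equals
    ``S``; ``eta_s`` counts derived singletons when the matrix is
    polarized, minor-allele singletons otherwise.
    """

    n: int
    S: int
    eta: int
    eta_s: int
    theta_w: float
    pi: float
    tajima_d: Optional[float]
    fu_li_d: Optional[float]
    fu_li_dstar: Optional[float]


def _as_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("haplotype matrix must be 2-D (haplotypes x sites)")
    if m.size and not np.isin(m, (0, 1)).all():
        raise ValueError("haplotype matrix entries must be 0/1")
    return m.astype(np.int64, copy=False)


def watterson_theta(n: int, S: int) -> float:
    """Watterson's estimator S / a1(n) with a1 = H_{n-1}."""
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got n={n}")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return 0.0
    return S / neutrality_constants(n).a1


def mean_pairwise_diff(matrix: np.ndarray) -> float:
    """Mean number of pairwise differences pi over all unordered pairs.

    Equals sum over sites of 2 i (n - i) / (n (n - 1)) where i is the
    derived (or alternate) allele count at the site.
    """
    m = _as_matrix(matrix)
    n = m.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got n={n}")
    if m.shape[1] == 0:
        return 0.0
    counts = m.sum(axis=0)
    return float((2.0 * counts * (n - counts)).sum() / (n * (n - 1)))


def _derived_counts(matrix: np.ndarray) -> np.ndarray:
    m = _as_matrix(matrix)
    return m.sum(axis=0)


def tajimas_d(matrix: np.ndarray) -> Optional[float]:
    """Tajima's D: normalized difference between pi and S/a1.

    Returns ``None`` when S = 0 (the statistic is undefined).
    """
    m = _as_matrix(matrix)
    n = m.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got n={n}")
    counts = _derived_counts(m)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return None
    k = neutrality_constants(n)
    pi = mean_pairwise_diff(m[:, seg])
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi - S / k.a1) / math.sqrt(var)


def fu_li_d(matrix: np.ndarray) -> Optional[float]:
    """Fu & Li's D (polarized; 0 must encode the ancestral allele).

    Contrasts the number of derived singletons (external-branch
    mutations) with the total mutation count.  ``None`` when there are
    no segregating sites.
    """
    m = _as_matrix(matrix)
    n = m.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got n={n}")
    counts = _derived_counts(m)
    seg = (counts > 0) & (counts < n)
    eta = int(seg.sum())
    if eta == 0:
        return None
    eta_e = int((counts[seg] == 1).sum())
    k = neutrality_constants(n)
    var = k.u_d * eta + k.v_d * eta * eta
    if var <= 0:
        return None
    return (eta - k.a1 * eta_e) / math.sqrt(var)


def fu_li_dstar(matrix: np.ndarray) -> Optional[float]:
    """Fu & Li's D* (outgroup-free; singletons = alleles seen once)."""
    m = _as_matrix(matrix)
    n = m.shape[0]
    if n < 3:
        raise ValueError(f"D* needs at least 3 haplotypes, got n={n}")
    counts = _derived_counts(m)
    seg = (counts > 0) & (counts < n)
    eta = int(seg.sum())
    if eta == 0:
        return None
    cseg = counts[seg]
    eta_s = int(((cseg == 1) | (cseg == n - 1)).sum())
    k = neutrality_constants(n)
    var = k.u_dstar * eta + k.v_dstar * eta * eta
    if var <= 0:
        return None
    return (n / (n - 1.0) * eta - k.a1 * eta_s) / math.sqrt(var)


def summarize_matrix(matrix: np.ndarray, polarized: bool = True) -> SummaryStats:
    """Compute all four statistics on a 0/1 haplotype matrix.

    ``polarized`` selects Fu & Li's D (simulator output, 0 = ancestral)
    vs D* only in what ``fu_li_d``/``fu_li_dstar`` mean downstream; both
    are reported when computable.
    """
    m = _as_matrix(matrix)
    n = m.shape[0]
    counts = _derived_counts(m)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    cseg = counts[seg]
    if polarized:
        eta_s = int((cseg == 1).sum())
    else:
        eta_s = int(((cseg == 1) | (cseg == n - 1)).sum())
    return SummaryStats(
        n=n,
        S=S,
        eta=S,
        eta_s=eta_s,
        theta_w=watterson_theta(n, S),
        pi=mean_pairwise_diff(m),
        tajima_d=tajimas_d(m),
        fu_li_d=fu_li_d(m) if polarized else None,
        fu_li_dstar=fu_li_dstar(m) if n >= 3 else None,
    )


def empirical_distribution(
    values: Sequence[Optional[float]],
    probs: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> dict:
    """Quantile table + histogram over the defined subset of ``values``.

    Undefined entries (``None`` or NaN) are excluded and counted.
    Quantiles use linear interpolation of order statistics.  Raises
    ``ValueError`` when every value is undefined.
    """
    defined = [v for v in values if v is not None and not math.isnan(v)]
    n_undef = len(values) - len(defined)
    if not defined:
        raise ValueError("empirical distribution of an all-undefined sample")
    arr = np.asarray(defined, dtype=float)
    qs = np.quantile(arr, probs, method="linear")
    hist, edges = np.histogram(arr, bins="auto")
    return {
        "n": int(arr.size),
        "n_undefined": int(n_undef),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "quantiles": {float(p): float(q) for p, q in zip(probs, qs)},
        "hist_counts": hist.tolist(),
        "hist_edges": edges.tolist(),
    }
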