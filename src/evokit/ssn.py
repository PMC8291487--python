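"""Sample-specific network (SSN) analysis.

Given a reference cohort expression matrix (genes x samples) and one
query sample, each gene pair's edge is scored by the change in Pearson
correlation when the query sample is appended to the cohort:
delta_pcc = pcc(n+1) - pcc(n).  Under the null that the query sample
comes from the reference distribution, delta_pcc is approximately
normal with standard deviation (1 - pcc_ref^2) / (n - 1), giving a
Z score and a two-sided p value per edge; edges are ranked by |Z| and
Benjamini-Hochberg q values are reported alongside raw p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionMatrix",
    "SSNEdge",
    "reference_correlations",
    "ssn_sample",
    "synth_expression",
]

PAIR_CAP = 2_000_000


@dataclass
class ExpressionMatrix:
    """Genes x reference-samples expression values (finite floats)."""

    genes: List[str]
    samples: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample counts")
        if not np.isfinite(v).all():
            raise ValueError("expression values must be finite")
        if len(self.samples) < 3:
            raise ValueError("need at least 3 reference samples")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        self.values = v

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    def constant_genes(self) -> List[str]:
        sd = self.values.std(axis=1)
        return [g for g, s in zip(self.genes, sd) if s == 0.0]


@dataclass
class SSNEdge:
    gene_a: str
    gene_b: str
    pcc_ref: float
    pcc_pert: float
    delta_pcc: float
    z: Optional[float]  # None when |pcc_ref| = 1 (zero null variance)
    p: Optional[float]
    q: Optional[float] = None
    significant: bool = False


def _select_pairs(
    genes: List[str], gene_subset: Optional[Sequence[str]]
) -> List[Tuple[int, int]]:
    if gene_subset is None:
        idx = list(range(len(genes)))
    else:
        pos = {g: i for i, g in enumerate(genes)}
        missing = [g for g in gene_subset if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = [pos[g] for g in gene_subset]
    n_pairs = len(idx) * (len(idx) - 1) // 2
    if n_pairs > PAIR_CAP:
        raise ValueError(
            f"{n_pairs} gene pairs exceeds the cap of {PAIR_CAP}; "
            "pass an explicit gene_subset"
        )
    return list(combinations(sorted(idx), 2))


def reference_correlations(
    mat: ExpressionMatrix, gene_subset: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pearson correlation for each unordered gene pair in the subset.

    Pairs involving a constant gene row are skipped and reported in the
    ``skipped`` column of the returned frame's attrs.
    """
    pairs = _select_pairs(mat.genes, gene_subset)
    v = mat.values
    sd = v.std(axis=1)
    centered = v - v.mean(axis=1, keepdims=True)
    rows, skipped = [], []
    for i, j in pairs:
        ga, gb = mat.genes[i], mat.genes[j]
        if sd[i] == 0.0 or sd[j] == 0.0:
            skipped.append((ga, gb))
            continue
        r = float(centered[i] @ centered[j] / (len(mat.samples) * sd[i] * sd[j]))
        rows.append((ga, gb, max(-1.0, min(1.0, r))))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc_ref"])
    df.attrs["skipped"] = skipped
    return df


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return max(-1.0, min(1.0, float(xc @ yc) / denom))


def ssn_sample(
    mat: ExpressionMatrix,
    sample: Dict[str, float],
    alpha: float = 0.05,
    gene_subset: Optional[Sequence[str]] = None,
) -> List[SSNEdge]:
    """Score every gene-pair edge of one query sample.

    ``sample`` maps gene id -> expression value and must cover all
    tested genes.  Per edge: delta_pcc = pcc over n+1 samples (cohort
    plus query) minus pcc over the n reference samples;
    z = delta_pcc / ((1 - pcc_ref^2) / (n - 1)); two-sided normal p;
    BH q across scored edges; edges ranked by |z| (ties broken by the
    lexicographic gene pair).  Edges with |pcc_ref| = 1 are reported
    unscored (z = p = None).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    pairs = _select_pairs(mat.genes, gene_subset)
    tested_genes = {mat.genes[k] for ij in pairs for k in ij}
    missing = [g for g in tested_genes if g not in sample]
    if missing:
        raise KeyError(f"query sample lacks genes: {sorted(missing)[:5]}")
    n = len(mat.samples)
    v = mat.values
    sd = v.std(axis=1)
    edges: List[SSNEdge] = []
    for i, j in pairs:
        ga, gb = mat.genes[i], mat.genes[j]
        if sd[i] == 0.0 or sd[j] == 0.0:
            continue
        r_ref = _pearson(v[i], v[j])
        xi = np.append(v[i], sample[ga])
        xj = np.append(v[j], sample[gb])
        r_pert = _pearson(xi, xj)
        delta = r_pert - r_ref
        if abs(r_ref) >= 1.0 - 1e-15:
            edges.append(SSNEdge(ga, gb, r_ref, r_pert, delta, None, None))
            continue
        z = delta / ((1.0 - r_ref * r_ref) / (n - 1))
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = max(p, np.nextafter(0.0, 1.0))  # keep p in (0, 1]
        edges.append(SSNEdge(ga, gb, r_ref, r_pert, delta, float(z), p))

    scored = [e for e in edges if e.p is not None]
    if scored:
        order = np.argsort([e.p for e in scored], kind="stable")
        m = len(scored)
        qmin = 1.0
        qs = [0.0] * m
        for rank_from_last in range(m - 1, -1, -1):
            e = scored[order[rank_from_last]]
            qmin = min(qmin, e.p * m / (rank_from_last + 1))
            qs[order[rank_from_last]] = qmin
        for e, q in zip(scored, qs):
            e.q = float(max(q, e.p))  # clamp float round-off; BH q >= p
            e.significant = e.p < alpha
    edges.sort(
        key=lambda e: (-(abs(e.z) if e.z is not None else -1.0), e.gene_a, e.gene_b)
    )
    return edges


def synth_expression(
    n_genes: int,
    n_samples: int,
    block_correlation: float = 0.0,
    block_size: int = 5,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Multivariate-normal expression with block-structured correlation.

    Genes are grouped into consecutive blocks of ``block_size``; within
    a block every pair has correlation ``block_correlation``, across
    blocks zero.  Returns the matrix and a truth ledger of the planted
    correlation per gene pair.
    """
    if not -1.0 < block_correlation < 1.0:
        raise ValueError("block_correlation must be in (-1, 1)")
    if block_correlation < 0 and block_size > 2:
        # equicorrelated blocks need r >= -1/(k-1) to stay positive-definite
        if block_correlation < -1.0 / (block_size - 1):
            raise ValueError("negative block_correlation too strong for block size")
    rng = np.random.default_rng(seed)
    cov = np.eye(n_genes)
    block_of = np.arange(n_genes) // block_size
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if block_of[i] == block_of[j]:
                cov[i, j] = cov[j, i] = block_correlation
    vals = rng.multivariate_normal(np.zeros(n_genes), cov, size=n_samples,
                                   method="cholesky").T
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    rows = [
        (genes[i], genes[j],
         block_correlation if block_of[i] == block_of[j] else 0.0)
        for i in range(n_genes) for j in range(i + 1, n_genes)
    ]
    ledger = pd.DataFrame(rows, columns=["gene_a", "gene_b", "true_pcc"])
    return ExpressionMatrix(genes, samples, vals), ledger
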