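"""Gene trees from alignments or distance matrices via neighbor-joining.

Distances: uncorrected p, Jukes-Cantor (JC69) and Kimura two-parameter
(K2P), with pairwise deletion of gap/N columns.  Tree building is the
canonical Studier-Keppler O(n^3) neighbor-joining with a deterministic
lexicographic tie-break, negative branch lengths kept by default, and
column-bootstrap support.  Newick read/write round-trips the trees.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "SaturationError",
    "pairwise_distance",
    "neighbor_joining",
    "write_newick",
    "parse_newick",
    "bootstrap_support",
    "random_additive_tree",
]

_VALID = set("ACGT-N")
_PURINES = {"A", "G"}


class SaturationError(ValueError):
    """Distance undefined because the correction's log argument is <= 0."""


@dataclass
class Alignment:
    """Equal-length, uniquely labelled nucleotide records (upper-cased)."""

    records: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        self.records = [(lab, seq.upper()) for lab, seq in self.records]
        lens = {len(s) for _, s in self.records}
        if len(lens) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lens)}")
        labels = [lab for lab, _ in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in alignment")
        for lab, seq in self.records:
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"{lab}: invalid characters {sorted(bad)}")

    @property
    def labels(self) -> List[str]:
        return [lab for lab, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        return cls(recs)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(self.length, size=self.length)
        return Alignment(
            [(lab, "".join(seq[c] for c in cols)) for lab, seq in self.records]
        )


@dataclass
class DistanceMatrix:
    labels: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("non-zero diagonal")
        if (m < -1e-12).any():
            raise ValueError("negative distances")
        self.matrix = m

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        """Read a square PHYLIP distance matrix (relaxed label widths)."""
        with open(path) as fh:
            tokens = fh.read().split("\n")
        tokens = [ln for ln in tokens if ln.strip()]
        n = int(tokens[0].split()[0])
        labels, rows = [], []
        for ln in tokens[1 : 1 + n]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows))

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.matrix):
            lines.append(lab + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[int] = None
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: List[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary (trifurcating) root."""

    root: TreeNode

    @property
    def leaf_labels(self) -> List[str]:
        return [l.label for l in self.root.leaves()]

    def bipartitions(self) -> Dict[frozenset, TreeNode]:
        """Non-trivial splits, keyed by the leaf set NOT containing the
        lexicographically smallest leaf label (canonical side)."""
        all_leaves = set(self.leaf_labels)
        anchor = min(all_leaves)
        out: Dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> set:
            if node.is_leaf:
                return {node.label}
            below = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                out[frozenset(side)] = node
            return below

        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# genetic distances

def _pair_stats(s1: str, s2: str) -> Tuple[int, int, int]:
    """(comparable sites, transitions, transversions) after pairwise deletion."""
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a in "-N" or b in "-N":
            continue
        n += 1
        if a != b:
            if (a in _PURINES) == (b in _PURINES):
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def pairwise_distance(
    aln: Alignment, model: str = "p", deletion: str = "pairwise"
) -> DistanceMatrix:
    """Pairwise genetic distances under p, jc69 or k2p.

    p: mismatch fraction.  jc69: -(3/4) ln(1 - 4p/3).  k2p from the
    transition/transversion fractions P, Q:
    -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).
    ``deletion`` removes gap/N columns per pair ("pairwise", the
    default: preserves signal in sparse alignments) or once across all
    records ("complete").  Raises SaturationError naming the pair when
    a correction's log argument is non-positive, and ValueError when a
    pair shares no comparable site.
    """
    if model not in ("p", "jc69", "k2p"):
        raise ValueError(f"unknown distance model {model!r}")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    records = aln.records
    if deletion == "complete":
        keep = [
            j for j in range(aln.length)
            if all(seq[j] not in "-N" for _, seq in records)
        ]
        records = [(lab, "".join(seq[j] for j in keep)) for lab, seq in records]
    labels = aln.labels
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sites, ts, tv = _pair_stats(records[i][1], records[j][1])
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            p = (ts + tv) / sites
            if model == "p":
                dist = p
            elif model == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    raise SaturationError(
                        f"JC69 saturated for pair ({labels[i]!r}, {labels[j]!r}): p={p:.4f}"
                    )
                dist = -0.75 * math.log(arg)
            else:
                P, Q = ts / sites, tv / sites
                a1, a2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
                if a1 <= 0 or a2 <= 0:
                    raise SaturationError(
                        f"K2P saturated for pair ({labels[i]!r}, {labels[j]!r}): "
                        f"P={P:.4f} Q={Q:.4f}"
                    )
                dist = -0.5 * math.log(a1) - 0.25 * math.log(a2)
            d[i, j] = d[j, i] = dist + 0.0 if dist != 0 else 0.0
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# neighbor-joining

def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Canonical NJ (Studier-Keppler) with lexicographic tie-breaks.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j; branch
    lengths by the rate-corrected split formula.  Negative branch
    lengths are kept by default (faithful to the algorithm);
    ``clamp_negative`` zeroes them and moves the deficit to the sibling
    branch, preserving the pair's path length.  For n = 2 the single
    distance is split evenly; the returned tree carries the
    conventional trifurcating root for n >= 3.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        h = dm.matrix[0, 1] / 2.0
        return PhyloTree(
            TreeNode(children=[TreeNode(labels[0], h), TreeNode(labels[1], h)])
        )

    d = dm.matrix.copy()
    nodes = [TreeNode(lab) for lab in labels]
    canon = list(labels)  # canonical (min leaf) label per cluster, for ties

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(canon[i], canon[j]), max(canon[i], canon[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if clamp_negative:
            li, lj = _clamp_pair(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[-1, : m - 2] = dnew[keep]
        d2[: m - 2, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        canon = [canon[k] for k in keep] + [min(canon[i], canon[j])]
        d = d2

    # three clusters left: attach to the trifurcating root by the
    # three-point formulas
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = (dab + dac - dbc) / 2.0
    b.length = (dab + dbc - dac) / 2.0
    c.length = (dac + dbc - dab) / 2.0
    if clamp_negative:
        for node in (a, b, c):
            if node.length < 0:
                node.length = 0.0
    return PhyloTree(TreeNode(children=[a, b, c]))


def _clamp_pair(li: float, lj: float):
    """Zero a negative branch, shifting the deficit to its sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# Newick I/O

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def _fmt_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, decimals: int = 6) -> str:
    """Serialize with branch lengths; support values as internal labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = _fmt_label(node.label or "")
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += str(node.support)
            elif node.label:
                s += _fmt_label(node.label)
        if node.length is not None:
            s += f":{node.length:.{decimals}g}"
        return s

    return fmt(tree.root) + ";"


class _NewickParser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def error(self, msg: str):
        raise ValueError(f"newick parse error at position {self.pos}: {msg}")

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> TreeNode:
        node = self.node()
        if self.peek() != ";":
            self.error("missing trailing semicolon")
        self.pos += 1
        if self.peek():
            self.error("unexpected text after the closing semicolon")
        return node

    def node(self) -> TreeNode:
        n = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            n.children.append(self.node())
            while self.peek() == ",":
                self.pos += 1
                n.children.append(self.node())
            if self.peek() != ")":
                self.error("expected ')' or ','")
            self.pos += 1
        lab = self.label()
        if lab:
            if n.children and lab.isdigit():
                n.support = int(lab)
            else:
                n.label = lab
        if self.peek() == ":":
            self.pos += 1
            n.length = self.number()
        # collapse redundant unary nesting, summing branch lengths
        if len(n.children) == 1:
            child = n.children[0]
            if n.length is not None or child.length is not None:
                child.length = (n.length or 0.0) + (child.length or 0.0)
            if n.label and not child.label:
                child.label = n.label
            return child
        return n

    def label(self) -> str:
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    self.error("unterminated quoted label")
                ch = self.text[self.pos]
                if ch == "'":
                    if self.text[self.pos : self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(ch)
                self.pos += 1
            return "".join(out)
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in "(),:;[]":
            self.pos += 1
        return self.text[start : self.pos].strip()

    def number(self) -> float:
        self._skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos] in "+-.eE0123456789"
        ):
            self.pos += 1
        try:
            return float(self.text[start : self.pos])
        except ValueError:
            self.error("malformed branch length")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; errors report the character position."""
    return PhyloTree(_NewickParser(text).parse())


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    aln: Alignment, model: str = "jc69", B: int = 100, seed: int = 0
) -> Tuple[PhyloTree, int]:
    """Column bootstrap: support of each internal edge of the NJ tree.

    Resamples alignment columns with replacement B times, rebuilds the
    tree per replicate, and counts how many replicates contain each
    bipartition of the original tree.  Replicates whose distances are
    saturated are skipped; their count is returned alongside the tree.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tree = neighbor_joining(pairwise_distance(aln, model))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(B):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep, model))
        except (SaturationError, ValueError):
            skipped += 1
            continue
        rep_splits = rep_tree.bipartitions()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for s, node in splits.items():
        node.support = counts[s]
    return tree, skipped


# ---------------------------------------------------------------------------
# fixtures

def random_additive_tree(
    n_taxa: int, seed: int = 0
) -> Tuple[PhyloTree, DistanceMatrix]:
    """Random topology with branch lengths U[0.05, 1]; matrix = path lengths.

    The returned matrix is exactly additive, so NJ must reconstruct the
    generating topology — the standard consistency fixture.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(0.05, 1.0))

    labels = [f"t{i}" for i in range(n_taxa)]
    root = TreeNode(
        children=[TreeNode(labels[0], blen()), TreeNode(labels[1], blen()), TreeNode(labels[2], blen())]
    )
    # grow by splitting a uniformly chosen edge
    for lab in labels[3:]:
        edges = []

        def collect(node: TreeNode) -> None:
            for c in node.children:
                edges.append((node, c))
                collect(c)

        collect(root)
        parent, child = edges[rng.integers(len(edges))]
        mid = TreeNode(length=child.length / 2.0)
        child.length = child.length / 2.0
        mid.children = [child, TreeNode(lab, blen())]
        parent.children[parent.children.index(child)] = mid

    # path-length matrix
    idx = {lab: i for i, lab in enumerate(labels)}
    d = np.zeros((n_taxa, n_taxa))

    def below(node: TreeNode) -> Dict[str, float]:
        """leaf label -> path length from node."""
        if node.is_leaf:
            return {node.label: 0.0}
        out: Dict[str, float] = {}
        groups = []
        for c in node.children:
            g = {lab: dist + c.length for lab, dist in below(c).items()}
            groups.append(g)
            out.update(g)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, da in groups[gi].items():
                    for lb, db in groups[gj].items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
        return out

    below(root)
    return PhyloTree(root), DistanceMatrix(labels, d)
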