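"""Indexed region retrieval from multi-genome alignments (MAF).

A MAF file is indexed by the forward-strand coordinates of any member
genome; region queries then fetch only the overlapping blocks by byte
offset.  Neighboring blocks are chained into ortholog segments on the
query genome; when gene duplication makes several chains compete for
the same query interval, the chain covering the most query sequence
wins (synteny: the longer the query-genome segment, the more likely it
is the ortholog).  Results serialize to a JSON schema with
Ensembl-REST-like field names.

The block reader is a small hand-written scanner because the index
needs the byte offset and length of every block, which alignment
parsers do not expose; the index itself is a versioned, sorted TSV
interval table searched by bisection.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

__all__ = [
    "MafRow",
    "MafBlock",
    "GenomeIndex",
    "OrthologSegment",
    "iter_maf_blocks",
    "build_index",
    "query_region",
    "merge_and_resolve",
    "result_to_json",
    "synth_maf",
]

_INDEX_MAGIC = "#evokit-maf-index"
_INDEX_VERSION = "1"


@dataclass
class MafRow:
    src: str  # "genome.chrom"
    start: int  # strand-relative, per the MAF convention
    size: int
    strand: str  # '+' or '-'
    src_size: int
    text: str  # gapped sequence

    @property
    def genome(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]

    @property
    def fwd_start(self) -> int:
        """0-based forward-strand start (minus strands normalized)."""
        if self.strand == "+":
            return self.start
        return self.src_size - self.start - self.size

    @property
    def fwd_end(self) -> int:
        return self.fwd_start + self.size


@dataclass
class MafBlock:
    score: Optional[float]
    rows: List[MafRow]
    offset: int = 0  # byte offset of the 'a' line
    length: int = 0  # byte length of the block

    def row_for(self, genome: str) -> Optional[MafRow]:
        for r in self.rows:
            if r.genome == genome:
                return r
        return None

    def validate(self) -> None:
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"block at offset {self.offset}: unequal row widths")
        for r in self.rows:
            ungapped = len(r.text) - r.text.count("-")
            if ungapped != r.size:
                raise ValueError(
                    f"block at offset {self.offset}, row {r.src}: ungapped length "
                    f"{ungapped} != declared size {r.size}"
                )
            if r.start < 0 or r.start + r.size > r.src_size:
                raise ValueError(
                    f"block at offset {self.offset}, row {r.src}: coordinates "
                    "exceed srcSize"
                )


def _parse_block_text(text: str, offset: int = 0) -> MafBlock:
    score = None
    rows: List[MafRow] = []
    for line in text.splitlines():
        if line.startswith("a"):
            for tok in line.split()[1:]:
                if tok.startswith("score="):
                    score = float(tok[6:])
        elif line.startswith("s "):
            _, src, start, size, strand, src_size, seq = line.split()
            rows.append(MafRow(src, int(start), int(size), strand, int(src_size), seq))
    block = MafBlock(score=score, rows=rows, offset=offset, length=len(text.encode()))
    block.validate()
    return block


def iter_maf_blocks(path) -> Iterator[MafBlock]:
    """Scan a MAF file, yielding blocks with their byte offsets."""
    with open(path, "rb") as fh:
        offset = None
        buf: List[str] = []
        pos = 0
        for raw in fh:
            line = raw.decode()
            if line.startswith("a"):
                if buf:
                    blk = _parse_block_text("".join(buf), offset)
                    blk.length = pos - offset
                    yield blk
                offset = pos
                buf = [line]
            elif buf and (line.startswith("s ") or line.startswith("i ")
                          or line.startswith("e ") or line.startswith("q ")):
                buf.append(line)
            elif buf and not line.strip():
                blk = _parse_block_text("".join(buf), offset)
                blk.length = pos + len(raw) - offset
                yield blk
                buf = []
                offset = None
            pos += len(raw)
        if buf:
            blk = _parse_block_text("".join(buf), offset)
            blk.length = pos - offset
            yield blk


@dataclass
class GenomeIndex:
    """Per-chromosome sorted interval table over MAF blocks.

    Intervals are 0-based half-open on the forward strand of the query
    genome; each carries the byte offset and length of its block.
    """

    genome: str
    intervals: Dict[str, List[Tuple[int, int, int, int]]]  # chrom -> (s, e, off, len)
    n_skipped: int = 0  # blocks lacking the genome
    version: str = _INDEX_VERSION

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{_INDEX_MAGIC}\tv{self.version}\t{self.genome}\t{self.n_skipped}\n")
            for chrom in sorted(self.intervals):
                for s, e, off, ln in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{off}\t{ln}\n")

    @classmethod
    def load(cls, path) -> "GenomeIndex":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != _INDEX_MAGIC:
                raise ValueError(f"{path} is not an evokit MAF index")
            version = header[1].lstrip("v")
            genome = header[2]
            n_skipped = int(header[3]) if len(header) > 3 else 0
            intervals: Dict[str, List[Tuple[int, int, int, int]]] = {}
            for line in fh:
                chrom, s, e, off, ln = line.rstrip("\n").split("\t")
                intervals.setdefault(chrom, []).append(
                    (int(s), int(e), int(off), int(ln))
                )
        return cls(genome=genome, intervals=intervals, n_skipped=n_skipped,
                   version=version)


def build_index(maf_path, genome_id: str, index_path=None) -> GenomeIndex:
    """Index a MAF file by the coordinates of ``genome_id``.

    One interval per block containing the genome (minus-strand rows are
    normalized to the forward strand); blocks lacking the genome are
    skipped and counted.  Raises when the genome appears in no block.
    If ``index_path`` is given the index is persisted there as TSV.
    """
    intervals: Dict[str, List[Tuple[int, int, int, int]]] = {}
    skipped = 0
    for blk in iter_maf_blocks(maf_path):
        row = blk.row_for(genome_id)
        if row is None:
            skipped += 1
            continue
        intervals.setdefault(row.chrom, []).append(
            (row.fwd_start, row.fwd_end, blk.offset, blk.length)
        )
    if not intervals:
        raise ValueError(f"genome {genome_id!r} absent from all blocks of {maf_path}")
    for chrom in intervals:
        intervals[chrom].sort()
    idx = GenomeIndex(genome=genome_id, intervals=intervals, n_skipped=skipped)
    if index_path is not None:
        idx.save(index_path)
    return idx


def _fetch_block(fh, offset: int, length: int) -> MafBlock:
    fh.seek(offset)
    return _parse_block_text(fh.read(length).decode(), offset)


def query_region(
    index: GenomeIndex, maf_path, chrom: str, start: int, end: int
) -> List[MafBlock]:
    """Blocks whose query-genome interval overlaps [start, end).

    Blocks are fetched by their stored byte offsets — no full-file scan.
    An unknown chromosome yields an empty list.
    """
    if start >= end:
        raise ValueError(f"empty query interval [{start}, {end})")
    table = index.intervals.get(chrom, [])
    if not table:
        return []
    starts = [iv[0] for iv in table]
    hi = bisect.bisect_left(starts, end)
    hits = [iv for iv in table[:hi] if iv[1] > start]
    out: List[MafBlock] = []
    with open(maf_path, "rb") as fh:
        for s, e, off, ln in hits:
            out.append(_fetch_block(fh, off, ln))
    return out


@dataclass
class OrthologSegment:
    chrom: str
    start: int  # query genome, 0-based half-open, forward strand
    end: int
    blocks: List[MafBlock] = field(default_factory=list)
    coverage: int = 0  # total query-genome bases covered

    def species_coords(self, query_genome: str) -> Dict[str, Dict]:
        """Stitched per-species coordinate extents across the blocks."""
        out: Dict[str, Dict] = {}
        for blk in self.blocks:
            for r in blk.rows:
                if r.genome == query_genome:
                    continue
                cur = out.get(r.genome)
                if cur is None or cur["chrom"] == r.chrom:
                    if cur is None:
                        out[r.genome] = {
                            "chrom": r.chrom,
                            "start": r.fwd_start,
                            "end": r.fwd_end,
                            "strand": r.strand,
                        }
                    else:
                        cur["start"] = min(cur["start"], r.fwd_start)
                        cur["end"] = max(cur["end"], r.fwd_end)
        return out


def merge_and_resolve(
    blocks: List[MafBlock],
    index: GenomeIndex,
    start: int,
    end: int,
    max_gap: int = 0,
) -> List[OrthologSegment]:
    """Chain neighboring blocks and resolve duplicated chains.

    Blocks adjacent on the query genome (gap <= ``max_gap``, no
    overlap) are chained into segments.  When chains compete for
    overlapping query intervals (paralogs from gene duplication), the
    chain with the greatest total query-genome coverage is kept; ties
    go to the smaller start.
    """
    genome = index.genome
    keyed = []
    for blk in blocks:
        row = blk.row_for(genome)
        if row is None:
            continue
        keyed.append((row.fwd_start, row.fwd_end, blk))
    keyed.sort(key=lambda t: (t[0], t[1]))

    chains: List[OrthologSegment] = []
    for s, e, blk in keyed:
        best = None
        for c in chains:
            gap = s - c.end
            if 0 <= gap <= max_gap:
                if best is None or c.coverage > best.coverage or (
                    c.coverage == best.coverage and c.start < best.start
                ):
                    best = c
        if best is None:
            chains.append(
                OrthologSegment(chrom="", start=s, end=e, blocks=[blk], coverage=e - s)
            )
        else:
            best.blocks.append(blk)
            best.end = e
            best.coverage += e - s
    if not chains:
        return []
    chrom = keyed[0][2].row_for(genome).chrom
    for c in chains:
        c.chrom = chrom

    # resolve competition among chains overlapping on the query genome
    chains.sort(key=lambda c: (c.start, c.end))
    kept: List[OrthologSegment] = []
    cluster: List[OrthologSegment] = []
    cluster_end = -1

    def flush() -> None:
        if cluster:
            winner = max(cluster, key=lambda c: (c.coverage, -c.start))
            kept.append(winner)

    for c in chains:
        if cluster and c.start < cluster_end:
            cluster.append(c)
            cluster_end = max(cluster_end, c.end)
        else:
            flush()
            cluster = [c]
            cluster_end = c.end
    flush()
    kept.sort(key=lambda c: c.start)
    return kept


def _slice_block_columns(blk: MafBlock, genome: str, start: int, end: int) -> MafBlock:
    """Trim alignment columns to the query interval [start, end)."""
    qrow = blk.row_for(genome)
    keep = []
    k = 0  # ungapped position along the query row text
    for col, ch in enumerate(qrow.text):
        if ch == "-":
            continue
        fwd = qrow.fwd_start + k if qrow.strand == "+" else qrow.fwd_end - 1 - k
        if start <= fwd < end:
            keep.append(col)
        k += 1
    keep_set = set(keep)
    new_rows = []
    for r in blk.rows:
        text = "".join(c for i, c in enumerate(r.text) if i in keep_set)
        ungapped = len(text) - text.count("-")
        # strand-relative start shifts by the ungapped chars dropped on the left
        left = r.text[: min(keep) if keep else len(r.text)]
        dropped_left = len(left) - left.count("-")
        new_rows.append(
            MafRow(r.src, r.start + dropped_left, ungapped, r.strand, r.src_size, text)
        )
    return MafBlock(score=blk.score, rows=new_rows, offset=blk.offset, length=0)


def result_to_json(
    segments: List[OrthologSegment],
    query_genome: str,
    slice_to: Optional[Tuple[int, int]] = None,
    indent: Optional[int] = None,
) -> str:
    """Serialize ortholog segments to JSON.

    Schema: array of ``{query: {chrom,start,end,strand},
    species: [{genome, chrom, start, end, strand, aligned_seq}]}``.
    With ``slice_to=(start, end)`` alignment columns are trimmed to the
    query interval.  Per-species aligned sequences concatenate the
    constituent blocks in query order, padding species absent from a
    block with gap columns.
    """
    out = []
    for seg in segments:
        blocks = seg.blocks
        if slice_to is not None:
            blocks = [
                _slice_block_columns(b, query_genome, slice_to[0], slice_to[1])
                for b in blocks
            ]
        species_order: List[str] = []
        for b in blocks:
            for r in b.rows:
                if r.genome != query_genome and r.genome not in species_order:
                    species_order.append(r.genome)
        qparts = []
        parts: Dict[str, List[str]] = {g: [] for g in species_order}
        meta: Dict[str, Dict] = {}
        qmeta = None
        for b in blocks:
            qrow = b.row_for(query_genome)
            width = len(qrow.text)
            qparts.append(qrow.text)
            if qmeta is None:
                qmeta = {
                    "chrom": qrow.chrom,
                    "start": qrow.fwd_start,
                    "end": qrow.fwd_end,
                    "strand": "+",
                }
            else:
                qmeta["start"] = min(qmeta["start"], qrow.fwd_start)
                qmeta["end"] = max(qmeta["end"], qrow.fwd_end)
            for g in species_order:
                row = b.row_for(g)
                if row is None:
                    parts[g].append("-" * width)
                else:
                    parts[g].append(row.text)
                    m = meta.get(g)
                    if m is None:
                        meta[g] = {
                            "chrom": row.chrom,
                            "start": row.fwd_start,
                            "end": row.fwd_end,
                            "strand": row.strand,
                        }
                    else:
                        m["start"] = min(m["start"], row.fwd_start)
                        m["end"] = max(m["end"], row.fwd_end)
        species = [
            {
                "genome": query_genome,
                "chrom": qmeta["chrom"],
                "start": qmeta["start"],
                "end": qmeta["end"],
                "strand": "+",
                "aligned_seq": "".join(qparts),
            }
        ] + [
            {
                "genome": g,
                "chrom": meta[g]["chrom"],
                "start": meta[g]["start"],
                "end": meta[g]["end"],
                "strand": meta[g]["strand"],
                "aligned_seq": "".join(parts[g]),
            }
            for g in species_order
        ]
        out.append(
            {
                "query": {
                    "chrom": seg.chrom,
                    "start": seg.start if slice_to is None else max(seg.start, slice_to[0]),
                    "end": seg.end if slice_to is None else min(seg.end, slice_to[1]),
                    "strand": "+",
                },
                "species": species,
            }
        )
    return json.dumps(out, indent=indent)


def synth_maf(
    n_species: int = 3,
    n_blocks: int = 10,
    dup_fraction: float = 0.0,
    seed: int = 0,
    query_genome: str = "qry",
    chrom: str = "chr1",
) -> Tuple[str, Dict]:
    """Generate a consistent synthetic MAF with a truth ledger.

    Blocks tile the query genome left to right with random gaps; other
    species get random coordinates and occasional minus-strand rows.
    With probability ``dup_fraction`` a block is shadowed by a planted
    "duplicate" block whose query coverage is less than half of the
    true block's chain, and the ledger designates the true ortholog
    interval.  The ledger records every indexed interval, so it can
    serve as an oracle for ``build_index`` and ``merge_and_resolve``.
    """
    if n_species < 2:
        raise ValueError("need the query genome plus at least one other species")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    others = [f"sp{i}" for i in range(1, n_species)]
    src_sizes = {query_genome: 10_000_000}
    for g in others:
        src_sizes[g] = 10_000_000

    def seq(k: int) -> str:
        return "".join(rng.choice(bases, size=k))

    def gapped(raw: str, width: int, rng) -> str:
        """Insert gaps to pad raw to width columns."""
        n_gaps = width - len(raw)
        positions = sorted(rng.choice(width, size=n_gaps, replace=False))
        out, j = [], 0
        it = iter(raw)
        pos_set = set(positions)
        for i in range(width):
            out.append("-" if i in pos_set else next(it))
        return "".join(out)

    lines = ["##maf version=1 scoring=synthetic", ""]
    ledger: Dict = {"intervals": [], "duplications": [], "blocks": []}
    qpos = int(rng.integers(100, 1000))

    def emit_block(qstart: int, qsize: int, tag: str) -> None:
        width = qsize + int(rng.integers(0, max(2, qsize // 5)))
        rows = [f"a score={float(rng.integers(100, 9999)):.1f}"]
        qtext = gapped(seq(qsize), width, rng)
        rows.append(
            f"s {query_genome}.{chrom} {qstart} {qsize} + {src_sizes[query_genome]} {qtext}"
        )
        for g in others:
            strand = "-" if rng.random() < 0.3 else "+"
            size = qsize
            start = int(rng.integers(0, src_sizes[g] - size))
            rows.append(
                f"s {g}.chrA {start} {size} {strand} {src_sizes[g]} "
                f"{gapped(seq(size), width, rng)}"
            )
        lines.extend(rows)
        lines.append("")
        ledger["intervals"].append((qstart, qstart + qsize))
        ledger["blocks"].append({"start": qstart, "end": qstart + qsize, "tag": tag})

    for b in range(n_blocks):
        qsize = int(rng.integers(50, 200))
        emit_block(qpos, qsize, "ortholog")
        if rng.random() < dup_fraction:
            # planted paralog: overlaps the true block, < half its span
            dsize = max(5, qsize // 3)
            dstart = qpos + int(rng.integers(0, max(1, qsize - dsize)))
            emit_block(dstart, dsize, "paralog")
            ledger["duplications"].append(
                {
                    "true": (qpos, qpos + qsize),
                    "paralog": (dstart, dstart + dsize),
                }
            )
        qpos += qsize + int(rng.integers(1, 500))

    # one block without the query genome: must be skipped by the index
    width = 60
    lines.append("a score=1.0")
    for g in others:
        lines.append(
            f"s {g}.chrB {int(rng.integers(0, 1000))} {width} + {src_sizes[g]} {seq(width)}"
        )
    lines.append("")
    return "\n".join(lines), ledger
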