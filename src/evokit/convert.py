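"""File format conversion between alignment and haplotype dialects.

Supported pairs: fasta <-> phylip (relaxed PHYLIP, full names kept —
the classic 10-character truncation is deliberately disabled),
ms -> fasta (0/1 haplotypes as two-state nucleotide symbols A/T), and
ms -> vcf-lite (a minimal VCF 4.2 with haploid GT fields, positions
scaled onto an integer locus).  Lossy conversions emit warnings.
"""

from __future__ import annotations

import math
import warnings
from typing import List

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import SegSites
from .msio import read_ms_file

__all__ = ["convert_format", "ms_to_vcf_lite", "SUPPORTED_PAIRS"]

SUPPORTED_PAIRS = [
    ("fasta", "phylip"),
    ("phylip", "fasta"),
    ("ms", "fasta"),
    ("ms", "vcf-lite"),
]

_MS_SYMBOLS = {0: "A", 1: "T"}  # ancestral / derived two-state encoding


def _read_alignment(path, fmt: str) -> MultipleSeqAlignment:
    bio_fmt = "phylip-relaxed" if fmt == "phylip" else fmt
    return AlignIO.read(str(path), bio_fmt)


def _write_alignment(aln: MultipleSeqAlignment, path, fmt: str) -> None:
    bio_fmt = "phylip-relaxed" if fmt == "phylip" else fmt
    with open(path, "w") as fh:
        AlignIO.write(aln, fh, bio_fmt)


def _first_replicate(path) -> SegSites:
    reps = read_ms_file(path)
    if not reps:
        raise ValueError(f"no replicates found in ms file {path}")
    if len(reps) > 1:
        warnings.warn(
            f"{path} holds {len(reps)} replicates; converting the first only"
        )
    return reps[0]


def ms_to_fasta_records(seg: SegSites) -> List[SeqRecord]:
    return [
        SeqRecord(
            Seq("".join(_MS_SYMBOLS[int(x)] for x in row)),
            id=f"hap_{i}",
            description="",
        )
        for i, row in enumerate(seg.matrix)
    ]


def ms_to_vcf_lite(seg: SegSites, locus_length: int = 1000,
                   chrom: str = "locus") -> str:
    """Render one ms replicate as minimal VCF 4.2 with haploid GT calls.

    Positions in (0,1) scale to 1-based integers by floor(p * L) + 1
    (capped at L); collisions are nudged right to keep the file sorted
    and positions unique, with a warning.
    """
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    samples = [f"hap_{i}" for i in range(seg.n)]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={locus_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    prev = 0
    bumped = False
    for j, p in enumerate(seg.positions):
        pos = min(int(math.floor(p * locus_length)) + 1, locus_length)
        if pos <= prev:
            pos = prev + 1
            bumped = True
        prev = pos
        gts = "\t".join(str(int(x)) for x in seg.matrix[:, j])
        lines.append(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    if bumped:
        warnings.warn("position collisions after scaling; some sites nudged right")
    return "\n".join(lines) + "\n"


def convert_format(in_path, in_fmt: str, out_fmt: str, out_path,
                   locus_length: int = 1000) -> None:
    """Convert ``in_path`` to ``out_path``; see SUPPORTED_PAIRS."""
    pair = (in_fmt, out_fmt)
    if pair not in SUPPORTED_PAIRS:
        raise ValueError(
            f"unsupported conversion {in_fmt} -> {out_fmt}; supported: "
            + ", ".join(f"{a}->{b}" for a, b in SUPPORTED_PAIRS)
        )
    if pair in (("fasta", "phylip"), ("phylip", "fasta")):
        _write_alignment(_read_alignment(in_path, in_fmt), out_path, out_fmt)
    elif pair == ("ms", "fasta"):
        seg = _first_replicate(in_path)
        with open(out_path, "w") as fh:
            SeqIO.write(ms_to_fasta_records(seg), fh, "fasta")
    else:  # ms -> vcf-lite
        seg = _first_replicate(in_path)
        with open(out_path, "w") as fh:
            fh.write(ms_to_vcf_lite(seg, locus_length))
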