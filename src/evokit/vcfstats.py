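"""VCF snapshot summaries and sliding-window diversity/selection scans.

Reads VCF 4.x (plain or bgzipped) through pysam, classifies records
(biallelic SNP / indel / multiallelic / other), and computes a quick
"snapshot" (class counts, ts/tv, per-sample missingness, folded SFS)
plus sliding-window pi, Watterson's theta, Tajima's D and, with exactly
two populations, Hudson's Fst.

Coordinate convention, stated once: VCF positions are 1-based; windows
and BED output are 0-based half-open; the conversion is pos - 1.
Missing genotypes are handled by site-wise deletion (per-site
complete-case allele counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from .sumstats import neutrality_constants

__all__ = [
    "VcfRecord",
    "VcfDataset",
    "VcfSummary",
    "WindowStat",
    "read_vcf",
    "vcf_snapshot",
    "sliding_window_stats",
    "hudson_fst",
    "synth_vcf",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class VcfRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: Tuple[str, ...]
    genotypes: List[Tuple[Optional[int], ...]]  # per sample, phase-agnostic
    vclass: str  # snp | indel | multiallelic | other

    @property
    def is_biallelic_snp(self) -> bool:
        return self.vclass == "snp"


@dataclass
class VcfDataset:
    samples: List[str]
    records: List[VcfRecord]

    def class_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.records:
            out[r.vclass] = out.get(r.vclass, 0) + 1
        return out


@dataclass
class VcfSummary:
    n_records: int
    n_biallelic_snp: int
    n_indel: int
    n_multiallelic: int
    n_other: int
    n_transitions: int
    n_transversions: int
    ts_tv: Optional[float]
    missing_fraction: Dict[str, float]
    folded_sfs: List[int]  # bins 0..floor(n_hap/2), complete-call sites only


@dataclass
class WindowStat:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_variants: int  # raw variant records in the window (all classes)
    S: int  # segregating biallelic SNPs after site-wise deletion
    pi: float  # per window
    pi_per_site: float
    theta_w: float
    theta_w_per_site: float
    tajima_d: Optional[float]
    fst: Optional[float] = None


def _classify(ref: str, alts: Tuple[str, ...]) -> str:
    if not alts:
        return "other"
    if len(alts) > 1:
        return "multiallelic"
    alt = alts[0]
    if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
        return "snp"
    if len(ref) != len(alt):
        return "indel"
    return "other"


def read_vcf(path) -> VcfDataset:
    """Load a VCF 4.x file (plain text or bgzipped).

    All records are retained with class labels; downstream statistics
    use biallelic SNPs only.  Positions must be non-decreasing within a
    chromosome (sorted-input error otherwise); malformed records raise
    with the record number.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vf.header.samples)
    records: List[VcfRecord] = []
    last: Dict[str, int] = {}
    for i, rec in enumerate(vf, start=1):
        try:
            chrom = rec.chrom
            pos = rec.pos
            ref = rec.ref or ""
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            gts = [tuple(rec.samples[s].get("GT") or (None,)) for s in samples]
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{i} in {path}: {exc}") from exc
        if chrom in last and pos < last[chrom]:
            raise ValueError(
                f"unsorted input: record #{i} at {chrom}:{pos} after position "
                f"{last[chrom]}"
            )
        last[chrom] = pos
        records.append(
            VcfRecord(chrom, pos, ref.upper(), tuple(a.upper() for a in alts), gts,
                      _classify(ref.upper(), tuple(a.upper() for a in alts)))
        )
    vf.close()
    return VcfDataset(samples=samples, records=records)


def _allele_counts(rec: VcfRecord) -> Tuple[int, int]:
    """(alt allele count, called allele count) with site-wise deletion."""
    alt = called = 0
    for gt in rec.genotypes:
        for a in gt:
            if a is None:
                continue
            called += 1
            if a == 1:
                alt += 1
    return alt, called


def vcf_snapshot(ds: VcfDataset) -> VcfSummary:
    """One-glance summary: class counts, ts/tv, missingness, folded SFS."""
    counts = ds.class_counts()
    ts = tv = 0
    n_hap = 0
    for r in ds.records:
        if r.is_biallelic_snp:
            if (r.ref, r.alts[0]) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
            n_hap = max(n_hap, sum(len(g) for g in r.genotypes))
    missing = {}
    for si, s in enumerate(ds.samples):
        miss = sum(
            1 for r in ds.records if any(a is None for a in r.genotypes[si])
        )
        missing[s] = miss / len(ds.records) if ds.records else 0.0
    sfs = [0] * (n_hap // 2 + 1) if n_hap else [0]
    for r in ds.records:
        if not r.is_biallelic_snp:
            continue
        alt, called = _allele_counts(r)
        if called != n_hap:  # folded SFS over complete-call sites only
            continue
        sfs[min(alt, n_hap - alt)] += 1
    return VcfSummary(
        n_records=len(ds.records),
        n_biallelic_snp=counts.get("snp", 0),
        n_indel=counts.get("indel", 0),
        n_multiallelic=counts.get("multiallelic", 0),
        n_other=counts.get("other", 0),
        n_transitions=ts,
        n_transversions=tv,
        ts_tv=(ts / tv) if tv else None,
        missing_fraction=missing,
        folded_sfs=sfs,
    )


def _tajima_d_from_counts(n: int, S: int, pi: float) -> Optional[float]:
    if n < 2 or S == 0:
        return None
    k = neutrality_constants(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi - S / k.a1) / math.sqrt(var)


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> Optional[float]:
    """Hudson's Fst estimator for one site (Bhatia et al. form).

    Returns ``None`` when the denominator is zero (both populations
    monomorphic for the same allele).
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("allele frequencies must be in [0, 1]")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 haplotypes per population")
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        return None
    return num / den


def _hudson_components(p1, n1, p2, n2) -> Tuple[float, float]:
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def sliding_window_stats(
    ds: VcfDataset,
    window: int,
    step: int,
    pops: Optional[Dict[str, str]] = None,
) -> List[WindowStat]:
    """Sliding-window pi / theta_W / Tajima's D (and Fst with 2 pops).

    Windows tile [0, chrom_max_pos) per chromosome in 0-based half-open
    coordinates; a variant at 1-based ``pos`` belongs to every window
    covering ``pos - 1``.  Statistics use biallelic SNPs with site-wise
    deletion of missing genotypes; Tajima's D uses the nominal haploid
    sample size.  With ``pops`` mapping samples to exactly two
    populations, window Fst is the ratio of summed Hudson numerators
    over summed denominators.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    pop_of: Optional[List[Optional[str]]] = None
    pop_ids: List[str] = []
    if pops is not None:
        pop_ids = sorted(set(pops.values()))
        if len(pop_ids) != 2:
            raise ValueError(
                f"Fst needs exactly 2 populations, got {len(pop_ids)}: {pop_ids}"
            )
        pop_of = [pops.get(s) for s in ds.samples]

    by_chrom: Dict[str, List[VcfRecord]] = {}
    for r in ds.records:
        by_chrom.setdefault(r.chrom, []).append(r)

    out: List[WindowStat] = []
    for chrom, recs in by_chrom.items():
        chrom_len = max(r.pos for r in recs)  # max 1-based pos == tiled length
        start = 0
        while start < chrom_len:
            end = min(start + window, chrom_len)
            wrecs = [r for r in recs if start <= r.pos - 1 < end]
            snps = [r for r in wrecs if r.is_biallelic_snp]
            n_nominal = 0
            pi = theta_w = 0.0
            S = 0
            fst_num = fst_den = 0.0
            any_fst = False
            for r in snps:
                alt, called = _allele_counts(r)
                n_nominal = max(n_nominal, sum(len(g) for g in r.genotypes))
                if called >= 2 and 0 < alt < called:
                    S += 1
                    pi += 2.0 * alt * (called - alt) / (called * (called - 1))
                    theta_w += 1.0 / neutrality_constants(called).a1
                if pop_of is not None:
                    cnt = {p: [0, 0] for p in pop_ids}  # alt, called
                    for gi, gt in enumerate(r.genotypes):
                        p = pop_of[gi]
                        if p is None:
                            continue
                        for a in gt:
                            if a is None:
                                continue
                            cnt[p][1] += 1
                            if a == 1:
                                cnt[p][0] += 1
                    (a1c, n1c), (a2c, n2c) = cnt[pop_ids[0]], cnt[pop_ids[1]]
                    if n1c >= 2 and n2c >= 2:
                        num, den = _hudson_components(
                            a1c / n1c, n1c, a2c / n2c, n2c
                        )
                        fst_num += num
                        fst_den += den
                        any_fst = True
            span = end - start
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_variants=len(wrecs),
                    S=S,
                    pi=pi,
                    pi_per_site=pi / span,
                    theta_w=theta_w,
                    theta_w_per_site=theta_w / span,
                    tajima_d=_tajima_d_from_counts(n_nominal, S, pi),
                    fst=(fst_num / fst_den) if (any_fst and fst_den != 0) else None,
                )
            )
            start += step
    return out


def synth_vcf(
    n_samples: int,
    n_sites: int,
    chrom_len: int,
    maf_dist: str = "uniform",
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> Tuple[str, "np.ndarray"]:
    """Generate a sorted, parseable diploid VCF with a truth ledger.

    Allele frequencies are drawn from ``maf_dist`` ("uniform" on
    [0.05, 0.5] or "beta" with a U-shaped Beta(0.5, 0.5)); diploid
    genotypes are binomial draws, and genotype calls go missing
    independently at ``missing_rate``.  Returns the VCF text and a
    structured ledger array with per-site position, planted frequency,
    and realised alt/called allele counts (after missingness).
    """
    if n_samples < 1 or n_sites < 1 or chrom_len < n_sites:
        raise ValueError("need n_samples>=1, 1<=n_sites<=chrom_len")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(chrom_len, size=n_sites, replace=False)) + 1
    if maf_dist == "uniform":
        freqs = rng.uniform(0.05, 0.5, size=n_sites)
    elif maf_dist == "beta":
        freqs = rng.beta(0.5, 0.5, size=n_sites)
    else:
        raise ValueError(f"unknown maf_dist {maf_dist!r}")

    bases = ["A", "C", "G", "T"]
    samples = [f"s{i}" for i in range(n_samples)]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={chrom_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    ledger = np.zeros(
        n_sites,
        dtype=[("pos", "i8"), ("freq", "f8"), ("alt_count", "i8"), ("called", "i8")],
    )
    for i, (pos, f) in enumerate(zip(positions, freqs)):
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        gts = rng.binomial(1, f, size=(n_samples, 2))
        miss = rng.random(n_samples) < missing_rate
        fields = []
        alt_count = called = 0
        for s in range(n_samples):
            if miss[s]:
                fields.append("./.")
            else:
                a, b = int(gts[s, 0]), int(gts[s, 1])
                fields.append(f"{a}/{b}")
                alt_count += a + b
                called += 2
        ledger[i] = (pos, f, alt_count, called)
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(fields)
        )
    return "\n".join(lines) + "\n", ledger
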