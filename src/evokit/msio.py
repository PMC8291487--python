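"""Reader/writer for the classic ms-style segregating-sites text dialect.

The dialect is the familiar one: a free-form header line, then per
replicate a ``//`` separator, ``segsites: S``, ``positions: ...`` and
one 0/1 row per haplotype.  It is emitted alongside the native
structured form to ease cross-checks with external coalescent tools.
"""

from __future__ import annotations

from typing import Iterable, List, TextIO

import numpy as np

from .coalescent import SegSites

__all__ = ["write_ms", "parse_ms", "read_ms_file"]


def write_ms(
    replicates: Iterable[SegSites],
    out: TextIO,
    header: str = "evokit simulate",
    seed_line: str = "",
) -> None:
    out.write(header.rstrip("\n") + "\n")
    out.write((seed_line or "") + "\n")
    for seg in replicates:
        out.write("\n//\n")
        out.write(f"segsites: {seg.S}\n")
        if seg.S:
            out.write("positions: " + " ".join(f"{p:.6f}" for p in seg.positions) + "\n")
            for row in seg.matrix:
                out.write("".join(str(int(x)) for x in row) + "\n")


def parse_ms(text: str) -> List[SegSites]:
    """Parse ms-style text into SegSites, one per replicate."""
    lines = text.splitlines()
    reps: List[SegSites] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        while i < len(lines) and not lines[i].startswith("segsites:"):
            i += 1
        if i >= len(lines):
            break
        S = int(lines[i].split(":", 1)[1])
        i += 1
        if S == 0:
            reps.append(
                SegSites(
                    positions=np.empty(0),
                    matrix=np.zeros((0, 0), dtype=np.int8),
                    label=f"rep_{len(reps)}",
                )
            )
            continue
        while i < len(lines) and not lines[i].startswith("positions:"):
            i += 1
        if i >= len(lines):
            raise ValueError(f"replicate {len(reps)}: missing positions line")
        pos = np.array([float(x) for x in lines[i].split(":", 1)[1].split()])
        if pos.size != S:
            raise ValueError(
                f"replicate {len(reps)}: {pos.size} positions but segsites: {S}"
            )
        i += 1
        rows = []
        while i < len(lines):
            s = lines[i].strip()
            if not s or s == "//":
                break
            if not set(s) <= {"0", "1"}:
                raise ValueError(f"line {i + 1}: non-binary haplotype row {s!r}")
            if len(s) != S:
                raise ValueError(f"line {i + 1}: row length {len(s)} != segsites {S}")
            rows.append([int(c) for c in s])
            i += 1
        matrix = np.array(rows, dtype=np.int8) if rows else np.zeros((0, S), np.int8)
        reps.append(SegSites(positions=pos, matrix=matrix, label=f"rep_{len(reps)}"))
    return reps


def read_ms_file(path) -> List[SegSites]:
    with open(path) as fh:
        return parse_ms(fh.read())
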