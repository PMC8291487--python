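"""Composable demographic models for the coalescent simulator.

A model is assembled from block-like primitives: populations with
relative sizes, piecewise-constant size changes, backward-in-time
lineage merges, and per-epoch backward migration matrices.  Time is
measured in units of 4N0 generations throughout, matching the classic
``ms`` convention, and theta = 4N0*mu per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "DemographicModel",
    "SampleConfig",
    "ValidationReport",
    "validate_model",
    "load_model",
]


@dataclass(frozen=True)
class SizeChange:
    time: float
    pop: str
    size: float


@dataclass(frozen=True)
class Merge:
    """Backward in time, at ``time`` all lineages in ``source`` join ``dest``."""

    time: float
    source: str
    dest: str


@dataclass(frozen=True)
class MigrationEpoch:
    """Backward migration rates from ``start_time`` until the next epoch.

    ``rates[i][j]`` is the rate at which a lineage in population i moves
    to population j (fraction of pop i replaced from j per 4N0
    generations), indexed by population order in the model.
    """

    start_time: float
    rates: tuple  # tuple of tuples, row-major


@dataclass
class DemographicModel:
    populations: list  # list of (pop_id, relative_size)
    size_changes: list = field(default_factory=list)  # list of SizeChange
    merges: list = field(default_factory=list)  # list of Merge
    migration_epochs: list = field(default_factory=list)  # list of MigrationEpoch

    @property
    def pop_ids(self) -> list:
        return [p for p, _ in self.populations]

    def pop_index(self, pop_id: str) -> int:
        return self.pop_ids.index(pop_id)


@dataclass
class SampleConfig:
    """Sampled haplotypes: list of (pop_id, n_haplotypes, sampling_time)."""

    entries: list

    @property
    def total(self) -> int:
        return sum(n for _, n, _ in self.entries)


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _merge_time(model: DemographicModel, pop: str) -> Optional[float]:
    """Time at which ``pop`` is merged away (backward), or None."""
    times = [m.time for m in model.merges if m.source == pop]
    return min(times) if times else None


def _live_pops_at(model: DemographicModel, t: float) -> set:
    """Populations that still hold their own identity at time t (backward)."""
    live = set(model.pop_ids)
    for m in sorted(model.merges, key=lambda m: m.time):
        if m.time <= t and m.source in live:
            live.discard(m.source)
    return live


def _final_pops_connected(model: DemographicModel) -> bool:
    """After the last merge, can all remaining populations exchange lineages?

    True when a single population remains, or the final-epoch migration
    matrix connects the survivors (undirected reachability over positive
    rates).
    """
    last_t = max((m.time for m in model.merges), default=0.0)
    live = _live_pops_at(model, last_t)
    if len(live) <= 1:
        return True
    if not model.migration_epochs:
        return False
    final = max(model.migration_epochs, key=lambda e: e.start_time)
    idx = {p: model.pop_index(p) for p in live}
    # undirected connectivity over positive final-epoch rates
    adj = {p: set() for p in live}
    for a in live:
        for b in live:
            if a != b and (
                final.rates[idx[a]][idx[b]] > 0 or final.rates[idx[b]][idx[a]] > 0
            ):
                adj[a].add(b)
                adj[b].add(a)
    seen = set()
    stack = [next(iter(live))]
    while stack:
        p = stack.pop()
        if p in seen:
            continue
        seen.add(p)
        stack.extend(adj[p] - seen)
    return seen == live


def validate_model(model: DemographicModel, samples: SampleConfig) -> ValidationReport:
    """Check model invariants and sample placement; never raises."""
    rep = ValidationReport()
    ids = model.pop_ids
    if not ids:
        rep.errors.append("model has no populations")
        return rep
    if len(set(ids)) != len(ids):
        rep.errors.append("duplicate population ids")
    for pid, size in model.populations:
        if size <= 0:
            rep.errors.append(f"population {pid!r} has non-positive size {size}")
    for sc in model.size_changes:
        if sc.time < 0:
            rep.errors.append(f"size change at negative time {sc.time}")
        if sc.size <= 0:
            rep.errors.append(f"size change to non-positive size {sc.size}")
        if sc.pop not in ids:
            rep.errors.append(f"size change references unknown population {sc.pop!r}")
    for m in model.merges:
        if m.time <= 0:
            rep.errors.append(f"merge at non-positive time {m.time}")
        for p in (m.source, m.dest):
            if p not in ids:
                rep.errors.append(f"merge references unknown population {p!r}")
        if m.source == m.dest:
            rep.errors.append(f"merge of {m.source!r} into itself")
    n_pops = len(ids)
    for ep in model.migration_epochs:
        if ep.start_time < 0:
            rep.errors.append(f"migration epoch at negative time {ep.start_time}")
        rows = ep.rates
        if len(rows) != n_pops or any(len(r) != n_pops for r in rows):
            rep.errors.append("migration matrix shape does not match population count")
            continue
        for i in range(n_pops):
            for j in range(n_pops):
                if rows[i][j] < 0:
                    rep.errors.append(f"negative migration rate m[{i}][{j}]")

    if samples.total < 2:
        rep.errors.append("fewer than 2 haplotypes sampled in total")
    for pid, n, t in samples.entries:
        if n < 1:
            rep.errors.append(f"non-positive sample size for {pid!r}")
        if t < 0:
            rep.errors.append(f"negative sampling time for {pid!r}")
        if pid not in ids:
            rep.errors.append(f"sample from unknown population {pid!r}")
            continue
        mt = _merge_time(model, pid)
        if mt is not None and t >= mt:
            rep.errors.append(
                f"population not live at sampling time: {pid!r} sampled at t={t} "
                f"but merged away at t={mt}"
            )

    if rep.errors:
        return rep
    if not _final_pops_connected(model):
        rep.errors.append(
            "non-closing model: multiple populations remain with no merge or "
            "positive migration connecting them, so coalescence of all "
            "lineages is not guaranteed"
        )
    return rep


def load_model(path) -> tuple:
    """Read a declarative model file (YAML) -> (DemographicModel, SampleConfig).

    Schema::

        populations:            # required
          - {id: A, size: 1.0}
        size_changes:           # optional
          - {time: 0.5, pop: A, size: 0.2}
        merges:                 # optional
          - {time: 1.0, source: B, dest: A}
        migration_epochs:       # optional; rates row-major over population order
          - {start_time: 0.0, rates: [[0, 1.0], [1.0, 0]]}
        samples:                # required
          - {pop: A, n: 10, time: 0.0}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("model file must be a mapping")
    pops = [(str(p["id"]), float(p["size"])) for p in doc.get("populations", [])]
    scs = [
        SizeChange(float(s["time"]), str(s["pop"]), float(s["size"]))
        for s in doc.get("size_changes", []) or []
    ]
    merges = [
        Merge(float(m["time"]), str(m["source"]), str(m["dest"]))
        for m in doc.get("merges", []) or []
    ]
    epochs = [
        MigrationEpoch(float(e["start_time"]), tuple(tuple(float(x) for x in row) for row in e["rates"]))
        for e in doc.get("migration_epochs", []) or []
    ]
    model = DemographicModel(pops, scs, merges, epochs)
    samples = SampleConfig(
        [(str(s["pop"]), int(s["n"]), float(s.get("time", 0.0))) for s in doc.get("samples", [])]
    )
    return model, samples
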