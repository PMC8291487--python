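"""Neutral coalescent simulation under composable demographic models.

The simulator runs the structured coalescent backward in time: within a
population of relative size x the pairwise coalescence rate is 2/x per
unit of 4N0 generations, lineages migrate at the backward rates of the
current epoch, merges move all lineages of the source population into
the destination instantaneously, and serially sampled ("ancestral")
haplotypes enter the process at their sampling times.  Mutations are
dropped on the resulting genealogy under the infinite-sites model with
theta = 4N0*mu per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .demography import DemographicModel, SampleConfig, validate_model
from .sumstats import SummaryStats, empirical_distribution, summarize_matrix

__all__ = [
    "Genealogy",
    "SegSites",
    "ReplicateSet",
    "simulate_genealogy",
    "drop_mutations",
    "run_replicates",
]


@dataclass
class Genealogy:
    """A coalescent tree over n sampled haplotypes.

    Nodes 0..n-1 are leaves in SampleConfig order; internal nodes are
    appended as coalescences happen, so the root is node 2n-2.  Times
    are in 4N0 units; branch length = time[parent] - time[child].
    """

    n_leaves: int
    parent: np.ndarray  # int array, root has parent -1
    time: np.ndarray  # float array, node times
    leaf_pops: list  # pop_id per leaf, SampleConfig order

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def root_time(self) -> float:
        return float(self.time[self.root])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return 0.0 if p < 0 else float(self.time[p] - self.time[node])

    def total_branch_length(self) -> float:
        return sum(self.branch_length(v) for v in range(self.n_nodes - 1))

    def leaves_below(self, node: int) -> np.ndarray:
        """Boolean mask over leaves descending from ``node``."""
        children = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            children[self.parent[v]].append(v)
        mask = np.zeros(self.n_leaves, dtype=bool)
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                mask[v] = True
            else:
                stack.extend(children[v])
        return mask

    def mrca_time(self, leaf_a: int, leaf_b: int) -> float:
        anc = set()
        v = leaf_a
        while v >= 0:
            anc.add(v)
            v = int(self.parent[v])
        v = leaf_b
        while v not in anc:
            v = int(self.parent[v])
        return float(self.time[v])


@dataclass
class SegSites:
    """Segregating sites: sorted positions in (0,1) and a 0/1 matrix.

    Rows are haplotypes (SampleConfig order), columns sites; 0 encodes
    the ancestral allele.  Every column is segregating by construction.
    """

    positions: np.ndarray
    matrix: np.ndarray  # (n_haplotypes, S) int8
    label: str = "locus"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ReplicateSet:
    """Replicated simulation output with pooled empirical distributions."""

    replicates: list  # of SegSites
    genealogies: list  # of Genealogy
    stats: list  # of SummaryStats
    distributions: dict = field(default_factory=dict)


def _replicate_rng(master_seed: int, index: int) -> np.random.Generator:
    """Counter-based per-replicate stream: reproducible in isolation."""
    return np.random.default_rng([int(master_seed), int(index)])


_EV_SIZE, _EV_EPOCH, _EV_MERGE, _EV_SAMPLE = 0, 1, 2, 3


def simulate_genealogy(
    model: DemographicModel, samples: SampleConfig, seed=None
) -> Genealogy:
    """Simulate one genealogy; identical seed gives an identical tree.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Raises
    ``ValueError`` with the validation errors when the model is invalid.
    """
    report = validate_model(model, samples)
    if not report.ok:
        raise ValueError("invalid model: " + "; ".join(report.errors))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pop_ids = model.pop_ids
    n_pops = len(pop_ids)
    pidx = {p: i for i, p in enumerate(pop_ids)}
    sizes = np.array([s for _, s in model.populations], dtype=float)
    mig = np.zeros((n_pops, n_pops))
    alive_pop = np.ones(n_pops, dtype=bool)

    # leaves in SampleConfig order
    leaf_pops: list = []
    leaf_times: list = []
    for pid, n, t in samples.entries:
        leaf_pops.extend([pid] * n)
        leaf_times.extend([t] * n)
    n_leaves = len(leaf_pops)
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time_arr = np.zeros(n_nodes)
    time_arr[:n_leaves] = leaf_times

    events = []  # (time, kind_rank, payload)
    for sc in model.size_changes:
        events.append((sc.time, _EV_SIZE, sc))
    for ep in model.migration_epochs:
        events.append((ep.start_time, _EV_EPOCH, ep))
    for m in model.merges:
        events.append((m.time, _EV_MERGE, m))
    for leaf, t in enumerate(leaf_times):
        events.append((t, _EV_SAMPLE, leaf))
    events.sort(key=lambda e: (e[0], e[1]))

    lineages = [[] for _ in range(n_pops)]  # node ids per pop
    n_active = 0
    n_pending = n_leaves
    next_node = n_leaves
    t = 0.0
    ei = 0

    def apply_event(kind, payload):
        nonlocal n_active, n_pending
        if kind == _EV_SIZE:
            sizes[pidx[payload.pop]] = payload.size
        elif kind == _EV_EPOCH:
            mig[:, :] = np.asarray(payload.rates, dtype=float)
            mig[~alive_pop, :] = 0.0
            mig[:, ~alive_pop] = 0.0
        elif kind == _EV_MERGE:
            si, di = pidx[payload.source], pidx[payload.dest]
            lineages[di].extend(lineages[si])
            lineages[si] = []
            alive_pop[si] = False
            mig[si, :] = 0.0
            mig[:, si] = 0.0
        else:  # sample
            leaf = payload
            lineages[pidx[leaf_pops[leaf]]].append(leaf)
            n_active += 1
            n_pending -= 1

    # process t=0 events (initial samples, epoch 0, etc.)
    while ei < len(events) and events[ei][0] <= t:
        apply_event(events[ei][1], events[ei][2])
        ei += 1

    while n_active + n_pending > 1:
        ks = np.array([len(l) for l in lineages], dtype=float)
        coal_rates = ks * (ks - 1) / 2.0 * (2.0 / sizes)
        coal_rates[~alive_pop] = 0.0
        mig_rates = ks[:, None] * mig  # rate of a lineage i -> j
        total = coal_rates.sum() + mig_rates.sum()

        next_ev_t = events[ei][0] if ei < len(events) else np.inf
        if total <= 0:
            if not np.isfinite(next_ev_t):
                raise RuntimeError(
                    "coalescent stalled: no rates and no pending events"
                )
            t = next_ev_t
        else:
            dt = rng.exponential(1.0 / total)
            if t + dt >= next_ev_t:
                t = next_ev_t
            else:
                t += dt
                u = rng.uniform(0.0, total)
                acc = 0.0
                done = False
                for i in range(n_pops):
                    acc += coal_rates[i]
                    if u < acc:
                        a, b = rng.choice(len(lineages[i]), size=2, replace=False)
                        if a > b:
                            a, b = b, a
                        nb = lineages[i].pop(b)
                        na = lineages[i].pop(a)
                        parent[na] = next_node
                        parent[nb] = next_node
                        time_arr[next_node] = t
                        lineages[i].append(next_node)
                        next_node += 1
                        n_active -= 1
                        done = True
                        break
                if not done:
                    for i in range(n_pops):
                        for j in range(n_pops):
                            acc += mig_rates[i, j]
                            if u < acc:
                                k = rng.integers(len(lineages[i]))
                                lineages[j].append(lineages[i].pop(k))
                                done = True
                                break
                        if done:
                            break
                continue
        # we landed exactly on event time(s): apply all due events
        while ei < len(events) and events[ei][0] <= t:
            apply_event(events[ei][1], events[ei][2])
            ei += 1

    return Genealogy(n_leaves=n_leaves, parent=parent, time=time_arr, leaf_pops=leaf_pops)


def drop_mutations(
    genealogy: Genealogy, theta: float, seed=None, label: str = "locus"
) -> SegSites:
    """Drop infinite-sites mutations on the genealogy.

    Branch lengths are in 4N0-generation units, so a lineage
    accumulates mutations at rate theta = 4N0*mu per unit time: the
    count on each branch is Poisson(theta * length), which yields the
    classical E[S] = theta * H_{n-1} and E[pi] = theta under the
    constant-size model.  Each mutation receives a unique uniform
    position in (0,1); its carriers are the leaves below the branch.
    Mutations above the root do not exist, so every column is
    segregating.
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = genealogy
    positions: list = []
    cols: list = []
    for v in range(g.n_nodes - 1):  # root excluded: no branch above it
        bl = g.branch_length(v)
        k = rng.poisson(theta * bl) if bl > 0 else 0
        if k == 0:
            continue
        mask = g.leaves_below(v)
        for _ in range(k):
            positions.append(rng.uniform())
            cols.append(mask)
    if not positions:
        return SegSites(
            positions=np.empty(0),
            matrix=np.zeros((g.n_leaves, 0), dtype=np.int8),
            label=label,
        )
    pos = np.asarray(positions)
    order = np.argsort(pos, kind="stable")
    matrix = np.stack(cols, axis=1).astype(np.int8)[:, order]
    return SegSites(positions=pos[order], matrix=matrix, label=label)


def run_replicates(
    model: DemographicModel,
    samples: SampleConfig,
    theta: float,
    n_reps: int,
    seed: int,
    keep_genealogies: bool = False,
) -> ReplicateSet:
    """Run ``n_reps`` independent replicates and pool summary distributions.

    Replicate streams are derived from ``(seed, replicate_index)`` so
    any single replicate is reproducible in isolation.  Distributions
    (mean, SD, 2.5/25/50/75/97.5 percentiles) are reported for S,
    Watterson's theta, pi, Tajima's D and Fu & Li's D/D*.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    report = validate_model(model, samples)
    if not report.ok:
        raise ValueError("invalid model: " + "; ".join(report.errors))

    reps, trees, stats = [], [], []
    for r in range(n_reps):
        rng = _replicate_rng(seed, r)
        g = simulate_genealogy(model, samples, seed=rng)
        seg = drop_mutations(g, theta, seed=rng, label=f"rep_{r}")
        reps.append(seg)
        if keep_genealogies:
            trees.append(g)
        stats.append(summarize_matrix(seg.matrix, polarized=True))

    dists = {}
    for name in ("S", "theta_w", "pi", "tajima_d", "fu_li_d", "fu_li_dstar"):
        values = [getattr(s, name) for s in stats]
        try:
            dists[name] = empirical_distribution(values)
        except ValueError:
            dists[name] = None
    return ReplicateSet(replicates=reps, genealogies=trees, stats=stats, distributions=dists)
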