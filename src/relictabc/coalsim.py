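"""Backward-time structured coalescent simulator with infinite-sites mutation.

Time is measured in units of 4*N_ref generations (the ms convention).  With
k lineages in a population of relative size x, pair coalescences occur at
total rate k(k-1)/x per unit time, so two lineages in a population of
relative size 1 find their common ancestor after an Exponential(2) wait
(mean 0.5).  Migration moves single lineages between populations at rate
4*N_ref*m per lineage per unit time (matrix entries are already scaled,
i.e. entries are 4*N_ref*m).  Demographic events — population merges
(backward in time), instantaneous size changes and migration-matrix
changes — are applied at their scheduled times.

Mutations follow the infinite-sites model: Poisson(theta_locus/2 per unit
of 2*N_ref generations, i.e. theta_locus per unit of time here) mutations
on branches, each at a fresh site, giving a 0/1 derived-allele matrix;
conversion to concrete A/C/G/T sequences assigns mutated columns to
distinct positions of the locus.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import LocusAlignment, PhasedMultilocusDataset, SampleMap, SampleRecord

_NUC = "ACGT"


@dataclass(frozen=True)
class DemographicEvent:
    time: float  # units of 4*N_ref generations, backward from present
    kind: str    # 'merge' | 'size_change' | 'migration_change'
    source: int | None = None          # merge: lineages move source -> dest
    dest: int | None = None
    size: float | None = None          # size_change: new relative size of pop `source`
    matrix: np.ndarray | None = None   # migration_change: new scaled matrix


@dataclass
class DemographyProgram:
    """Backward-time demography on the 4*N_ref coalescent scale."""

    n_pops: int
    sizes: np.ndarray                 # relative sizes at time 0
    migration: np.ndarray             # scaled 4*N_ref*m, diagonal 0
    events: list[DemographicEvent] = field(default_factory=list)
    n_ref: float = 10_000.0           # diploid reference size (for unit conversion)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.migration = np.asarray(self.migration, dtype=float)
        if self.sizes.shape != (self.n_pops,) or (self.sizes <= 0).any():
            raise ValueError("sizes must be positive, one per population")
        if self.migration.shape != (self.n_pops, self.n_pops):
            raise ValueError("migration matrix shape mismatch")
        if (self.migration < 0).any() or np.diag(self.migration).any():
            raise ValueError("migration entries must be >= 0 with zero diagonal")
        times = [e.time for e in self.events]
        if any(t < 0 for t in times) or any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-negative and non-decreasing")
        merged = set()
        for e in self.events:
            if e.kind == "merge":
                if e.source in merged:
                    raise ValueError(f"population {e.source} merged twice")
                merged.add(e.source)
        if len(merged) != self.n_pops - 1:
            raise ValueError("after all merges exactly one population must remain")


@dataclass(frozen=True)
class LocusSpec:
    locus_id: str
    length_bp: int
    theta: float  # 4*N_ref*mu_g*length_bp

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass
class Genealogy:
    """Binary coalescent tree: arrays over 2n-1 nodes (leaves first)."""

    n_samples: int
    parent: np.ndarray      # parent node id, -1 at root
    node_time: np.ndarray   # coalescent time of each node (leaves at 0)
    leaf_pop: np.ndarray    # sampled population of each leaf

    @property
    def total_branch_length(self) -> float:
        p = self.parent
        has_parent = p >= 0
        return float((self.node_time[p[has_parent]] - self.node_time[has_parent.nonzero()[0]]).sum())

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    def leaf_sets(self) -> list[np.ndarray]:
        """Boolean leaf-descendant mask per node (index-aligned)."""
        n_nodes = self.parent.size
        masks = np.zeros((n_nodes, self.n_samples), dtype=bool)
        masks[np.arange(self.n_samples), np.arange(self.n_samples)] = True
        # children precede parents (nodes created in time order)
        for child in range(n_nodes - 1):
            masks[self.parent[child]] |= masks[child]
        return masks


class StrandedLineagesError(RuntimeError):
    """Lineages isolated in zero-rate populations with no future events."""


def simulate_genealogy(program: DemographyProgram, samples: list[int],
                       rng: np.random.Generator) -> Genealogy:
    """Draw one genealogy under the structured coalescent."""
    samples = list(samples)
    if len(samples) != program.n_pops:
        raise ValueError("one sample count per population required")
    n = int(sum(samples))
    if n < 2:
        raise ValueError("need >= 2 sampled lineages")

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    leaf_pop = np.repeat(np.arange(program.n_pops), samples)

    lineage_node = list(range(n))            # active lineage -> node id
    lineage_pop = list(leaf_pop)
    sizes = program.sizes.copy()
    mig = program.migration.copy()
    events = list(program.events)
    next_event = 0
    t = 0.0
    next_node = n
    active_pops = set(range(program.n_pops))

    while len(lineage_node) > 1:
        k = np.bincount(lineage_pop, minlength=program.n_pops).astype(float)
        coal = k * (k - 1) / sizes
        mig_rate = (k[:, None] * mig).sum(axis=1)
        total = coal.sum() + mig_rate.sum()
        if total <= 0:
            if next_event >= len(events):
                raise StrandedLineagesError(
                    "lineages stranded: no coalescence/migration possible and no events remain"
                )
            t = events[next_event].time
        else:
            wait = rng.exponential(1.0 / total)
            if next_event < len(events) and t + wait >= events[next_event].time:
                t = events[next_event].time
            else:
                t += wait
                u = rng.random() * total
                csum = np.cumsum(np.concatenate([coal, mig_rate]))
                choice = int(np.searchsorted(csum, u, side="right"))
                if choice < program.n_pops:  # coalescence in pop `choice`
                    members = [i for i, p in enumerate(lineage_pop) if p == choice]
                    i1, i2 = rng.choice(len(members), size=2, replace=False)
                    a, b = members[i1], members[i2]
                    node_time[next_node] = t
                    parent[lineage_node[a]] = next_node
                    parent[lineage_node[b]] = next_node
                    lineage_node[a] = next_node
                    lineage_pop[a] = choice
                    del lineage_node[b], lineage_pop[b]
                    next_node += 1
                else:  # migration out of pop `src`
                    src = choice - program.n_pops
                    members = [i for i, p in enumerate(lineage_pop) if p == src]
                    mover = members[int(rng.integers(len(members)))]
                    dest_p = mig[src] / mig[src].sum()
                    lineage_pop[mover] = int(rng.choice(program.n_pops, p=dest_p))
                continue
        # apply all events scheduled at (or before) time t
        while next_event < len(events) and events[next_event].time <= t:
            ev = events[next_event]
            next_event += 1
            if ev.kind == "merge":
                for i, p in enumerate(lineage_pop):
                    if p == ev.source:
                        lineage_pop[i] = ev.dest
                active_pops.discard(ev.source)
                mig[ev.source, :] = 0.0
                mig[:, ev.source] = 0.0
            elif ev.kind == "size_change":
                sizes[ev.source] = ev.size
            elif ev.kind == "migration_change":
                mig = np.asarray(ev.matrix, dtype=float).copy()
                for p in range(program.n_pops):
                    if p not in active_pops:
                        mig[p, :] = 0.0
                        mig[:, p] = 0.0
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
    return Genealogy(n, parent, node_time, leaf_pop)


def drop_mutations(genealogy: Genealogy, locus: LocusSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Place infinite-sites mutations; returns the (n, S) 0/1 derived matrix."""
    n_nodes = genealogy.parent.size
    has_parent = genealogy.parent >= 0
    lengths = np.zeros(n_nodes)
    lengths[has_parent] = (
        genealogy.node_time[genealogy.parent[has_parent]]
        - genealogy.node_time[has_parent]
    )
    total = lengths.sum()
    # branch lengths are in 4*N_ref units; theta/2 mutations per unit of
    # 2*N_ref generations == theta per unit here (E[S] for a pair = theta)
    n_mut = int(rng.poisson(locus.theta * total)) if total > 0 and locus.theta > 0 else 0
    if n_mut == 0:
        return np.zeros((genealogy.n_samples, 0), dtype=np.int8)
    if n_mut > locus.length_bp:
        raise RuntimeError(
            f"locus {locus.locus_id}: {n_mut} mutations exceed length {locus.length_bp} "
            "(infinite-sites sites exhausted)"
        )
    branch = rng.choice(n_nodes, size=n_mut, p=lengths / total)
    masks = genealogy.leaf_sets()
    out = np.zeros((genealogy.n_samples, n_mut), dtype=np.int8)
    for j, b in enumerate(branch):
        out[masks[b], j] = 1
    return out


def binary_to_sequences(matrix: np.ndarray, locus: LocusSpec,
                        rng: np.random.Generator) -> list[str]:
    """Concrete A/C/G/T sequences with mutated columns at distinct positions."""
    n, s = matrix.shape
    if s > locus.length_bp:
        raise RuntimeError("more segregating sites than positions")
    backbone = rng.integers(0, 4, size=locus.length_bp)
    positions = rng.choice(locus.length_bp, size=s, replace=False)
    derived = np.array([(backbone[p] + 1 + rng.integers(3)) % 4 for p in positions])
    seqs = np.tile(backbone, (n, 1))
    for j, (pos, d) in enumerate(zip(positions, derived)):
        seqs[matrix[:, j] == 1, pos] = d
    lut = np.array(list(_NUC))
    return ["".join(lut[row]) for row in seqs]


def locus_rng(seed: int, locus_index: int) -> np.random.Generator:
    """Per-locus substream; adding loci never shifts earlier loci."""
    return np.random.default_rng([int(seed), int(locus_index)])


def simulate_binary_replicate(program: DemographyProgram, samples: list[int],
                              loci: list[LocusSpec], seed: int) -> list[np.ndarray]:
    """Independent genealogy + mutations per locus; 0/1 matrices (fast path)."""
    out = []
    for i, locus in enumerate(loci):
        rng = locus_rng(seed, i)
        g = simulate_genealogy(program, samples, rng)
        out.append(drop_mutations(g, locus, rng))
    return out


def simulate_dataset(program: DemographyProgram, loci: list[LocusSpec],
                     samples: list[int], seed: int,
                     population_labels: list[tuple[str, str]] | None = None,
                     individuals_per_population: int | None = None) -> PhasedMultilocusDataset:
    """Simulate a full phased sequence dataset.

    Each sampled population contributes ``samples[p]`` haplotypes (must be
    even), paired arbitrarily into diploid individuals.  population_labels
    gives (population_code, region) per simulated population; default
    ("P0","SEA"), ("P1","NEA"), ...  When individuals_per_population is
    given, each simulated population's individuals are spread round-robin
    over that many labelled populations of the same region (sampling
    labels only; panmixia within the simulated deme).
    """
    if any(s % 2 for s in samples):
        raise ValueError("per-population haplotype counts must be even (diploids)")
    if population_labels is None:
        population_labels = [
            (f"P{p}", "SEA" if p == 0 else "NEA") for p in range(program.n_pops)
        ]
    records = []
    hap_ids: list[str] = []
    idx = 0
    for p, count in enumerate(samples):
        code, region = population_labels[p]
        n_ind = count // 2
        n_sub = individuals_per_population or 1
        for i in range(n_ind):
            sub = i % n_sub
            pop_code = code if n_sub == 1 else f"{code}{sub + 1:02d}"
            ind = f"{pop_code}_i{i // n_sub + 1}"
            lat = (30.0 if region == "SEA" else 38.0) + 0.1 * sub
            lon = 100.0 + 2.0 * sub + (20.0 if region == "NEA" else 0.0)
            records.append(SampleRecord(ind, pop_code, region, lat, lon))
            hap_ids += [f"{ind}_1", f"{ind}_2"]
            idx += 1
    sample_map = SampleMap(records)
    alignments = []
    for i, locus in enumerate(loci):
        rng = locus_rng(seed, i)
        g = simulate_genealogy(program, samples, rng)
        mat = drop_mutations(g, locus, rng)
        seqs = binary_to_sequences(mat, locus, rng)
        alignments.append(LocusAlignment(locus.locus_id, dict(zip(hap_ids, seqs))))
    return PhasedMultilocusDataset(alignments, sample_map)
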