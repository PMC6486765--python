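"""Metapopulation dynamics: N populations coupled by directed gene flow.

Populations are equal-sized and exchange zygotes each generation according
to a migration matrix ``m``, where ``m[i, j]`` is the fraction of
population ``i``'s zygote pool drawn from population ``j``. Within each
population the single-population recursion applies unchanged; migration
mixes genotype frequencies after reproduction and local release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import (
    ExtinctionError,
    GenotypeDistribution,
    ReleaseSchedule,
    Trajectory,
    initialize_population,
    next_generation,
)
from .genetics import DriveArchitecture, FitnessModel

__all__ = [
    "PopulationGraph",
    "chain_graph",
    "migrate",
    "simulate_metapopulation",
]


@dataclass(frozen=True)
class PopulationGraph:
    """Directed migration structure over ``N`` equal-sized populations.

    ``migration[i, j]`` (0-based) is the per-generation fraction of
    population ``i`` replaced by migrants from population ``j``; the
    diagonal is zero and each row sums to less than 1.
    """

    migration: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.migration, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("migration matrix must be square")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("migration matrix diagonal must be zero")
        if np.any(m < 0.0) or np.any(m >= 1.0):
            raise ValueError("migration rates must be in [0, 1)")
        if np.any(m.sum(axis=1) >= 1.0):
            raise ValueError("each row of the migration matrix must sum to < 1")
        object.__setattr__(self, "migration", m)

    @property
    def N(self) -> int:
        return self.migration.shape[0]


def chain_graph(N: int, m: float) -> PopulationGraph:
    """Populations in a line with bidirectional flow ``m`` between neighbours."""
    if N < 2:
        raise ValueError("a chain needs at least 2 populations")
    if not 0.0 <= m < 0.5:
        raise ValueError(f"per-edge migration rate must be in [0, 0.5), got {m}")
    mat = np.zeros((N, N))
    for i in range(N - 1):
        mat[i, i + 1] = m
        mat[i + 1, i] = m
    return PopulationGraph(mat)


def migrate(
    states: list[GenotypeDistribution], graph: PopulationGraph
) -> list[GenotypeDistribution]:
    """Mix genotype frequencies across populations in one migration step."""
    if len(states) != graph.N:
        raise ValueError("state count does not match graph size")
    m = graph.migration
    stay = 1.0 - m.sum(axis=1)
    out = []
    for i in range(graph.N):
        F = stay[i] * states[i].F
        for j in range(graph.N):
            if m[i, j] > 0.0:
                F = F + m[i, j] * states[j].F
        out.append(GenotypeDistribution(states[i].n, F / F.sum()))
    return out


def simulate_metapopulation(
    arch: DriveArchitecture,
    fit: FitnessModel,
    schedules: list[ReleaseSchedule],
    graph: PopulationGraph,
    generations: int,
) -> list[Trajectory]:
    """Run the coupled recursion; one trajectory per population.

    Each generation every population independently undergoes selection,
    gamete production, random union and local release, then migration mixes
    the resulting zygote pools. A population whose mean fitness hits zero
    is frozen at its last state (it still exports migrants) and a warning
    is issued; the rest of the system continues.
    """
    if len(schedules) != graph.N:
        raise ValueError("need one release schedule per population")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    states = [initialize_population(arch.n, s) for s in schedules]
    freqs = [[d.allele_frequencies()] for d in states]
    wbar = [[d.mean_fitness(fit)] for d in states]
    frozen = [False] * graph.N
    for _ in range(generations):
        stepped = []
        for i, dist in enumerate(states):
            if frozen[i]:
                stepped.append(dist)
                continue
            try:
                stepped.append(next_generation(dist, arch, fit, schedules[i]))
            except ExtinctionError:
                frozen[i] = True
                stepped.append(dist)
                warnings.warn(
                    f"population {i + 1} went extinct; its frequencies are frozen",
                    RuntimeWarning,
                    stacklevel=2,
                )
        states = migrate(stepped, graph)
        for i, dist in enumerate(states):
            freqs[i].append(dist.allele_frequencies())
            wbar[i].append(dist.mean_fitness(fit))
    return [
        Trajectory(
            n=arch.n,
            allele_freqs=np.array(freqs[i]),
            mean_fitness=np.array(wbar[i]),
            extinct=frozen[i],
        )
        for i in range(graph.N)
    ]
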