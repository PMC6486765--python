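"""Deterministic single-population recursion for daisy-drive dynamics.

The population is infinite, diploid and randomly mating; its state is the
frequency distribution over multilocus diploid genotypes. One generation is
the ordered composition

    viability selection  ->  germline conversion / gamete production
    ->  random union of gametes  ->  release injection,

with selection acting first because lethal costs (dominant-lethal cargo
resistance) remove inheriting zygotes before they reproduce.

The state is stored as a dense ``3**n x 3**n`` array ``F`` over *ordered*
haplotype pairs (symmetric, so ``F[i, j] + F[j, i]`` is the frequency of
the unordered genotype ``{i, j}``). Gamete-pool computation exploits the
chain topology: conversion at a locus depends only on that locus and the
locus driving it, so the sum over parental genotypes contracts locus by
locus, carrying a single "driver present" bit between neighbours. This
keeps six- and seven-element chains (729/2187 haplotypes) exact and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genetics import (
    Allele,
    DiploidGenotype,
    DriveArchitecture,
    FitnessModel,
    enumerate_haplotypes,
    gamete_distribution,
    genotype_fitness,
    haplotype_index,
)

__all__ = [
    "ExtinctionError",
    "ReleaseSchedule",
    "GenotypeDistribution",
    "Trajectory",
    "initialize_population",
    "apply_selection",
    "produce_gamete_pool",
    "next_generation",
    "simulate",
    "allele_frequencies",
]

_FREQ_TOL = 1e-9


class ExtinctionError(RuntimeError):
    """Raised when mean population fitness reaches zero."""


@dataclass(frozen=True)
class ReleaseSchedule:
    """Release sizes and the genotype of released organisms.

    ``initial_fraction`` is the fraction of the generation-0 population made
    up of released homozygotes; ``continuous_fraction`` is the fraction of
    every subsequent generation's zygote pool replaced by fresh releases.
    ``release_genotype`` defaults to the complete-chain drive homozygote
    (D at every locus on both haplotypes).
    """

    initial_fraction: float = 0.0
    continuous_fraction: float = 0.0
    release_genotype: DiploidGenotype | None = None

    def __post_init__(self) -> None:
        for name in ("initial_fraction", "continuous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    def release_index(self, n: int) -> int:
        """Haplotype pair index of the released genotype (homozygous)."""
        if self.release_genotype is None:
            all_d = (Allele.D,) * n
            return haplotype_index(all_d)
        h1, h2 = self.release_genotype
        if h1 != h2:
            raise ValueError("release genotype must be homozygous")
        if len(h1) != n:
            raise ValueError("release genotype length does not match chain")
        return haplotype_index(h1)


class GenotypeDistribution:
    """Frequency distribution over diploid multilocus genotypes.

    Wraps the symmetric ordered-pair array ``F`` of shape
    ``(3**n, 3**n)``; row/column indices are canonical base-3 haplotype
    indices (see :mod:`daisydrive.genetics`).
    """

    def __init__(self, n: int, F: np.ndarray):
        M = 3**n
        F = np.asarray(F, dtype=float)
        if F.shape != (M, M):
            raise ValueError(f"expected shape {(M, M)}, got {F.shape}")
        if np.any(F < -_FREQ_TOL):
            raise ValueError("negative genotype frequency")
        self.n = n
        self.F = F

    @classmethod
    def from_point_masses(
        cls, n: int, masses: Mapping[DiploidGenotype, float]
    ) -> "GenotypeDistribution":
        M = 3**n
        F = np.zeros((M, M))
        for (h1, h2), freq in masses.items():
            i, j = haplotype_index(h1), haplotype_index(h2)
            if i == j:
                F[i, i] += freq
            else:  # split an unordered genotype evenly over ordered pairs
                F[i, j] += freq / 2.0
                F[j, i] += freq / 2.0
        return cls(n, F)

    def total(self) -> float:
        return float(self.F.sum())

    def normalized(self) -> "GenotypeDistribution":
        return GenotypeDistribution(self.n, self.F / self.F.sum())

    def genotype_frequency(self, genotype: DiploidGenotype) -> float:
        """Frequency of an unordered genotype."""
        i = haplotype_index(genotype[0])
        j = haplotype_index(genotype[1])
        if i == j:
            return float(self.F[i, i])
        return float(self.F[i, j] + self.F[j, i])

    def unordered_frequencies(self) -> np.ndarray:
        """Vector over canonical unordered genotypes (i <= j, row-major)."""
        M = self.F.shape[0]
        iu, ju = np.triu_indices(M)
        sym = self.F + self.F.T
        out = sym[iu, ju]
        out[iu == ju] = np.diag(self.F)
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus allele frequencies, shape ``(n, 3)`` over (W, D, R)."""
        n = self.n
        row = self.F.sum(axis=1).reshape((3,) * n)  # marginal of haplotype 1
        col = self.F.sum(axis=0).reshape((3,) * n)
        out = np.empty((n, 3))
        for j in range(n):
            axes = tuple(k for k in range(n) if k != j)
            out[j] = (row.sum(axis=axes) + col.sum(axis=axes)) / 2.0
        return np.clip(out, 0.0, 1.0)  # shave float residue off 0/1

    def mean_fitness(self, fit: FitnessModel) -> float:
        return float((self.F * fitness_tensor(fit)).sum())


def fitness_tensor(fit: FitnessModel) -> np.ndarray:
    """Fitness of every ordered haplotype pair, shape ``(3**n, 3**n)``.

    Built as a Kronecker product of per-locus pair factors, matching the
    multiplicative dominant-cost model of :func:`genetics.genotype_fitness`.
    """
    n = fit.n
    W = np.ones((1, 1))
    for i in range(n):
        f = np.ones((3, 3))
        d = int(Allele.D)
        f[d, :] *= 1.0 - fit.element_costs[i]
        f[:, d] *= 1.0 - fit.element_costs[i]
        f[d, d] = 1.0 - fit.element_costs[i]  # cost is dominant, not additive
        if i == n - 1:
            r = int(Allele.R)
            g = np.ones((3, 3))
            g[r, :] = 1.0 - fit.cargo_resistance_cost
            g[:, r] = 1.0 - fit.cargo_resistance_cost
            f = f * g
        W = np.kron(W, f)
    return W


def _transmission_table(H: float) -> np.ndarray:
    """``t[u, a1, a2, b]``: transmit allele ``b`` from pair ``(a1, a2)``.

    ``u = 0``: plain Mendelian segregation. ``u = 1``: upstream drive
    present — the pair is converted (WW/WR -> RR; WD -> DD w.p. H else DR)
    before segregation.
    """
    from .genetics import _converted_pairs

    t = np.zeros((2, 3, 3, 3))
    for a1 in range(3):
        for a2 in range(3):
            t[0, a1, a2, a1] += 0.5
            t[0, a1, a2, a2] += 0.5
            for prob, (b1, b2) in _converted_pairs(Allele(a1), Allele(a2), H):
                t[1, a1, a2, int(b1)] += 0.5 * prob
                t[1, a1, a2, int(b2)] += 0.5 * prob
    return t


_HAS_D = np.array([[1 if (a1 == 1 or a2 == 1) else 0 for a2 in range(3)] for a1 in range(3)])


def _chain_contractable(arch: DriveArchitecture) -> bool:
    return all(src in (dst - 1, dst) for src, dst in arch.target_map.items())


def _gamete_pool_chain(F: np.ndarray, arch: DriveArchitecture) -> np.ndarray:
    """Gamete pool by locus-by-locus contraction (driver = previous or self)."""
    n = arch.n
    t = _transmission_table(arch.H)
    # one-hot "does this pair carry D" factor carried to the next locus
    E = np.zeros((3, 3, 2))
    for a1 in range(3):
        for a2 in range(3):
            E[a1, a2, _HAS_D[a1, a2]] = 1.0
    # interleave parental axes: (a1_1, a2_1, a1_2, a2_2, ...)
    Ft = np.transpose(
        F.reshape((3,) * (2 * n)), [ax for j in range(n) for ax in (j, n + j)]
    )
    G = Ft.reshape(1, 1, 3, 3, -1)  # (gamete-prefix, driver-bit, a1_j, a2_j, rest)
    ar = np.arange(3)
    for j in range(1, n + 1):
        driver = arch.driver_of(j)
        ddim = G.shape[1]
        if arch.kappa == 0 or driver is None:
            u = np.zeros((ddim, 3, 3), dtype=int)
        elif driver == j - 1:
            u = np.broadcast_to(np.arange(ddim)[:, None, None], (ddim, 3, 3))
        elif driver == j:
            u = np.broadcast_to(_HAS_D[None], (ddim, 3, 3))
        else:  # pragma: no cover - guarded by _chain_contractable
            raise NotImplementedError("driver must be previous locus or self")
        tsel = t[u, ar[None, :, None], ar[None, None, :], :]  # (d, a1, a2, b)
        L = tsel[..., None] * E[None, :, :, None, :]  # (d, a1, a2, b, e)
        G = np.einsum("udxyr,dxybe->uber", G, L)
        B = G.shape[0] * 3
        G = G.reshape(B, 2, 3, 3, -1) if j < n else G.reshape(B, 2)
    return G.sum(axis=1)


def _gamete_pool_generic(F: np.ndarray, arch: DriveArchitecture) -> np.ndarray:
    """Fallback for arbitrary target maps: sum per-genotype distributions."""
    haps = enumerate_haplotypes(arch.n)
    g = np.zeros(len(haps))
    for i, j in zip(*np.nonzero(F)):
        g += F[i, j] * gamete_distribution((haps[i], haps[j]), arch)
    return g


def initialize_population(n: int, schedule: ReleaseSchedule) -> GenotypeDistribution:
    """Mix of resident wild-type homozygotes and released drive homozygotes."""
    M = 3**n
    F = np.zeros((M, M))
    rho0 = schedule.initial_fraction
    F[0, 0] = 1.0 - rho0
    r = schedule.release_index(n)
    F[r, r] += rho0
    return GenotypeDistribution(n, F)


def apply_selection(
    dist: GenotypeDistribution, fit: FitnessModel
) -> GenotypeDistribution:
    """Viability selection: reweight genotypes by fitness and renormalize."""
    W = fitness_tensor(fit)
    F = dist.F * W
    wbar = F.sum()
    if wbar <= 0.0:
        raise ExtinctionError("mean population fitness is zero")
    return GenotypeDistribution(dist.n, F / wbar)


def produce_gamete_pool(
    dist: GenotypeDistribution, arch: DriveArchitecture
) -> np.ndarray:
    """Frequency-weighted gamete haplotype pool of the whole population."""
    if _chain_contractable(arch):
        g = _gamete_pool_chain(dist.F, arch)
    else:
        g = _gamete_pool_generic(dist.F, arch)
    return g / g.sum()


def next_generation(
    dist: GenotypeDistribution,
    arch: DriveArchitecture,
    fit: FitnessModel,
    schedule: ReleaseSchedule,
) -> GenotypeDistribution:
    """One full generation: selection, gametes, random union, release."""
    selected = apply_selection(dist, fit)
    g = produce_gamete_pool(selected, arch)
    F = np.outer(g, g)  # random union of gametes (ordered pairs)
    rho = schedule.continuous_fraction
    if rho > 0.0:
        F *= 1.0 - rho
        r = schedule.release_index(dist.n)
        F[r, r] += rho
    return GenotypeDistribution(dist.n, F)


def allele_frequencies(dist: GenotypeDistribution) -> np.ndarray:
    """Per-locus allele frequency vectors over (W, D, R)."""
    return dist.allele_frequencies()


@dataclass
class Trajectory:
    """Per-generation record of a simulation.

    ``allele_freqs[g, j, a]`` is the frequency of allele ``a`` (W=0, D=1,
    R=2) at locus ``j+1`` in generation ``g``; generation 0 is the census
    immediately after the initial release. ``mean_fitness[g]`` is the mean
    viability of generation ``g`` before selection.
    """

    n: int
    allele_freqs: np.ndarray
    mean_fitness: np.ndarray
    extinct: bool = False
    snapshots: list[tuple[int, GenotypeDistribution]] = field(default_factory=list)

    @property
    def generations(self) -> int:
        """Index of the last recorded generation."""
        return self.allele_freqs.shape[0] - 1

    def frequency(self, locus: int, allele: Allele | int) -> np.ndarray:
        """Time series of one allele's frequency at a 1-based locus."""
        if not 1 <= locus <= self.n:
            raise ValueError(f"locus {locus} outside 1..{self.n}")
        return self.allele_freqs[:, locus - 1, int(allele)]

    def cargo_frequency(self) -> np.ndarray:
        """Drive-allele frequency at the cargo (last) locus over time."""
        return self.frequency(self.n, Allele.D)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: generation, locus, allele, frequency."""
        G, n, _ = self.allele_freqs.shape
        gens = np.repeat(np.arange(G), n * 3)
        loci = np.tile(np.repeat(np.arange(1, n + 1), 3), G)
        alleles = np.tile([a.name for a in Allele], G * n)
        return pd.DataFrame(
            {
                "generation": gens,
                "locus": loci,
                "allele": alleles,
                "frequency": self.allele_freqs.ravel(),
            }
        )


def simulate(
    arch: DriveArchitecture,
    fit: FitnessModel,
    schedule: ReleaseSchedule,
    generations: int,
    snapshot_every: int | None = None,
) -> Trajectory:
    """Iterate the deterministic recursion and record allele frequencies.

    Generation 0 is the post-release census, so times-to-threshold count
    generations elapsed since release. If the population goes extinct
    (mean fitness zero) the trajectory is truncated and flagged.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if fit.n != arch.n:
        raise ValueError("fitness model and architecture disagree on n")
    dist = initialize_population(arch.n, schedule)
    freqs = [dist.allele_frequencies()]
    wbar = [dist.mean_fitness(fit)]
    snaps: list[tuple[int, GenotypeDistribution]] = []
    if snapshot_every:
        snaps.append((0, dist))
    extinct = False
    for g in range(1, generations + 1):
        try:
            dist = next_generation(dist, arch, fit, schedule)
        except ExtinctionError:
            extinct = True
            break
        freqs.append(dist.allele_frequencies())
        wbar.append(dist.mean_fitness(fit))
        if snapshot_every and g % snapshot_every == 0:
            snaps.append((g, dist))
    return Trajectory(
        n=arch.n,
        allele_freqs=np.array(freqs),
        mean_fitness=np.array(wbar),
        extinct=extinct,
        snapshots=snaps,
    )
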