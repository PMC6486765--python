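"""Alleles, haplotypes, drive architectures, germline conversion and fitness.

Each locus of a daisy-chain drive carries one of three alleles: wild-type
(W), the daisy-drive element (D), or an allele resistant to cutting by the
upstream element (R). A haplotype is an ordered tuple of alleles over the
``n`` loci of the chain; locus 1 is the base of the chain and locus ``n``
carries the cargo. Haplotypes are indexed in base-3 order (locus 1 most
significant, W=0, D=1, R=2), which fixes a canonical enumeration used
throughout the package.

Germline dynamics follow the homing model: a drive element at locus ``i``
cuts wild-type alleles at its target locus (locus ``i+1`` in a daisy chain,
itself for a standard self-propagating drive) with probability ``kappa``
(restricted to 0 or 1); a cut allele is repaired by homologous recombination
with probability ``H`` (copying the homologous allele) or by end-joining
with probability ``1 - H`` (creating an R allele). Conversion acts on the
diploid target-locus genotype before Mendelian segregation: WW -> RR,
WR -> RR, WD -> DD with probability H else DR; D/R pairs are immune.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Allele",
    "Haplotype",
    "DiploidGenotype",
    "DriveArchitecture",
    "FitnessModel",
    "enumerate_haplotypes",
    "haplotype_index",
    "haplotype_from_index",
    "locus_gamete_distribution",
    "gamete_distribution",
    "genotype_fitness",
]


class Allele(IntEnum):
    """One of the three allele states at a drive locus."""

    W = 0  # wild-type
    D = 1  # daisy-drive element
    R = 2  # drive-resistant

    def __str__(self) -> str:  # "W", not "Allele.W", in tables
        return self.name


Haplotype = tuple[Allele, ...]
DiploidGenotype = tuple[Haplotype, Haplotype]


def enumerate_haplotypes(n: int) -> list[Haplotype]:
    """All ``3**n`` haplotypes for an ``n``-locus chain in canonical order.

    Canonical order is base-3 with locus 1 most significant and W=0, D=1,
    R=2, so index 0 is the all-wild haplotype and index ``3**n - 1`` the
    all-resistant one.
    """
    if n < 1:
        raise ValueError(f"chain length must be >= 1, got {n}")
    return [tuple(Allele(a) for a in combo) for combo in product(range(3), repeat=n)]


def haplotype_index(hap: Sequence[int]) -> int:
    """Canonical base-3 index of a haplotype."""
    idx = 0
    for a in hap:
        idx = idx * 3 + int(a)
    return idx


def haplotype_from_index(idx: int, n: int) -> Haplotype:
    """Inverse of :func:`haplotype_index` for an ``n``-locus chain."""
    if not 0 <= idx < 3**n:
        raise ValueError(f"haplotype index {idx} out of range for n={n}")
    alleles = []
    for _ in range(n):
        alleles.append(Allele(idx % 3))
        idx //= 3
    return tuple(reversed(alleles))


def parse_haplotype(s: str) -> Haplotype:
    """Parse a string like ``"WDR"`` into a haplotype."""
    try:
        return tuple(Allele[ch] for ch in s.strip().upper())
    except KeyError as exc:
        raise ValueError(f"invalid allele in haplotype string {s!r}") from exc


def format_genotype(genotype: DiploidGenotype) -> str:
    """Render a diploid genotype as e.g. ``"WDR/WDD"`` (canonical order)."""
    h1, h2 = sorted(genotype, key=haplotype_index)
    return "".join(a.name for a in h1) + "/" + "".join(a.name for a in h2)


@dataclass(frozen=True)
class DriveArchitecture:
    """Topology and germline parameters of a drive system.

    Parameters
    ----------
    n : int
        Number of loci. Locus ``n`` carries the cargo.
    target_map : mapping of int to int
        ``target_map[i] = j`` means the element at locus ``i`` cuts
        wild-type alleles at locus ``j``. A daisy chain has
        ``target_map[i] = i + 1`` for ``i < n``; a standard drive is a
        single self-targeting locus (``{1: 1}``). Loci are 1-based.
    H : float
        Homing efficiency: probability a cut allele is repaired by
        homologous recombination (copying the drive) rather than
        end-joining (creating an R allele).
    kappa : int
        Cut probability, restricted to 0 (no cutting; Mendelian
        comparator) or 1 (certain cutting).
    """

    n: int
    target_map: Mapping[int, int] = field(default_factory=dict)
    H: float = 1.0
    kappa: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"chain length must be >= 1, got {self.n}")
        if not 0.0 <= self.H <= 1.0:
            raise ValueError(f"homing efficiency H must be in [0, 1], got {self.H}")
        if self.kappa not in (0, 1):
            raise ValueError(
                f"cut probability kappa must be 0 or 1, got {self.kappa!r}; "
                "intermediate cut probabilities are not modeled"
            )
        for src, dst in self.target_map.items():
            if not (1 <= src <= self.n and 1 <= dst <= self.n):
                raise ValueError(
                    f"target_map entry {src}->{dst} outside loci 1..{self.n}"
                )
        object.__setattr__(self, "target_map", dict(self.target_map))

    def driver_of(self, locus: int) -> int | None:
        """The locus whose element targets ``locus``, or None if untargeted."""
        for src, dst in self.target_map.items():
            if dst == locus:
                return src
        return None


@dataclass(frozen=True)
class FitnessModel:
    """Dominant, multiplicative fitness costs of drive and resistance alleles.

    Each drive element confers a dominant cost ``element_costs[i-1]`` on any
    carrier (one or two D copies at locus ``i``). Resistance is neutral at
    every upstream locus but costs ``cargo_resistance_cost`` (``s``) at the
    cargo locus; ``s = 1`` is dominant lethality, the intended design when
    the cargo targets a haploinsufficient essential gene and carries a
    recoded rescue copy. Costs combine multiplicatively across loci.
    """

    element_costs: tuple[float, ...]
    cargo_resistance_cost: float = 1.0

    def __post_init__(self) -> None:
        costs = tuple(float(c) for c in self.element_costs)
        object.__setattr__(self, "element_costs", costs)
        for c in costs:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"element cost {c} outside [0, 1]")
        if not 0.0 <= self.cargo_resistance_cost <= 1.0:
            raise ValueError(
                f"cargo resistance cost {self.cargo_resistance_cost} outside [0, 1]"
            )

    @property
    def n(self) -> int:
        return len(self.element_costs)

    @classmethod
    def daisy(
        cls, n: int, cargo_cost: float, upstream_cost: float, s: float = 1.0
    ) -> "FitnessModel":
        """Uniform upstream costs ``d`` plus a cargo cost ``c`` at locus n."""
        return cls(
            element_costs=(upstream_cost,) * (n - 1) + (cargo_cost,),
            cargo_resistance_cost=s,
        )


def _has_d(pair: Iterable[int]) -> bool:
    return any(int(a) == Allele.D for a in pair)


def _converted_pairs(
    a1: Allele, a2: Allele, H: float
) -> list[tuple[float, tuple[Allele, Allele]]]:
    """Outcomes of germline conversion of a cut target-locus genotype.

    Returns ``(probability, converted pair)`` tuples. WW and WR become RR
    (both W copies cut, no drive template); WD is repaired off the drive
    template with probability H (-> DD) else end-joined (-> DR); pairs
    without W are immune.
    """
    pair = frozenset((int(a1), int(a2)))
    W, D, R = Allele.W, Allele.D, Allele.R
    if pair == {int(W)}:  # WW
        return [(1.0, (R, R))]
    if pair == {int(W), int(R)}:  # WR
        return [(1.0, (R, R))]
    if pair == {int(W), int(D)}:  # WD
        return [(H, (D, D)), (1.0 - H, (D, R))]
    return [(1.0, (Allele(a1), Allele(a2)))]


def locus_gamete_distribution(
    genotype: DiploidGenotype, locus: int, arch: DriveArchitecture
) -> np.ndarray:
    """Transmission probabilities of W, D, R from one locus of a genotype.

    Cutting at ``locus`` is active when ``kappa = 1`` and the locus that
    targets it carries at least one D allele (a dominant, trans-acting
    requirement — the nuclease and guide RNAs act in trans in the germline).
    When active, the target-locus diploid genotype is converted before
    Mendelian segregation; otherwise segregation is plain Mendelian.
    """
    h1, h2 = genotype
    n = arch.n
    if len(h1) != n or len(h2) != n:
        raise ValueError("genotype length does not match architecture")
    if not 1 <= locus <= n:
        raise ValueError(f"locus {locus} outside 1..{n}")
    a1, a2 = h1[locus - 1], h2[locus - 1]
    driver = arch.driver_of(locus)
    active = (
        arch.kappa == 1
        and driver is not None
        and _has_d((h1[driver - 1], h2[driver - 1]))
    )
    out = np.zeros(3)
    if not active:
        out[int(a1)] += 0.5
        out[int(a2)] += 0.5
        return out
    for prob, (b1, b2) in _converted_pairs(a1, a2, arch.H):
        out[int(b1)] += 0.5 * prob
        out[int(b2)] += 0.5 * prob
    return out


def gamete_distribution(
    genotype: DiploidGenotype, arch: DriveArchitecture
) -> np.ndarray:
    """Probability vector over all ``3**n`` gamete haplotypes.

    Loci are unlinked, so the probability of a gamete haplotype is the
    product of its per-locus transmission probabilities.
    """
    per_locus = [
        locus_gamete_distribution(genotype, j, arch) for j in range(1, arch.n + 1)
    ]
    out = per_locus[0]
    for vec in per_locus[1:]:
        out = np.outer(out, vec).ravel()
    return out


def genotype_fitness(genotype: DiploidGenotype, fit: FitnessModel) -> float:
    """Multiplicative dominant fitness of a diploid genotype.

    A genotype pays ``1 - c_i`` for carrying at least one D at locus ``i``
    and ``1 - s`` for carrying at least one R at the cargo locus; upstream
    resistance is neutral. Heterozygotes pay the full cost (complete
    dominance) and costs across loci multiply (independence).
    """
    h1, h2 = genotype
    n = fit.n
    if len(h1) != n or len(h2) != n:
        raise ValueError("genotype length does not match fitness model")
    w = 1.0
    for i in range(n):
        if h1[i] == Allele.D or h2[i] == Allele.D:
            w *= 1.0 - fit.element_costs[i]
    if h1[n - 1] == Allele.R or h2[n - 1] == Allele.R:
        w *= 1.0 - fit.cargo_resistance_cost
    return w
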