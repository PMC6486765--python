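"""Preset architectures and scenario configurations.

Three release strategies are provided as architecture builders:

* :func:`daisy_architecture` — an ``n``-element daisy chain in which each
  element drives the next and the terminal cargo element drives nothing.
* :func:`standard_drive_architecture` — a single self-targeting locus, the
  classic self-propagating homing drive. Multi-gRNA targeting of an
  essential gene is approximated by dominant-lethal resistance (``s = 1``):
  end-joining products disrupt the essential gene and are removed, so no
  functional resistant class accumulates.
* :func:`inundative_architecture` — the same single-locus construct with
  cutting switched off, so the engineered allele is inherited Mendelian-ly
  and subject only to its fitness cost.

:class:`ScenarioConfig` bundles an architecture with fitness costs, release
schedules, an optional population graph and a horizon, and round-trips
through plain dictionaries (YAML/JSON-friendly). Named presets reproduce
the published figure parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

from .dynamics import ReleaseSchedule, Trajectory, simulate
from .genetics import DriveArchitecture, FitnessModel
from .metapop import PopulationGraph, chain_graph, simulate_metapopulation

__all__ = [
    "daisy_architecture",
    "standard_drive_architecture",
    "inundative_architecture",
    "ScenarioConfig",
    "preset",
    "PRESET_NAMES",
]

CONFIG_SCHEMA_VERSION = 1


def daisy_architecture(n: int, H: float) -> DriveArchitecture:
    """Daisy chain of ``n`` unlinked elements; locus i drives locus i+1."""
    return DriveArchitecture(
        n=n, target_map={i: i + 1 for i in range(1, n)}, H=H, kappa=1
    )


def standard_drive_architecture(H: float) -> DriveArchitecture:
    """Single-locus self-propagating drive (self-targeting, certain cutting)."""
    return DriveArchitecture(n=1, target_map={1: 1}, H=H, kappa=1)


def inundative_architecture() -> DriveArchitecture:
    """Non-driving engineered allele: no cutting, purely Mendelian."""
    return DriveArchitecture(n=1, target_map={}, H=1.0, kappa=0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one simulation run.

    ``kind`` selects the architecture: ``"daisy"`` (chain length ``n``),
    ``"standard"`` (self-propagating single locus) or ``"inundative"``
    (non-driving release). All fractions are proportions, not percents.
    For a metapopulation run set ``n_populations >= 2``; releases then
    apply to ``release_population`` (1-based) only.
    """

    name: str = "custom"
    kind: str = "daisy"
    n: int = 3
    H: float = 0.95
    cargo_cost: float = 0.10
    upstream_cost: float = 0.0001
    cargo_resistance_cost: float = 1.0
    initial_release: float = 0.01
    continuous_release: float = 0.0
    generations: int = 100
    n_populations: int = 1
    migration_rate: float = 0.0
    release_population: int = 1
    snapshot_every: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("daisy", "standard", "inundative"):
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if self.kind in ("standard", "inundative") and self.n != 1:
            raise ValueError(f"{self.kind} architecture requires n=1")
        if not 1 <= self.release_population <= self.n_populations:
            raise ValueError("release_population outside 1..n_populations")

    # -- model objects -------------------------------------------------
    def architecture(self) -> DriveArchitecture:
        if self.kind == "daisy":
            return daisy_architecture(self.n, self.H)
        if self.kind == "standard":
            return standard_drive_architecture(self.H)
        return inundative_architecture()

    def fitness(self) -> FitnessModel:
        if self.n == 1:
            return FitnessModel(
                element_costs=(self.cargo_cost,),
                cargo_resistance_cost=self.cargo_resistance_cost,
            )
        return FitnessModel.daisy(
            self.n, self.cargo_cost, self.upstream_cost, self.cargo_resistance_cost
        )

    def schedule(self) -> ReleaseSchedule:
        return ReleaseSchedule(self.initial_release, self.continuous_release)

    def schedules(self) -> list[ReleaseSchedule]:
        out = [ReleaseSchedule() for _ in range(self.n_populations)]
        out[self.release_population - 1] = self.schedule()
        return out

    def graph(self) -> PopulationGraph | None:
        if self.n_populations == 1:
            return None
        return chain_graph(self.n_populations, self.migration_rate)

    def run(self) -> Trajectory | list[Trajectory]:
        """Simulate; a single Trajectory, or one per population if coupled."""
        arch, fit = self.architecture(), self.fitness()
        if self.n_populations == 1:
            return simulate(
                arch, fit, self.schedule(), self.generations,
                snapshot_every=self.snapshot_every,
            )
        return simulate_metapopulation(
            arch, fit, self.schedules(), self.graph(), self.generations
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = {"schema_version": CONFIG_SCHEMA_VERSION}
        for f in self.__dataclass_fields__:
            d[f] = getattr(self, f)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        version = d.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def with_overrides(self, **kwargs: Any) -> "ScenarioConfig":
        return replace(self, **kwargs)


_PRESETS: dict[str, ScenarioConfig] = {
    # Single-population three-element chain at 95% / 60% homing.
    "fig2b_left": ScenarioConfig(
        name="fig2b_left", kind="daisy", n=3, H=0.95, cargo_cost=0.08,
        upstream_cost=0.0001, initial_release=0.02, generations=100,
    ),
    "fig2b_center": ScenarioConfig(
        name="fig2b_center", kind="daisy", n=3, H=0.60, cargo_cost=0.08,
        upstream_cost=0.0001, initial_release=0.02, generations=100,
    ),
    "fig2b_right": ScenarioConfig(
        name="fig2b_right", kind="daisy", n=3, H=0.60, cargo_cost=0.08,
        upstream_cost=0.0001, initial_release=0.15, generations=100,
    ),
    # Long chains, small single or continuous releases.
    "fig3a": ScenarioConfig(
        name="fig3a", kind="daisy", n=6, H=0.95, cargo_cost=0.10,
        upstream_cost=0.0001, initial_release=0.01, generations=100,
    ),
    "fig3b": ScenarioConfig(
        name="fig3b", kind="daisy", n=6, H=0.95, cargo_cost=0.10,
        upstream_cost=0.0001, initial_release=0.01, continuous_release=0.01,
        generations=100,
    ),
    # Five-population chain comparators.
    "fig4_daisy": ScenarioConfig(
        name="fig4_daisy", kind="daisy", n=3, H=0.80, cargo_cost=0.10,
        upstream_cost=0.0001, initial_release=0.15, generations=500,
        n_populations=5, migration_rate=0.01,
    ),
    "fig4_standard": ScenarioConfig(
        name="fig4_standard", kind="standard", n=1, H=0.80, cargo_cost=0.10,
        initial_release=0.15, generations=500, n_populations=5,
        migration_rate=0.01,
    ),
    "fig4_inundative": ScenarioConfig(
        name="fig4_inundative", kind="inundative", n=1, cargo_cost=0.10,
        initial_release=0.999, generations=500, n_populations=5,
        migration_rate=0.01,
    ),
    # Base point for the persistence-above-50% parameter sweep: chosen so
    # the cargo clears 50% across the swept neighbourhoods of each
    # parameter (strong homing, generous release).
    "s4_persistence": ScenarioConfig(
        name="s4_persistence", kind="daisy", n=3, H=0.95, cargo_cost=0.10,
        upstream_cost=0.0001, initial_release=0.20, generations=500,
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> ScenarioConfig:
    """A named, fully populated scenario configuration."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
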