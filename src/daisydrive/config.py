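"""Configuration files, tabular output and run manifests.

Configs are YAML (JSON is a YAML subset, so both parse). All rate-like
fields are proportions by default; a top-level ``units: percent`` key lets
captions quoted in percent (e.g. a "0.01%" upstream cost) be entered
verbatim, preventing the percent/proportion footgun.
"""

from __future__ import annotations

import json
import datetime as _dt
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dynamics import GenotypeDistribution, Trajectory
from .genetics import enumerate_haplotypes
from .metapop import PopulationGraph
from .metrics import SweepResult
from .scenarios import ScenarioConfig

__all__ = [
    "load_config",
    "save_config",
    "read_migration_matrix",
    "trajectory_frame",
    "write_trajectories",
    "write_snapshots",
    "write_manifest",
]

_PERCENT_FIELDS = (
    "H",
    "cargo_cost",
    "upstream_cost",
    "cargo_resistance_cost",
    "initial_release",
    "continuous_release",
    "migration_rate",
)


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse a YAML/JSON scenario configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    units = raw.pop("units", "proportion")
    if units not in ("proportion", "percent"):
        raise ValueError(f"units must be 'proportion' or 'percent', got {units!r}")
    if units == "percent":
        for key in _PERCENT_FIELDS:
            if key in raw:
                raw[key] = raw[key] / 100.0
    return ScenarioConfig.from_dict(raw)


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Serialize a configuration (always in proportion units)."""
    d = cfg.to_dict()
    d["units"] = "proportion"
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_migration_matrix(path: str | Path) -> PopulationGraph:
    """Read an N x N tab-separated migration matrix (no header)."""
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    return PopulationGraph(m)


def trajectory_frame(trajectories: Trajectory | list[Trajectory]) -> pd.DataFrame:
    """Long-format allele-frequency table, with a population column when
    more than one trajectory is given."""
    if isinstance(trajectories, Trajectory):
        return trajectories.to_frame()
    frames = []
    for i, traj in enumerate(trajectories, start=1):
        df = traj.to_frame()
        df.insert(0, "population", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_trajectories(
    trajectories: Trajectory | list[Trajectory], path: str | Path
) -> None:
    trajectory_frame(trajectories).to_csv(path, sep="\t", index=False)


def write_snapshots(traj: Trajectory, path: str | Path, min_freq: float = 1e-12) -> None:
    """Genotype-distribution snapshots as (generation, genotype, frequency)."""
    rows = []
    for gen, dist in traj.snapshots:
        rows.extend(
            (gen, name, freq) for name, freq in _genotype_rows(dist, min_freq)
        )
    pd.DataFrame(rows, columns=["generation", "genotype", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def _genotype_rows(dist: GenotypeDistribution, min_freq: float):
    haps = enumerate_haplotypes(dist.n)
    sym = dist.F + dist.F.T
    M = len(haps)
    for i in range(M):
        for j in range(i, M):
            freq = dist.F[i, i] if i == j else sym[i, j]
            if freq > min_freq:
                name = "".join(a.name for a in haps[i]) + "/" + "".join(
                    a.name for a in haps[j]
                )
                yield name, freq


def write_sweep(result: SweepResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_manifest(
    cfg: ScenarioConfig,
    outputs: list[str | Path],
    path: str | Path,
    extra: dict[str, Any] | None = None,
) -> None:
    """JSON manifest: fully resolved config (defaults included), version,
    timestamp and output inventory — enough to reproduce a run bit-exactly."""
    try:
        tool_version = _pkg_version("daisydrive")
    except Exception:  # not installed (e.g. run from a source tree)
        tool_version = "unknown"
    manifest = {
        "tool": "daisydrive",
        "version": tool_version,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": cfg.to_dict(),
        "outputs": [str(p) for p in outputs],
        "seeds": {},  # the deterministic engine uses no randomness
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
        fh.write("\n")
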