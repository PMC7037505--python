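"""Configuration schema: one document resolving every model parameter.

A run is fully described by five blocks — ``economics`` (group1/group2),
``policy``, ``network``, ``simulation`` and an optional ``sweep`` — in a
single YAML or JSON file.  Loading fills every omitted key with the
packaged defaults (the expert-elicited reference economics, the midpoint
policy profile, a 200-node small-world network, 20 rounds x 200
repetitions at noise k = 1) and rejects unknown keys by name, so the
resolved configuration echoed into result files is complete and
unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .abm import SimConfig
from .network import NetworkSpec
from .payoffs import GroupEconomics, PolicyParams

__all__ = ["ResolvedConfig", "load_config", "dump_config", "DEFAULT_GRIDS"]

# Policy grids used in the packaged sweep experiments.
DEFAULT_GRIDS: dict[str, tuple[float, ...]] = {
    "beta": (0.05, 0.25, 0.45, 0.65, 0.85),
    "theta": (0.05, 0.25, 0.45, 0.65, 0.85),
    "delta": (0.1, 0.2, 0.3, 0.4, 0.5),
    "epsilon": (0.9, 0.8, 0.7, 0.6, 0.5),
    "eta": (0.9, 0.8, 0.7, 0.6, 0.5),
}


@dataclass(frozen=True)
class ResolvedConfig:
    """Fully resolved run configuration with every default filled in."""

    econ1: GroupEconomics
    econ2: GroupEconomics
    policy: PolicyParams
    network: NetworkSpec
    simulation: SimConfig
    sweep_parameter: str | None = None
    sweep_grid: tuple[float, ...] | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "economics": {"group1": asdict(self.econ1), "group2": asdict(self.econ2)},
            "policy": asdict(self.policy),
            "network": asdict(self.network),
            "simulation": asdict(self.simulation),
        }
        if self.sweep_parameter is not None:
            out["sweep"] = {
                "parameter": self.sweep_parameter,
                "grid": list(self.sweep_grid or ()),
            }
        return out

    def replace(self, **changes) -> "ResolvedConfig":
        return dataclasses.replace(self, **changes)


def _build(cls, block: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in '{where}'; valid keys: {sorted(known)}"
        )
    try:
        return cls(**block)
    except ValueError as exc:
        raise ValueError(f"invalid value in '{where}': {exc}") from exc


def from_dict(data: dict | None) -> ResolvedConfig:
    """Resolve a (possibly partial) config mapping against the defaults."""
    data = dict(data or {})
    top_known = {"economics", "policy", "network", "simulation", "sweep"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(
            f"unknown top-level key(s) {sorted(unknown)}; valid keys: {sorted(top_known)}"
        )
    econ_block = dict(data.get("economics") or {})
    unknown = set(econ_block) - {"group1", "group2"}
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in 'economics'; valid keys: "
            f"['group1', 'group2']"
        )
    econ1 = _build(GroupEconomics, dict(econ_block.get("group1") or {}), "economics.group1")
    econ2 = _build(GroupEconomics, dict(econ_block.get("group2") or {}), "economics.group2")
    policy = _build(PolicyParams, dict(data.get("policy") or {}), "policy")
    network = _build(NetworkSpec, dict(data.get("network") or {}), "network")
    simulation = _build(SimConfig, dict(data.get("simulation") or {}), "simulation")

    sweep_parameter = None
    sweep_grid = None
    sweep_block = data.get("sweep")
    if sweep_block is not None:
        sweep_block = dict(sweep_block)
        unknown = set(sweep_block) - {"parameter", "grid"}
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in 'sweep'; valid keys: "
                f"['parameter', 'grid']"
            )
        sweep_parameter = sweep_block.get("parameter")
        if sweep_parameter not in DEFAULT_GRIDS and sweep_parameter != "alpha":
            raise ValueError(
                f"sweep.parameter must be one of "
                f"{sorted(DEFAULT_GRIDS) + ['alpha']}, got {sweep_parameter!r}"
            )
        grid = sweep_block.get("grid", DEFAULT_GRIDS.get(sweep_parameter))
        if grid is None or len(grid) < 2:
            raise ValueError("sweep.grid must list at least 2 values")
        sweep_grid = tuple(float(v) for v in grid)
        for v in sweep_grid:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"sweep.grid values must be in [0, 1], got {v!r}")
    return ResolvedConfig(
        econ1=econ1,
        econ2=econ2,
        policy=policy,
        network=network,
        simulation=simulation,
        sweep_parameter=sweep_parameter,
        sweep_grid=sweep_grid,
    )


def load_config(path: str | Path | None = None) -> ResolvedConfig:
    """Load a YAML/JSON configuration file (or the pure defaults).

    Every omitted key takes its packaged default; unknown keys are
    rejected with an error naming the key and the valid alternatives.
    """
    if path is None:
        return from_dict({})
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return from_dict(data)


def dump_config(cfg: ResolvedConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML (round-trips exactly)."""
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
    else:
        p.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
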