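"""Configuration schema and loader.

A run configuration is a YAML (or JSON) document with four blocks —
``kinetics``, ``process``, ``costs`` (optional), ``experiments``
(optional) — plus ``output_dir`` and ``seed``.  Loading validates every
module-level invariant up front and rejects unknown keys so that typos
fail loudly rather than silently falling back to defaults.

The bundled fixture ``optimal_50L`` encodes the optimized 50 L reference
scenario: the level-sensor settings and influent concentrations found by
the two-round grid search, the *E. coli* reference kinetics and the
standard cost rates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .economics import CostModel
from .kinetics import (
    DiscretizedInfection,
    InfectionResponse,
    KineticParameters,
    build_discretization,
    loglinear_infection_response,
)
from .process import ProcessSpec, ReactorSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "load_example_config", "example_config_path"]


class ConfigError(ValueError):
    """A configuration value violates the schema; the message names the
    offending field and the constraint."""


def _take(block: Mapping[str, Any], allowed: dict[str, Any], context: str) -> dict[str, Any]:
    """Extract ``allowed`` keys (with defaults) and reject anything else."""
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
    out = dict(allowed)
    out.update(block)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration assembled from a config file."""

    params: KineticParameters
    response: InfectionResponse
    disc: DiscretizedInfection
    process: ProcessSpec
    costs: CostModel | None
    experiments: dict[str, Any]
    output_dir: Path
    seed: int
    solver: dict[str, float]

    def describe(self) -> dict[str, Any]:
        """Flat, JSON-serializable echo of every effective setting."""
        return {
            "kinetics": dataclasses.asdict(self.params),
            "discretization": {"M": self.disc.M, "N": self.disc.N},
            "process": {
                "scf": dataclasses.asdict(self.process.scf),
                "sci": dataclasses.asdict(self.process.sci),
                "cycle_time": self.process.cycle_time,
                "n_cycles": self.process.n_cycles,
                "initial_inoculum": self.process.initial_inoculum,
                "initial_phage": self.process.initial_phage,
            },
            "costs": dataclasses.asdict(self.costs) if self.costs else None,
            "experiments": self.experiments,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "solver": self.solver,
        }


def _parse_reactor(block: Mapping[str, Any], context: str, needs_mls: bool) -> ReactorSpec:
    allowed: dict[str, Any] = {"hls": None, "lls": None, "influent_substrate": None}
    if needs_mls:
        allowed["mls"] = None
    vals = _take(block, allowed, context)
    for key in ("hls", "lls", "influent_substrate"):
        if vals[key] is None:
            raise ConfigError(f"{context}: missing required key '{key}'")
    try:
        return ReactorSpec(
            hls=float(vals["hls"]),
            lls=float(vals["lls"]),
            influent_substrate=float(vals["influent_substrate"]),
            mls=float(vals["mls"]) if needs_mls and vals.get("mls") is not None else None,
        )
    except ValueError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def parse_config(doc: Mapping[str, Any], base_dir: Path | None = None) -> RunConfig:
    """Validate a parsed configuration mapping into a :class:`RunConfig`."""
    top = _take(
        doc,
        {
            "kinetics": {},
            "process": None,
            "costs": None,
            "experiments": {},
            "output_dir": "runs",
            "seed": 0,
            "solver": {},
        },
        "config",
    )

    kin = _take(
        top["kinetics"] or {},
        {
            "mu_max": 0.7726,
            "Km": 0.0727,
            "e": 1e-6,
            "dX": 0.0,
            "dP": 0.0,
            "M": 10,
            "N": 50,
            "response": {},
        },
        "kinetics",
    )
    try:
        params = KineticParameters(
            mu_max=float(kin["mu_max"]),
            Km=float(kin["Km"]),
            e=float(kin["e"]),
            dX=float(kin["dX"]),
            dP=float(kin["dP"]),
        )
    except ValueError as exc:
        raise ConfigError(f"kinetics: {exc}") from exc
    resp_block = _take(
        kin["response"] or {},
        {
            "ki_at_zero": 1e-9,
            "ki_at_max": 1e-7,
            "latent_at_zero": 0.8,
            "latent_at_max": 0.4,
            "burst_at_max": 90.0,
        },
        "kinetics.response",
    )
    try:
        response = loglinear_infection_response(
            params.mu_max, **{k: float(v) for k, v in resp_block.items()}
        )
        M, N = int(kin["M"]), int(kin["N"])
        disc = build_discretization(response, M, N)
    except ValueError as exc:
        raise ConfigError(f"kinetics.response: {exc}") from exc

    if top["process"] is None:
        raise ConfigError("config: missing required block 'process'")
    proc = _take(
        top["process"],
        {
            "scf": None,
            "sci": None,
            "cycle_time": None,
            "n_cycles": 45,
            "initial_inoculum": 1e6,
            "initial_phage": 1e8,
        },
        "process",
    )
    if proc["scf"] is None or proc["sci"] is None or proc["cycle_time"] is None:
        raise ConfigError("process: blocks 'scf', 'sci' and key 'cycle_time' are required")
    scf = _parse_reactor(proc["scf"], "process.scf", needs_mls=False)
    sci = _parse_reactor(proc["sci"], "process.sci", needs_mls=True)
    try:
        process = ProcessSpec(
            scf=scf,
            sci=sci,
            cycle_time=float(proc["cycle_time"]),
            n_cycles=int(proc["n_cycles"]),
            initial_inoculum=float(proc["initial_inoculum"]),
            initial_phage=float(proc["initial_phage"]),
        )
    except ValueError as exc:
        raise ConfigError(f"process: {exc}") from exc

    costs = None
    if top["costs"] is not None:
        cost_block = _take(
            top["costs"],
            {"operation_rate": 40.0, "substrate_cost": 0.1, "medium_cost": 15.0},
            "costs",
        )
        try:
            costs = CostModel(**{k: float(v) for k, v in cost_block.items()})
        except ValueError as exc:
            raise ConfigError(f"costs: {exc}") from exc

    solver = _take(top["solver"] or {}, {"rtol": 1e-8, "atol": 1e-2}, "solver")
    out_dir = Path(top["output_dir"])
    if base_dir is not None and not out_dir.is_absolute():
        out_dir = base_dir / out_dir

    return RunConfig(
        params=params,
        response=response,
        disc=disc,
        process=process,
        costs=costs,
        experiments=dict(top["experiments"] or {}),
        output_dir=out_dir,
        seed=int(top["seed"]),
        solver={k: float(v) for k, v in solver.items()},
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(doc, base_dir=path.parent)


def example_config_path(name: str = "optimal_50L") -> Path:
    """Filesystem path of a bundled example configuration."""
    path = resources.files("phagecycle") / "fixtures" / f"{name}.yaml"
    with resources.as_file(path) as p:
        if not p.exists():
            raise ConfigError(f"no bundled configuration named '{name}'")
        return p


def load_example_config(name: str = "optimal_50L") -> RunConfig:
    """Load a bundled example configuration by name."""
    return load_config(example_config_path(name))
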