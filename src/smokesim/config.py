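"""Packaged defaults and run-configuration handling.

A run configuration is a flat YAML file with optional sections
``scenario`` (ScenarioSpec fields), ``params`` (UtilityParameters fields),
``marginals`` (PopulationMarginals block) and ``grid`` (thetaValues /
crossoverValues); anything omitted falls back to the packaged defaults.
The packaged utility parameters are the output of calibrating the model
against the 2011–2014 NYTS prevalence trajectory.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

import yaml

from .calibration import CalibrationTarget, load_targets
from .engine import ScenarioSpec
from .population import PopulationMarginals
from .utility import UtilityParameters

__all__ = [
    "default_marginals",
    "default_params",
    "default_targets",
    "default_spec",
    "load_config",
    "ConfigError",
]

GRID_LEVELS = [0.0, 0.1, 0.2, 0.3]


class ConfigError(ValueError):
    """A run configuration failed validation."""


def _data_path(name: str):
    return resources.files("smokesim.data").joinpath(name)


def default_marginals() -> PopulationMarginals:
    """Initial-profile marginals emulating the 2011 NYTS (packaged YAML)."""
    with _data_path("marginals_2011.yaml").open() as fh:
        return PopulationMarginals.from_dict(yaml.safe_load(fh))


def default_params() -> UtilityParameters:
    """Calibrated baseline utility parameters (packaged YAML)."""
    with _data_path("params_calibrated.yaml").open() as fh:
        return UtilityParameters.from_dict(yaml.safe_load(fh))


def default_targets() -> list[CalibrationTarget]:
    """2011–2014 NYTS yearly prevalence targets with 95% CIs."""
    with resources.as_file(_data_path("targets_nyts.csv")) as path:
        return load_targets(path)


def default_spec(seed: int = 0, nReplicates: int = 100) -> ScenarioSpec:
    """Baseline study scenario: 3000 agents, 2011–2014, monthly cycles."""
    return ScenarioSpec(
        marginals=default_marginals(),
        params=default_params(),
        nAgents=3000,
        attachmentM=2,
        cyclesPerYear=12,
        startYear=2011,
        endYear=2014,
        nReplicates=nReplicates,
        baseSeed=seed,
    )


SCENARIO_FIELDS = {
    "nAgents",
    "attachmentM",
    "cyclesPerYear",
    "startYear",
    "endYear",
    "nReplicates",
    "baseSeed",
}


def load_config(path=None, seed: int | None = None, replicates: int | None = None):
    """Build (ScenarioSpec, grid dict) from a YAML config plus overrides."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - {"scenario", "params", "marginals", "grid", "seed"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    marginals = (
        PopulationMarginals.from_dict(raw["marginals"])
        if "marginals" in raw
        else default_marginals()
    )
    params = default_params()
    if "params" in raw:
        try:
            params = replace(params, **raw["params"])
        except TypeError as exc:
            raise ConfigError(f"params: {exc}") from None

    spec = ScenarioSpec(marginals=marginals, params=params)
    scenario_block = raw.get("scenario", {})
    bad = set(scenario_block) - SCENARIO_FIELDS
    if bad:
        raise ConfigError(f"unknown scenario field(s): {sorted(bad)}")
    spec = replace(spec, **scenario_block)
    if "seed" in raw:
        spec = replace(spec, baseSeed=int(raw["seed"]))
    if seed is not None:
        spec = replace(spec, baseSeed=int(seed))
    if replicates is not None:
        spec = replace(spec, nReplicates=int(replicates))

    grid = raw.get("grid", {})
    if not isinstance(grid, dict):
        raise ConfigError("grid: expected a mapping")
    theta_values = grid.get("thetaValues", GRID_LEVELS)
    chi_values = grid.get("crossoverValues", GRID_LEVELS)
    for key, values in (("thetaValues", theta_values), ("crossoverValues", chi_values)):
        if not isinstance(values, (list, tuple)) or not values or not all(
            isinstance(v, (int, float)) for v in values
        ):
            raise ConfigError(f"grid.{key}: expected a non-empty list of numbers")
    return spec, {"thetaValues": list(theta_values), "crossoverValues": list(chi_values)}
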