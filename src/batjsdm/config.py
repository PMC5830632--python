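"""Run configuration: a strict, human-editable YAML surface.

Unknown keys are rejected (typos should fail loudly, not silently fall
back to defaults).  The configuration mirrors the pipeline stages: input
paths, CLAM settings, MCMC settings, prediction and similarity flags, the
output directory and the global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .model import ModelSpec, PriorSet

__all__ = ["RunConfig", "load_config"]

_SCHEMA = {
    "seed": int,
    "out": str,
    "inputs": {"captures": str, "covariates": str, "traits": str,
               "tree": str, "species_filter": list},
    "clam": {"K": float, "alpha": float, "coverage_limit": int},
    "mcmc": {"n_iter": int, "n_burnin": int, "thin": int, "n_factors": int,
             "rho_grid_points": int},
    "prediction": {"marginal": bool},
    "similarity": {"per_draw": bool, "floor": float},
}


def _check(section, schema, prefix=""):
    for key, val in section.items():
        if key not in schema:
            raise ValueError(f"unknown config key {prefix}{key!r}")
        want = schema[key]
        if isinstance(want, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {prefix}{key!r} must be a map")
            _check(val, want, prefix=f"{prefix}{key}.")
        elif want is float:
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ValueError(f"config key {prefix}{key!r} must be a number")
        elif not isinstance(val, want) or (want is int and isinstance(val, bool)):
            raise ValueError(
                f"config key {prefix}{key!r} must be {want.__name__}")


@dataclass
class RunConfig:
    """Validated settings for one end-to-end pipeline run."""

    captures: str
    covariates: str
    tree: str
    out: str
    traits: str | None = None          # optional; CLAM groups used if absent
    species_filter: list[str] | None = None
    seed: int = 0
    clam_K: float = 2.0 / 3.0
    clam_alpha: float = 0.01
    clam_coverage_limit: int = 10
    n_iter: int = 2000
    n_burnin: int = 500
    thin: int = 5
    n_factors: int = 3
    rho_grid_points: int = 51
    marginal_predictions: bool = True
    similarity_per_draw: bool = True
    similarity_floor: float = 1e-12

    def model_spec(self) -> ModelSpec:
        return ModelSpec(n_iter=self.n_iter, n_burnin=self.n_burnin,
                         thin=self.thin, seed=self.seed,
                         n_factors=self.n_factors,
                         rho_grid=np.linspace(0, 1, self.rho_grid_points),
                         priors=PriorSet())

    def require_paths(self) -> None:
        for name in ("captures", "covariates", "tree", "traits"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r}: {p}")

    def to_jsonable(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    _check(raw, _SCHEMA)
    inputs = raw.get("inputs", {})
    for req in ("captures", "covariates", "tree"):
        if req not in inputs:
            raise ValueError(f"config inputs.{req} is required")
    clam = raw.get("clam", {})
    mcmc = raw.get("mcmc", {})
    pred = raw.get("prediction", {})
    sim = raw.get("similarity", {})
    return RunConfig(
        captures=inputs["captures"], covariates=inputs["covariates"],
        tree=inputs["tree"], traits=inputs.get("traits"),
        species_filter=inputs.get("species_filter"),
        out=raw.get("out", "batjsdm-run"), seed=raw.get("seed", 0),
        clam_K=clam.get("K", 2.0 / 3.0), clam_alpha=clam.get("alpha", 0.01),
        clam_coverage_limit=clam.get("coverage_limit", 10),
        n_iter=mcmc.get("n_iter", 2000), n_burnin=mcmc.get("n_burnin", 500),
        thin=mcmc.get("thin", 5), n_factors=mcmc.get("n_factors", 3),
        rho_grid_points=mcmc.get("rho_grid_points", 51),
        marginal_predictions=pred.get("marginal", True),
        similarity_per_draw=sim.get("per_draw", True),
        similarity_floor=sim.get("floor", 1e-12),
    )
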