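"""Packaged study-condition parameter sets.

The fixtures bundle the fitted cardinal temperatures and thermal-time
constants of the two seedlots' seed morphs, the dormancy-layer fractions
of freshly harvested black #1 seeds, and the replicate-dish experiment
layouts used for the parameter-recovery experiments.  They live in a JSON
config (``data/presets.json``) rather than in code so alternative
populations can be dropped in without edits.
"""

from __future__ import annotations

import json
from importlib import resources

from .model import SeedPopulationParams
from .simulate import (DormancyState, ExperimentDesign, TreatmentFlags,
                       TreatmentRules)

__all__ = [
    "available_populations",
    "population_params",
    "recovery_design",
    "dormancy_state",
    "fh_black_1_base",
]


def _load() -> dict:
    with resources.files("seedtherm.data").joinpath(
            "presets.json").open() as fh:
        return json.load(fh)


def available_populations() -> list[str]:
    return sorted(_load()["populations"])


def population_params(name: str) -> SeedPopulationParams:
    """Thermal-time parameters of a named seed population."""
    pops = _load()["populations"]
    if name not in pops:
        raise KeyError(f"unknown population {name!r}; available: "
                       f"{sorted(pops)}")
    return SeedPopulationParams(**pops[name]["params"])


def recovery_design(name: str, *, rng_seed: int = 0,
                    treatment: TreatmentFlags | None = None
                    ) -> ExperimentDesign:
    """The replicate-dish layout used to re-estimate a population's
    parameters (daily scoring; long enough for cold-temperature
    percentiles to plateau)."""
    pops = _load()["populations"]
    spec = pops[name]["recovery_design"]
    return ExperimentDesign(
        temperatures=tuple(float(t) for t in spec["temperatures"]),
        n_dishes=int(spec["n_dishes"]),
        seeds_per_dish=int(spec["seeds_per_dish"]),
        scoring_times=tuple(float(d) for d in
                            range(1, int(spec["scoring_days"]) + 1)),
        treatment=treatment or TreatmentFlags(),
        rng_seed=rng_seed)


def dormancy_state(name: str = "fh_black_1"
                   ) -> tuple[DormancyState, TreatmentRules]:
    """Layer fractions and treatment rules of a named dormant state."""
    states = _load()["dormancy_states"]
    if name not in states:
        raise KeyError(f"unknown dormancy state {name!r}")
    spec = states[name]
    return DormancyState(**spec["state"]), TreatmentRules(**spec["rules"])


def fh_black_1_base() -> SeedPopulationParams:
    """Population parameters of the freshly harvested black #1 state:
    after-ripened kinetics with the viability ceiling as p_viable (the
    treatment then scales it by the released fraction)."""
    cfg = _load()["dormancy_states"]["fh_black_1"]
    base = _load()["populations"][cfg["base_population"]]["params"].copy()
    base["p_viable"] = float(cfg["viability_ceiling"])
    return SeedPopulationParams(**base)
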