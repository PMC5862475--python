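"""Executable case-study fixtures and the synthetic observed-data generator.

The packaged scenario catalogue encodes the validation studies the model
was exercised on — inulin, caffeine, ofloxacin, theophylline, paracetamol
and acyclovir, across i.v. bolus and oral (solution/tablet) protocols —
each with the study body weight, the compound's physicochemistry, its
clearance parameterization, and the calibrated parameter adjustments as
scenario-local overrides. A reference AUC table ships alongside as a CSV
fixture; a lognormal-noise sampler stands in for digitized literature
concentration-time data so every stage (simulation, metrics, calibration)
is testable without downloads.

Parameter overrides are dotted paths into the input bundle, e.g.
``physiology.organs.kidney.volume`` or ``clearance.enzymes.0.Km``; the
same path language drives the sensitivity and calibration machinery.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .clearance import ClearanceSpec
from .compound import CompoundProperties
from .engine import ODESystem, SimulationResult, build_ode_system, run_simulation
from .git_absorption import AdministrationProtocol
from .physiology import PhysiologyParameters, load_physiology, scale_to_body_weight


class DomainError(ValueError):
    pass


class Scenario(BaseModel):
    """One executable case study."""

    model_config = ConfigDict(validate_assignment=True)

    id: str
    description: str = ""
    body_weight: float
    compound: CompoundProperties
    clearance: ClearanceSpec
    protocol: AdministrationProtocol
    physiology_overrides: dict[str, float] = {}
    calibrated_overrides: dict[str, float] = {}
    t_end_min: float = 1440.0
    output_step_min: float = 1.0
    tags: list[str] = []


class ObservedDataset(BaseModel):
    scenario_id: str
    tissue: str
    times: list[float]
    concentrations: list[float]
    noise_model: dict = {}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "tissue": self.tissue,
                "concentration": self.concentrations,
                "unit": "umol/L",
            }
        )


# ---------------------------------------------------------------------------
# dotted-path override machinery
# ---------------------------------------------------------------------------

#: organ sub-compartment fractions must stay a partition of unity; adjusting
#: one of these rebalances fraction_cellular by the complementary delta
_REBALANCED_FRACTIONS = ("fraction_interstitial", "fraction_vascular")


def _resolve(container, key: str):
    """Resolve one path segment in a dict/list tree (name or index for lists)."""
    if isinstance(container, list):
        if key.isdigit():
            return container[int(key)]
        for item in container:
            if isinstance(item, Mapping) and item.get("name") == key:
                return item
        raise KeyError(f"no list entry named {key!r}")
    return container[key]


def get_path(doc: Mapping, path: str):
    node = doc
    for seg in path.split("."):
        node = _resolve(node, seg)
    return node


def set_path(doc: dict, path: str, value) -> None:
    segs = path.split(".")
    node = doc
    for seg in segs[:-1]:
        node = _resolve(node, seg)
    leaf = segs[-1]
    if leaf in _REBALANCED_FRACTIONS and isinstance(node, dict) and "fraction_cellular" in node:
        delta = value - node[leaf]
        node["fraction_cellular"] -= delta
    if isinstance(node, list):
        node[int(leaf)] = value
    else:
        node[leaf] = value


@dataclass
class ScenarioInputs:
    """Validated input bundle for one simulation run."""

    physiology: PhysiologyParameters
    compound: CompoundProperties
    clearance: ClearanceSpec
    protocol: AdministrationProtocol


def build_inputs(
    scenario: Scenario,
    mode: str = "optimized",
    extra_overrides: Mapping[str, float] | None = None,
    dose_scale: float = 1.0,
) -> ScenarioInputs:
    """Resolve a scenario into validated inputs.

    ``mode='predicted'`` applies only the structural ``physiology_overrides``;
    ``mode='optimized'`` additionally applies the calibrated adjustments.
    ``extra_overrides`` (e.g. a sensitivity perturbation or calibration trial
    point) are applied last. The baseline physiology is never mutated.
    """
    if mode not in ("predicted", "optimized"):
        raise DomainError(f"unknown mode {mode!r}")
    phys = scale_to_body_weight(load_physiology(), scenario.body_weight)
    doc = {
        "physiology": phys.model_dump(),
        "compound": scenario.compound.model_dump(),
        "clearance": scenario.clearance.model_dump(),
        "protocol": scenario.protocol.model_dump(),
    }
    overrides: dict[str, float] = dict(scenario.physiology_overrides)
    if mode == "optimized":
        overrides.update(scenario.calibrated_overrides)
    if extra_overrides:
        overrides.update(extra_overrides)
    for path, value in overrides.items():
        set_path(doc, path, value)
    if dose_scale != 1.0:
        doc["protocol"]["dose"] *= dose_scale
    return ScenarioInputs(
        physiology=PhysiologyParameters.model_validate(doc["physiology"]),
        compound=CompoundProperties.model_validate(doc["compound"]),
        clearance=ClearanceSpec.model_validate(doc["clearance"]),
        protocol=AdministrationProtocol.model_validate(doc["protocol"]),
    )


def build_scenario_system(
    scenario: Scenario,
    mode: str = "optimized",
    extra_overrides: Mapping[str, float] | None = None,
    dose_scale: float = 1.0,
) -> ODESystem:
    inp = build_inputs(scenario, mode, extra_overrides, dose_scale)
    return build_ode_system(inp.physiology, inp.compound, inp.clearance, inp.protocol)


def simulate_scenario(
    scenario: Scenario,
    mode: str = "optimized",
    extra_overrides: Mapping[str, float] | None = None,
    dose_scale: float = 1.0,
    t_end: float | None = None,
    output_step: float | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> SimulationResult:
    system = build_scenario_system(scenario, mode, extra_overrides, dose_scale)
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol
    result = run_simulation(
        system,
        t_end if t_end is not None else scenario.t_end_min,
        output_step if output_step is not None else scenario.output_step_min,
        **kwargs,
    )
    result.metadata["scenario_id"] = scenario.id
    result.metadata["mode"] = mode
    return result


# ---------------------------------------------------------------------------
# catalogue and fixtures
# ---------------------------------------------------------------------------


def list_scenarios() -> dict[str, Scenario]:
    """Packaged scenario catalogue, keyed by scenario id."""
    catalogue: dict[str, Scenario] = {}
    root = resources.files("rabbitpbpk.data").joinpath("scenarios")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            doc = yaml.safe_load(entry.read_text())
            sc = Scenario.model_validate(doc)
            catalogue[sc.id] = sc
    return catalogue


def load_scenario(scenario_id: str) -> Scenario:
    catalogue = list_scenarios()
    try:
        return catalogue[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; available: {sorted(catalogue)}"
        ) from None


def table1_fixture() -> pd.DataFrame:
    """Reference AUC table: observed, predicted and optimized exposure.

    16 rows of (compound, tissue/administration, AUC observed, AUC
    predicted, AUC after optimization, printed percent errors), each mapped
    to a packaged scenario and output compartment. Missing optimized cells
    are NaN.
    """
    text = resources.files("rabbitpbpk.data").joinpath("table1.csv").read_text()
    import io

    return pd.read_csv(io.StringIO(text))


def generate_observed_data(
    scenario: Scenario,
    sampling_times: Sequence[float],
    noise_cv: float,
    seed: int,
    tissue: str = "venous_plasma",
    mode: str = "optimized",
    result: SimulationResult | None = None,
) -> ObservedDataset:
    """Synthetic observed dataset: simulate, sample, apply lognormal noise.

    Multiplicative noise exp(N(0, sigma)) with sigma = sqrt(log(1 + cv^2)),
    so the sampled values have coefficient of variation ``noise_cv`` around
    the simulated truth. Deterministic for a given seed.
    """
    times = np.asarray(sampling_times, dtype=float)
    if result is None:
        result = simulate_scenario(scenario, mode=mode)
    if times.min() < result.times[0] or times.max() > result.times[-1]:
        raise DomainError("sampling times fall outside the simulation horizon")
    truth = np.interp(times, result.times, result.concentration(tissue))
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    if noise_cv == 0:
        sampled = truth
    else:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        rng = np.random.default_rng(seed)
        sampled = truth * np.exp(rng.normal(0.0, sigma, size=times.size))
    return ObservedDataset(
        scenario_id=scenario.id,
        tissue=tissue,
        times=times.tolist(),
        concentrations=sampled.tolist(),
        noise_model={"kind": "lognormal", "cv": noise_cv, "seed": seed, "mode": mode},
    )
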