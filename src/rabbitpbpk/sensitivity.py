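"""Local sensitivity analysis of AUC and Cmax to physiology parameters.

One parameter at a time is increased by a fixed fraction of its nominal
value (10% by default) and the scenario is re-simulated; the sensitivity
coefficient is the forward difference quotient

    s_ij = (f_i(x_j * (1 + delta)) - f_i(x_j)) / (x_j * delta)

for endpoint f_i in {AUC, Cmax}. Coefficients are absolute (endpoint units
per parameter unit) as is their squared-magnitude ranking; an opt-in
normalized variant rescales to relative changes. By default only
rabbit-physiology parameters are screened — compound-specific parameters
are deliberately excluded — but any dotted parameter path is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .pkmetrics import simulation_metrics
from .scenarios import Scenario, build_inputs, get_path, simulate_scenario

ENDPOINTS = ("AUC", "Cmax")


@dataclass
class SensitivityResult:
    scenario_id: str
    delta: float
    nominal: dict[str, float]  # endpoint -> nominal value
    coefficients: dict[str, dict[str, float]]  # endpoint -> {parameter: s}
    parameter_values: dict[str, float]  # parameter -> nominal x_j
    failed: list[str] = field(default_factory=list)
    normalized: bool = False

    def table(self) -> pd.DataFrame:
        """(endpoint, parameter, nominal, s, s_squared, rank) export."""
        rows = []
        for endpoint, coeffs in self.coefficients.items():
            ranked = sorted(coeffs.items(), key=lambda kv: (-kv[1] ** 2, kv[0]))
            for rank, (param, s) in enumerate(ranked, start=1):
                rows.append(
                    {
                        "endpoint": endpoint,
                        "parameter": param,
                        "nominal_value": self.parameter_values[param],
                        "s": s,
                        "s_squared": s**2,
                        "rank": rank,
                    }
                )
        return pd.DataFrame(rows)


def default_physiology_parameters(scenario: Scenario) -> list[str]:
    """Rabbit-physiology parameter paths screened by default."""
    inp = build_inputs(scenario, mode="optimized")
    paths = [
        "physiology.GFR_specific",
        "physiology.haematocrit",
        "physiology.GET_hr",
        "physiology.venous_volume",
        "physiology.arterial_volume",
    ]
    for organ in inp.physiology.organs:
        paths.append(f"physiology.organs.{organ.name}.volume")
        paths.append(f"physiology.organs.{organ.name}.specific_blood_flow")
    for seg in inp.physiology.git:
        paths.append(f"physiology.git.{seg.name}.transit_time")
        paths.append(f"physiology.git.{seg.name}.length")
        paths.append(f"physiology.git.{seg.name}.ESAEF")
    return paths


def local_sensitivity(
    scenario: Scenario,
    parameters: list[str] | None = None,
    delta: float = 0.10,
    mode: str = "optimized",
    tissue: str = "venous_plasma",
    normalized: bool = False,
    rtol: float | None = None,
    atol: float | None = None,
) -> SensitivityResult:
    """One-at-a-time forward-difference sensitivities for AUC and Cmax.

    A perturbed simulation that fails to integrate marks its parameter as
    failed and the screen continues. ``normalized=True`` reports
    (df/f) / (dx/x) instead of the absolute quotient.
    """
    if parameters is None:
        parameters = default_physiology_parameters(scenario)
    base = simulate_scenario(scenario, mode=mode, rtol=rtol, atol=atol)
    base_m = simulation_metrics(base, tissue, extrapolate=False)
    nominal = {"AUC": base_m.AUC, "Cmax": base_m.Cmax}

    doc_inputs = build_inputs(scenario, mode=mode)
    doc = {
        "physiology": doc_inputs.physiology.model_dump(),
        "compound": doc_inputs.compound.model_dump(),
        "clearance": doc_inputs.clearance.model_dump(),
        "protocol": doc_inputs.protocol.model_dump(),
    }

    coeffs: dict[str, dict[str, float]] = {e: {} for e in ENDPOINTS}
    values: dict[str, float] = {}
    failed: list[str] = []
    for path in parameters:
        x = float(get_path(doc, path))
        values[path] = x
        if x == 0.0:
            for e in ENDPOINTS:
                coeffs[e][path] = 0.0
            continue
        try:
            pert = simulate_scenario(
                scenario, mode=mode, extra_overrides={path: x * (1.0 + delta)},
                rtol=rtol, atol=atol,
            )
            pm = simulation_metrics(pert, tissue, extrapolate=False)
        except Exception:
            failed.append(path)
            for e in ENDPOINTS:
                coeffs[e][path] = math.nan
            continue
        for e, f_pert in (("AUC", pm.AUC), ("Cmax", pm.Cmax)):
            s = (f_pert - nominal[e]) / (x * delta)
            if normalized:
                s = s * x / nominal[e] if nominal[e] != 0 else math.nan
            coeffs[e][path] = s
    return SensitivityResult(
        scenario_id=scenario.id,
        delta=delta,
        nominal=nominal,
        coefficients=coeffs,
        parameter_values=values,
        failed=failed,
        normalized=normalized,
    )


def rank_parameters(res: SensitivityResult, top_n: int = 10) -> dict[str, list[str]]:
    """Top parameters per endpoint by squared sensitivity coefficient.

    All-zero (and failed) entries are excluded; ties break on the parameter
    name for determinism.
    """
    out: dict[str, list[str]] = {}
    for endpoint, coeffs in res.coefficients.items():
        usable = {p: s for p, s in coeffs.items() if s == s and s != 0.0}
        ranked = sorted(usable.items(), key=lambda kv: (-kv[1] ** 2, kv[0]))
        out[endpoint] = [p for p, _ in ranked[:top_n]]
    return out
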