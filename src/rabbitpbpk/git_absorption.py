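"""Oral dosing: formulation dissolution, luminal transit, absorption flux.

Tablets dissolve following an empirical Weibull law parameterized by the
time to 50% dissolution (DT) and a shape factor (DS); solutions are
instantaneously available in the stomach. Dissolved material transits the
GIT chain with first-order rates (the stomach emptying at 1/GET), is
absorbed across the effective segment surface, and whatever leaves the
colon accumulates in a faeces sink.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .compound import CompoundProperties, effective_surface_area, membrane_permeability, neutral_fraction
from .physiology import GITSegment, PhysiologyParameters

LN2 = math.log(2.0)


class DomainError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class FormulationKind(str, Enum):
    solution = "solution"
    rapid_tablet = "rapid_tablet"
    conventional_tablet = "conventional_tablet"


class FormulationSpec(BaseModel):
    """Oral formulation; DT/DS describe the Weibull dissolution of tablets."""

    model_config = ConfigDict(validate_assignment=True)

    kind: FormulationKind
    DT: float | None = None  # min, time to 50% dissolved
    DS: float | None = None  # Weibull shape

    @model_validator(mode="after")
    def _route_consistent(self) -> "FormulationSpec":
        if self.kind is FormulationKind.solution:
            if self.DT is not None or self.DS is not None:
                raise ConfigurationError("a solution has no DT/DS")
        else:
            if self.DT is None or self.DS is None:
                raise ConfigurationError(f"{self.kind.value} requires DT and DS")
            if self.DT <= 0 or self.DS <= 0:
                raise DomainError(f"DT and DS must be > 0, got DT={self.DT}, DS={self.DS}")
        return self


class Route(str, Enum):
    iv_bolus = "iv_bolus"
    iv_infusion = "iv_infusion"
    oral = "oral"


class AdministrationProtocol(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    route: Route
    dose: float  # in dose_unit
    dose_unit: Literal["mg", "mg_per_kg"] = "mg"
    formulation: FormulationSpec | None = None
    GET_hr: float | None = None  # overrides the physiology default
    infusion_duration: float | None = None  # min

    @model_validator(mode="after")
    def _consistent(self) -> "AdministrationProtocol":
        if self.dose <= 0:
            raise DomainError(f"dose must be > 0, got {self.dose}")
        if self.route is Route.oral and self.formulation is None:
            raise ConfigurationError("oral route requires a formulation")
        if self.route is Route.iv_infusion and (
            self.infusion_duration is None or self.infusion_duration <= 0
        ):
            raise ConfigurationError("iv_infusion requires a positive infusion_duration")
        return self

    def dose_umol(self, phys: PhysiologyParameters, c: CompoundProperties) -> float:
        """Dose in umol; mg/kg doses resolved through the body weight."""
        mg = self.dose * (phys.body_weight if self.dose_unit == "mg_per_kg" else 1.0)
        return mg * 1000.0 / c.MW


def weibull_fraction_dissolved(t: float, DT: float, DS: float) -> float:
    """Cumulative fraction dissolved: F(t) = 1 - exp(-ln2 * (t/DT)^DS).

    F(0) = 0 and F(DT) = 0.5 for any shape; DS = 1 reduces to first-order
    dissolution with rate ln2/DT.
    """
    if DT <= 0 or DS <= 0:
        raise DomainError(f"DT and DS must be > 0, got DT={DT}, DS={DS}")
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    return 1.0 - math.exp(-LN2 * (t / DT) ** DS)


def weibull_hazard(t: float, DT: float, DS: float) -> float:
    """Instantaneous dissolution rate constant h(t) = F'(t)/(1-F(t)), 1/min.

    h(t) = ln2 * DS * t^(DS-1) / DT^DS. For DS < 1 the hazard diverges at
    t = 0; it is evaluated at max(t, 1e-6) to keep the ODE right-hand side
    finite.
    """
    if DT <= 0 or DS <= 0:
        raise DomainError(f"DT and DS must be > 0, got DT={DT}, DS={DS}")
    t = max(t, 1e-6)
    return LN2 * DS * t ** (DS - 1.0) / DT**DS


def apply_dose(
    protocol: AdministrationProtocol,
    state: np.ndarray,
    index,
    phys: PhysiologyParameters,
    c: CompoundProperties,
) -> np.ndarray:
    """Place the dose into a zero-drug initial state (umol).

    i.v. bolus: full dose into the venous plasma pool. Oral solution: full
    dose into the stomach dissolved pool (instantaneous availability). Oral
    tablet: full dose into the stomach solid pool, to dissolve under the
    Weibull law. Infusions leave the state untouched (the input enters
    through the rate function over the infusion duration).
    """
    if np.any(state != 0.0):
        raise DomainError("apply_dose expects a zero-initialized state")
    out = state.copy()
    dose = protocol.dose_umol(phys, c)
    if protocol.route is Route.iv_bolus:
        out[index.venous] = dose
    elif protocol.route is Route.iv_infusion:
        pass
    else:
        if protocol.formulation.kind is FormulationKind.solution:
            out[index.lumen_dissolved[0]] = dose
        else:
            out[index.lumen_solid[0]] = dose
    return out


def absorption_flux(
    dissolved_amount: float,
    c: CompoundProperties,
    seg: GITSegment,
    permeability: float | None = None,
) -> float:
    """Absorptive flux out of one segment's dissolved pool, umol/min.

    flux = P_eff * ESA * C_lumen, with P_eff the transcellular permeability
    scaled by the Henderson-Hasselbalch neutral fraction at the segment pH.
    """
    if dissolved_amount < 0:
        raise DomainError("dissolved luminal amount must be >= 0")
    if permeability is None:
        permeability = membrane_permeability(c)
    p_eff = permeability * neutral_fraction(c, seg.pH)
    c_lumen = dissolved_amount / seg.lumen_volume
    return p_eff * effective_surface_area(seg) * c_lumen
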