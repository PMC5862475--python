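"""Elimination rate laws and excretion bookkeeping.

Renal elimination combines glomerular filtration (unbound drug, scaled by
the kidney weight and the specific GFR) with an optional first-order
tubular secretion; hepatic elimination is either a first-order clearance
or one or more saturable Michaelis-Menten enzyme processes. Filtered and
secreted drug accumulates in a urine sink, metabolized drug in a
metabolite sink; neither is simulated further.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, field_validator

from .physiology import PhysiologyParameters


class DomainError(ValueError):
    pass


class EnzymeProcess(BaseModel):
    """One hepatic enzyme: Vmax (umol/L/min), Km (umol/L), E (umol/L).

    The enzyme concentration enters as a dimensionless multiplier
    normalized to 1 umol/L, so the maximal volumetric rate is Vmax * E.
    """

    Vmax: float
    Km: float
    E: float = 1.0

    @field_validator("Vmax")
    @classmethod
    def _vmax(cls, v):
        if v < 0:
            raise DomainError(f"Vmax must be >= 0, got {v}")
        return v

    @field_validator("Km", "E")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise DomainError(f"Km and E must be > 0, got {v}")
        return v


class ClearanceSpec(BaseModel):
    """Process parameterization for renal and hepatic elimination.

    First-order clearances can be given either in absolute L/min
    (``hepatic_CL_firstorder``) or per kg of liver (``hepatic_CL_specific``,
    L/min/kg), the latter scaling with the liver size of the animal.
    ``reference_concentration`` selects whether first-order and enzymatic
    rates are driven by the unbound or the total plasma concentration in
    the eliminating organ; glomerular filtration is always unbound.
    """

    model_config = ConfigDict(validate_assignment=True)

    gfr_fraction: float = 1.0
    tubular_secretion_CL: float = 0.0  # L/min
    hepatic_CL_firstorder: float = 0.0  # L/min
    hepatic_CL_specific: float = 0.0  # L/min per kg liver
    enzymes: list[EnzymeProcess] = []
    reference_concentration: Literal["unbound", "total"] = "unbound"

    @field_validator(
        "gfr_fraction", "tubular_secretion_CL", "hepatic_CL_firstorder", "hepatic_CL_specific"
    )
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise DomainError(f"clearances must be >= 0, got {v}")
        return v

    def hepatic_CL_total(self, phys: PhysiologyParameters) -> float:
        """Absolute first-order hepatic clearance, L/min."""
        return self.hepatic_CL_firstorder + self.hepatic_CL_specific * phys.organ("liver").volume


def gfr_filtration_rate(
    C_plasma: float,
    fu: float,
    GFR_specific: float,
    kidney_weight: float,
    gfr_fraction: float = 1.0,
) -> float:
    """Glomerular filtration rate, umol/min, routed to the urine sink.

    rate = gfr_fraction * GFR_specific * kidney_weight * fu * C_plasma
    """
    if min(C_plasma, fu, GFR_specific, kidney_weight, gfr_fraction) < 0:
        raise DomainError("filtration inputs must be non-negative")
    return gfr_fraction * GFR_specific * kidney_weight * fu * C_plasma


def mm_metabolism_rate(
    C_unbound_liver: float, Vmax: float, Km: float, E: float, V_liver: float
) -> float:
    """Michaelis-Menten hepatic metabolism, umol/min.

    rate = V_liver * Vmax * (E / 1 umol/L) * C / (Km + C); the saturation
    plateau is V_liver * Vmax * E. Guarded to return 0 when Km + C = 0.
    """
    if min(C_unbound_liver, Vmax, Km, E, V_liver) < 0:
        raise DomainError("metabolism inputs must be non-negative")
    denom = Km + C_unbound_liver
    if denom == 0.0:
        return 0.0
    return V_liver * Vmax * E * C_unbound_liver / denom


def linear_clearance_rate(C_reference: float, CL: float) -> float:
    """First-order elimination rate, umol/min: rate = CL * C_reference.

    Callers supply the driving concentration under the configured reference
    convention (unbound or total plasma in the eliminating organ).
    """
    if C_reference < 0 or CL < 0:
        raise DomainError("clearance inputs must be non-negative")
    return CL * C_reference


def fraction_excreted_urine(result) -> float:
    """Cumulative urinary excretion at the final time as a fraction of dose."""
    if result.dose <= 0:
        raise DomainError("fraction excreted requires a positive dose")
    return float(result.urine[-1] / result.dose)
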