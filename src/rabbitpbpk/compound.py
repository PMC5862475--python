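"""Compound physicochemistry and derived distribution inputs.

From a handful of measurable properties (molecular weight, lipophilicity,
plasma protein binding, ionization constants) this module derives the two
quantities the whole-body model needs for distribution: tissue:plasma
partition coefficients (Kp) and a transcellular membrane permeability.

Both follow documented, monotone approximations built from tissue
composition and compound lipophilicity/binding. They are intentionally
simple; per-organ Kp overrides and a permeability override let users
inject values exported from any external distribution model.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, field_validator

from .physiology import GITSegment, PhysiologyParameters

logger = logging.getLogger("rabbitpbpk")

# permeability law constants (see docs/methods.md): P = P_REF * 10^(ALPHA*logP)
# * sqrt(MW_REF / MW), anchored at a 300 g/mol neutral compound.
PERMEABILITY_P_REF = 4.0e-5  # dm/min
PERMEABILITY_ALPHA = 0.5
PERMEABILITY_MW_REF = 300.0


class SizeClass(str, Enum):
    small = "small"
    large = "large"


class UnsupportedOperationError(TypeError):
    """Operation not defined for this size class."""


class ConfigurationError(ValueError):
    pass


class PKa(BaseModel):
    value: float
    kind: Literal["acid", "base"]


class CompoundProperties(BaseModel):
    """Physicochemistry of one compound.

    ``blood_plasma_ratio`` is the red-blood-cell:plasma concentration ratio
    at equilibrium (1 for compounds that equilibrate freely with
    erythrocytes, 0 for compounds confined to plasma such as large
    polysaccharides).
    """

    model_config = ConfigDict(validate_assignment=True)

    name: str
    MW: float  # g/mol
    logP: float
    fu: float  # fraction unbound in plasma
    pKa: list[PKa] = []
    solubility: float | None = None  # mg/mL, required for oral dosing
    size_class: SizeClass = SizeClass.small
    blood_plasma_ratio: float = 1.0
    kp_overrides: dict[str, float] = {}
    permeability_override: float | None = None

    @field_validator("MW")
    @classmethod
    def _mw(cls, v: float) -> float:
        if v <= 0:
            raise ConfigurationError(f"MW must be > 0, got {v}")
        return v

    @field_validator("fu")
    @classmethod
    def _fu(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ConfigurationError(f"fu must lie in (0, 1], got {v}")
        return v

    @field_validator("solubility")
    @classmethod
    def _sol(cls, v):
        if v is not None and v <= 0:
            raise ConfigurationError(f"solubility must be > 0, got {v}")
        return v


class PartitionSet(BaseModel):
    """Per-organ tissue:plasma partition coefficients with provenance."""

    kp: dict[str, float]
    provenance: dict[str, Literal["calculated", "user_override"]]

    @field_validator("kp")
    @classmethod
    def _positive(cls, v):
        for organ, kp in v.items():
            if kp <= 0:
                raise ConfigurationError(f"Kp for {organ} must be > 0, got {kp}")
        return v


def partition_coefficients(
    c: CompoundProperties, p: PhysiologyParameters
) -> PartitionSet:
    """Tissue:plasma Kp per organ from tissue composition and lipophilicity.

        Kp = f_water + f_lipid * 10^logP + f_protein * (1/fu - 1)

    The water term carries the aqueous share, the lipid term scales with the
    octanol-water partition, and the protein term mirrors plasma-protein
    binding strength into tissue protein. User overrides replace the
    calculated entry and are logged; provenance is total over organs.
    """
    if c.size_class is not SizeClass.small:
        raise UnsupportedOperationError(
            "partition coefficients apply to small molecules; large molecules "
            "distribute by pore-limited interstitial exchange"
        )
    kp: dict[str, float] = {}
    prov: dict[str, str] = {}
    binding = (1.0 / c.fu) - 1.0
    for organ in p.organs:
        value = (
            organ.water_fraction
            + organ.lipid_fraction * 10.0**c.logP
            + organ.protein_fraction * binding
        )
        if organ.name in c.kp_overrides:
            value = c.kp_overrides[organ.name]
            prov[organ.name] = "user_override"
            logger.debug("Kp[%s] overridden to %g", organ.name, value)
        else:
            prov[organ.name] = "calculated"
        kp[organ.name] = value
    return PartitionSet(kp=kp, provenance=prov)


def membrane_permeability(c: CompoundProperties) -> float:
    """Transcellular membrane permeability, dm/min.

    Semi-empirical two-parameter law, increasing in logP and decreasing in
    MW:  P = P_ref * 10^(alpha*logP) * sqrt(MW_ref / MW).  A user override
    replaces the calculated value.
    """
    if c.size_class is not SizeClass.small:
        raise UnsupportedOperationError(
            "membrane permeability applies to small molecules; use the "
            "pore-limited (hydraulic conductivity) pathway for large molecules"
        )
    if c.permeability_override is not None:
        logger.debug("permeability for %s overridden to %g", c.name, c.permeability_override)
        return c.permeability_override
    return (
        PERMEABILITY_P_REF
        * 10.0 ** (PERMEABILITY_ALPHA * c.logP)
        * math.sqrt(PERMEABILITY_MW_REF / c.MW)
    )


def neutral_fraction(c: CompoundProperties, pH: float) -> float:
    """Henderson-Hasselbalch neutral (un-ionized) fraction at a given pH.

    Monoprotic terms are combined multiplicatively for polyprotic compounds;
    a compound without pKa entries is treated as fully neutral.
    """
    f = 1.0
    for pka in c.pKa:
        if pka.kind == "acid":
            f *= 1.0 / (1.0 + 10.0 ** (pH - pka.value))
        else:
            f *= 1.0 / (1.0 + 10.0 ** (pka.value - pH))
    return f


def effective_surface_area(seg: GITSegment) -> float:
    """Absorptive surface of a GIT segment, dm^2.

    Cylinder side area 2*pi*r*L (cm^2) scaled by the effective surface area
    enhancement factor (folds/villi/microvilli), converted to dm^2.
    """
    area_cm2 = 2.0 * math.pi * seg.radius * seg.length * seg.ESAEF
    return area_cm2 / 100.0


def cellular_partition(kp_tissue: float, organ) -> float:
    """Cell:interstitial partition that reproduces the tissue Kp at equilibrium.

    With interstitial water equilibrating to plasma (equal total
    concentrations) and the vascular plasma share f_vasc*(1-hct) folded into
    the tissue average, the cellular compartment must carry
    (Kp - f_vasc - f_int) / f_cell to recompose Kp. Floored at a small
    positive value for very hydrophilic compounds.
    """
    residual = kp_tissue - organ.fraction_vascular - organ.fraction_interstitial
    return max(residual / organ.fraction_cellular, 1e-6)
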