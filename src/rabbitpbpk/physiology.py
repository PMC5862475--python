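"""Rabbit body composition: organs, blood-flow network, and GIT geometry.

The physiology layer defines *who* the animal is, independently of any
compound: organ volumes and their vascular/interstitial/cellular split,
specific blood flows, the haematocrit, the specific glomerular filtration
rate, and the gastrointestinal tract (GIT) as an ordered chain of luminal
segments with geometry, pH and transit times.

Units convention (package-wide): amounts in umol, volumes in L, time in
min, concentrations in umol/L. Organ density is taken as 1 kg/L, so an
organ's weight in kg equals its volume in L.

The packaged default parameter set (``data/rabbit_default.yaml``) describes
a 2.5 kg rabbit assembled from standard open physiology compilations; every
value can be overridden from a user configuration document.
"""

from __future__ import annotations

import copy
import io
import logging
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from pydantic import ValidationError as PydanticValidationError

logger = logging.getLogger("rabbitpbpk")

FRACTION_SUM_TOL = 1e-9
FLOW_BALANCE_RTOL = 1e-6

#: organs whose venous outflow drains into the liver via the portal vein
PORTAL_ORGANS = ("stomach", "small_intestine", "large_intestine", "spleen", "pancreas")

#: luminal segment -> gut-wall organ receiving the absorbed flux
SEGMENT_WALL_ORGAN = {
    "stomach": "stomach",
    "si_proximal": "small_intestine",
    "si_distal": "small_intestine",
    "caecum": "large_intestine",
    "colon": "large_intestine",
}


class ConfigurationError(ValueError):
    """A configuration document is missing or names an unusable field."""


class PhysiologyValidationError(ValueError):
    """A supplied physiology value violates a structural invariant."""


class OrganSpec(BaseModel):
    """One perfused organ.

    ``specific_blood_flow`` is the arterial inflow per kg of organ
    (L/min/kg); for the liver it is the hepatic-artery share only, the
    portal vein inflow being the venous outflow of the portal organs.
    ``hydraulic_conductivity`` (L/min/dm^2) drives the pore-limited
    plasma<->interstitial flux used for large molecules. The water/lipid/
    protein fractions describe tissue composition for partition-coefficient
    calculation.
    """

    model_config = ConfigDict(validate_assignment=True)

    name: str
    volume: float  # L
    specific_blood_flow: float  # L/min per kg organ
    fraction_vascular: float
    fraction_interstitial: float
    fraction_cellular: float
    hydraulic_conductivity: float = 3.0e-5  # L/min per dm^2 exchange surface
    surface_area_scale: float = 1.0
    water_fraction: float = 0.75
    lipid_fraction: float = 0.04
    protein_fraction: float = 0.18

    @field_validator("volume")
    @classmethod
    def _volume_positive(cls, v: float) -> float:
        if v <= 0:
            raise PhysiologyValidationError(f"organ volume must be > 0, got {v}")
        return v

    @field_validator("specific_blood_flow", "hydraulic_conductivity", "surface_area_scale")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise PhysiologyValidationError(f"value must be >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _fractions_close(self) -> "OrganSpec":
        fr = (self.fraction_vascular, self.fraction_interstitial, self.fraction_cellular)
        if any(f < 0 for f in fr):
            raise PhysiologyValidationError(f"{self.name}: negative sub-compartment fraction {fr}")
        total = sum(fr)
        if abs(total - 1.0) > 1e-6:
            raise PhysiologyValidationError(
                f"{self.name}: vascular+interstitial+cellular fractions sum to {total}, expected 1"
            )
        return self

    @property
    def blood_flow(self) -> float:
        """Absolute arterial inflow, L/min (density 1 kg/L)."""
        return self.specific_blood_flow * self.volume

    @property
    def exchange_surface_area(self) -> float:
        """Nominal plasma/tissue exchange area, dm^2 (100 dm^2 per L tissue)."""
        return 100.0 * self.surface_area_scale * self.volume


class GITSegment(BaseModel):
    """One luminal GIT segment (geometry, pH, transit, absorptive area)."""

    model_config = ConfigDict(validate_assignment=True)

    name: str
    length: float  # cm
    radius: float  # cm
    pH: float
    transit_time: float  # min
    ESAEF: float = 1.0  # effective surface area enhancement factor

    @field_validator("length", "radius", "transit_time")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise PhysiologyValidationError(f"GIT segment dimension must be > 0, got {v}")
        return v

    @field_validator("ESAEF")
    @classmethod
    def _esaef(cls, v: float) -> float:
        if v < 1:
            raise PhysiologyValidationError(f"ESAEF must be >= 1, got {v}")
        return v

    @field_validator("pH")
    @classmethod
    def _ph(cls, v: float) -> float:
        if not 1.0 <= v <= 9.0:
            raise PhysiologyValidationError(f"GIT pH must lie in [1, 9], got {v}")
        return v

    @property
    def lumen_volume(self) -> float:
        """Luminal volume of the cylindrical segment, L."""
        import math

        return math.pi * self.radius**2 * self.length / 1000.0


class PhysiologyParameters(BaseModel):
    """The assembled rabbit: organs, blood pools, GIT, and renal capacity."""

    model_config = ConfigDict(validate_assignment=True)

    body_weight: float = 2.5  # kg
    haematocrit: float = 0.36
    GFR_specific: float = 0.6  # L/min per kg kidney
    arterial_volume: float = 0.04  # L whole blood
    venous_volume: float = 0.09  # L whole blood
    GET_hr: float = 0.5  # gastric emptying time, protocol-overridable
    organs: list[OrganSpec]
    git: list[GITSegment]

    @field_validator("body_weight", "arterial_volume", "venous_volume", "GET_hr")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise PhysiologyValidationError(f"value must be > 0, got {v}")
        return v

    @field_validator("haematocrit")
    @classmethod
    def _hct(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise PhysiologyValidationError(f"haematocrit must lie in (0, 1), got {v}")
        return v

    @model_validator(mode="after")
    def _structure(self) -> "PhysiologyParameters":
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise PhysiologyValidationError(f"duplicate organ names in {names}")
        total = sum(o.volume for o in self.organs) + self.arterial_volume + self.venous_volume
        if total >= self.body_weight:  # density ~1 kg/L
            raise PhysiologyValidationError(
                f"organ+blood volume {total:.3f} L exceeds body volume {self.body_weight} L"
            )
        return self

    # -- lookups ---------------------------------------------------------

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ named {name!r}")

    def segment(self, name: str) -> GITSegment:
        for s in self.git:
            if s.name == name:
                return s
        raise KeyError(f"no GIT segment named {name!r}")

    @property
    def kidney_weight(self) -> float:
        """Kidney weight in kg (volume at density 1 kg/L)."""
        return self.organ("kidney").volume

    @property
    def cardiac_output(self) -> float:
        """Total systemic arterial flow = lung perfusion, L/min."""
        return sum(o.blood_flow for o in self.organs if o.name != "lung")

    def flow_balance_residual(self) -> float:
        """Relative imbalance between venous return and cardiac output.

        Portal organs drain through the liver; the liver's outflow is its
        hepatic-artery inflow plus the portal-vein inflow, so the venous
        return recomposes exactly the cardiac output for any parameter set.
        """
        co = self.cardiac_output
        portal = sum(self.organ(n).blood_flow for n in PORTAL_ORGANS if _has_organ(self, n))
        liver_out = self.organ("liver").blood_flow + portal
        direct = sum(
            o.blood_flow
            for o in self.organs
            if o.name not in PORTAL_ORGANS and o.name not in ("lung", "liver")
        )
        venous_return = direct + liver_out
        return abs(venous_return - co) / co


def _has_organ(phys: PhysiologyParameters, name: str) -> bool:
    return any(o.name == name for o in phys.organs)


# ---------------------------------------------------------------------------
# loading / serialization
# ---------------------------------------------------------------------------

_REQUIRED_ORGAN_FIELDS = (
    "volume",
    "specific_blood_flow",
    "fraction_vascular",
    "fraction_interstitial",
    "fraction_cellular",
)


def default_physiology_document() -> dict:
    """Raw packaged default rabbit document (deep copy, safe to mutate)."""
    text = resources.files("rabbitpbpk.data").joinpath("rabbit_default.yaml").read_text()
    return yaml.safe_load(text)


def load_physiology(
    config: str | Mapping | None = None, merge_defaults: bool = True
) -> PhysiologyParameters:
    """Build a validated :class:`PhysiologyParameters` from a document.

    ``config`` may be ``None`` (packaged default rabbit), a YAML/JSON string,
    or an already-parsed mapping. With ``merge_defaults`` (the default),
    unspecified fields — including organs/segments omitted from partial
    lists — are filled from the packaged default file and every filled
    field is logged at DEBUG level; with ``merge_defaults=False`` the
    document must be complete (this is how reduced bodies are built).
    Missing mandatory fields raise :class:`ConfigurationError`; invariant
    violations raise :class:`PhysiologyValidationError`.
    """
    default = default_physiology_document()
    if config is None:
        doc = default
        filled = []
    else:
        if isinstance(config, str):
            user = yaml.safe_load(config)
        else:
            user = copy.deepcopy(dict(config))
        if not isinstance(user, Mapping):
            raise ConfigurationError("physiology config must be a mapping document")
        if merge_defaults:
            doc, filled = _merge_with_default(dict(user), default)
        else:
            doc, filled = dict(user), []
    for field in filled:
        logger.debug("physiology field %s filled from packaged default", field)
    try:
        organs = [OrganSpec(**o) for o in doc["organs"]]
        git = [GITSegment(**s) for s in doc["git"]]
        scalars = {k: v for k, v in doc.items() if k not in ("organs", "git")}
        phys = PhysiologyParameters(organs=organs, git=git, **scalars)
    except KeyError as exc:
        raise ConfigurationError(f"missing mandatory physiology field: {exc}") from exc
    except PydanticValidationError as exc:
        first = exc.errors()[0]
        raise PhysiologyValidationError(
            f"{'.'.join(str(x) for x in first.get('loc', ()))}: {first['msg']}"
        ) from exc
    res = phys.flow_balance_residual()
    if res > FLOW_BALANCE_RTOL:
        raise PhysiologyValidationError(f"blood-flow network imbalance: relative residual {res:.3g}")
    return phys


def _merge_with_default(user: dict, default: dict) -> tuple[dict, list[str]]:
    """Fill user document from the default; report which fields were filled."""
    filled: list[str] = []
    merged = dict(user)
    for key, dval in default.items():
        if key == "organs":
            merged["organs"], f = _merge_named(user.get("organs"), dval, _REQUIRED_ORGAN_FIELDS)
            filled += [f"organs.{x}" for x in f]
        elif key == "git":
            merged["git"], f = _merge_named(user.get("git"), dval, ("length", "radius", "pH", "transit_time"))
            filled += [f"git.{x}" for x in f]
        elif key not in merged:
            merged[key] = copy.deepcopy(dval)
            filled.append(key)
    return merged, filled


def _merge_named(user_items, default_items, required) -> tuple[list[dict], list[str]]:
    """Merge user organ/segment entries into the default set by name.

    Entries keep default values for unspecified fields; default entries the
    user does not mention are retained, so a partial list overrides without
    truncating the body.
    """
    filled: list[str] = []
    if user_items is None:
        return copy.deepcopy(default_items), [d["name"] for d in default_items]
    by_name = {item.get("name"): item for item in user_items}
    if None in by_name:
        raise ConfigurationError("every organ/GIT entry needs a 'name'")
    out = []
    seen = set()
    for dflt in default_items:
        base = copy.deepcopy(dflt)
        item = by_name.get(dflt["name"], {})
        seen.add(dflt["name"])
        for k, v in base.items():
            if k not in item:
                filled.append(f"{base['name']}.{k}")
        base.update(item)
        out.append(base)
    for name, item in by_name.items():
        if name in seen:
            continue
        missing = [f for f in required if f not in item]
        if missing:
            raise ConfigurationError(f"entry {name!r} missing mandatory field(s): {missing}")
        out.append(copy.deepcopy(item))
    return out, filled


def serialize_physiology(phys: PhysiologyParameters) -> str:
    """Round-trippable YAML document (``load_physiology`` recovers it)."""
    doc = phys.model_dump()
    return yaml.safe_dump(doc, sort_keys=False)


def export_parameter_table(
    phys: PhysiologyParameters, overridden: Iterable[str] = ()
) -> pd.DataFrame:
    """Resolved parameter table: (name, value, unit, source)."""
    overridden = set(overridden)
    rows = []

    def add(name, value, unit):
        rows.append(
            {
                "name": name,
                "value": value,
                "unit": unit,
                "source": "user" if name in overridden else "default",
            }
        )

    add("body_weight", phys.body_weight, "kg")
    add("haematocrit", phys.haematocrit, "-")
    add("GFR_specific", phys.GFR_specific, "L/min/kg kidney")
    add("arterial_volume", phys.arterial_volume, "L")
    add("venous_volume", phys.venous_volume, "L")
    add("GET_hr", phys.GET_hr, "hr")
    for o in phys.organs:
        for f, unit in (
            ("volume", "L"),
            ("specific_blood_flow", "L/min/kg"),
            ("fraction_vascular", "-"),
            ("fraction_interstitial", "-"),
            ("fraction_cellular", "-"),
            ("hydraulic_conductivity", "L/min/dm^2"),
        ):
            add(f"organs.{o.name}.{f}", getattr(o, f), unit)
    for s in phys.git:
        for f, unit in (
            ("length", "cm"),
            ("radius", "cm"),
            ("pH", "-"),
            ("transit_time", "min"),
            ("ESAEF", "-"),
        ):
            add(f"git.{s.name}.{f}", getattr(s, f), unit)
    return pd.DataFrame(rows)


def export_parameter_csv(phys: PhysiologyParameters, overridden: Iterable[str] = ()) -> str:
    buf = io.StringIO()
    export_parameter_table(phys, overridden).to_csv(buf, index=False)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def scale_to_body_weight(phys: PhysiologyParameters, bw: float) -> PhysiologyParameters:
    """Linearly rescale the body to a new weight.

    Organ volumes and blood-pool volumes scale with ``bw / reference_bw``
    (so absolute flows scale too, specific flows being per kg organ);
    fractions, pH, transit times and ``GFR_specific`` are unchanged.
    """
    if bw <= 0:
        raise PhysiologyValidationError(f"body weight must be > 0, got {bw}")
    factor = bw / phys.body_weight
    doc = phys.model_dump()
    doc["body_weight"] = bw
    doc["arterial_volume"] *= factor
    doc["venous_volume"] *= factor
    for o in doc["organs"]:
        o["volume"] *= factor
    organs = [OrganSpec(**o) for o in doc["organs"]]
    git = [GITSegment(**s) for s in doc["git"]]
    scalars = {k: v for k, v in doc.items() if k not in ("organs", "git")}
    return PhysiologyParameters(organs=organs, git=git, **scalars)


def git_transit_rates(git: list[GITSegment], GET_hr: float) -> dict[str, float]:
    """First-order luminal transit rate constants, 1/min, in segment order.

    The first (stomach) segment empties at ``1 / (GET * 60)``; every later
    segment at the reciprocal of its transit time.
    """
    if GET_hr <= 0:
        raise PhysiologyValidationError(f"gastric emptying time must be > 0, got {GET_hr}")
    rates: dict[str, float] = {}
    for i, seg in enumerate(git):
        if seg.transit_time <= 0:
            raise PhysiologyValidationError(f"non-positive transit time for {seg.name}")
        rates[seg.name] = 1.0 / (GET_hr * 60.0) if i == 0 else 1.0 / seg.transit_time
    return rates
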