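"""Whole-body ODE assembly and integration.

The state vector concatenates, in fixed order: per-organ vascular plasma,
per-organ red blood cells, per-organ interstitial, per-organ cellular
amounts (umol), the arterial and venous whole-blood pools, per-GIT-segment
solid and dissolved luminal pools, and three cumulative sinks (urine,
metabolite, faeces). For the default 14-organ rabbit with 5 GIT segments
the dimension is 14*4 + 2 + 5*2 + 3 = 71.

Blood circulates venous pool -> lung -> arterial pool -> systemic organs;
portal organs drain through the liver. Small molecules exchange
plasma<->interstitial in a flow-limited fashion and cross the cell
membrane with a permeability-limited flux against their cellular
partition; large molecules exchange plasma<->interstitial through a
pore-limited (hydraulic conductivity) pathway and never enter cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .clearance import ClearanceSpec
from .compound import (
    CompoundProperties,
    SizeClass,
    cellular_partition,
    effective_surface_area,
    membrane_permeability,
    neutral_fraction,
    partition_coefficients,
)
from .git_absorption import (
    AdministrationProtocol,
    FormulationKind,
    Route,
    apply_dose,
    weibull_hazard,
)
from .physiology import PORTAL_ORGANS, SEGMENT_WALL_ORGAN, PhysiologyParameters

#: plasma<->interstitial exchange clearance as a multiple of organ blood flow
#: (flow-limited distribution: the vascular barrier is fast relative to flow)
FLOW_EXCHANGE_FACTOR = 5.0
#: first-order RBC<->plasma equilibration rate, 1/min
RBC_EXCHANGE_RATE = 1.0

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10  # umol
NEGATIVE_FLOOR = -1e-9


class ConfigurationError(ValueError):
    pass


class IntegrationError(RuntimeError):
    """Integration failed; carries the solver diagnostics message."""


@dataclass
class StateIndex:
    """Positions of every compartment in the state vector."""

    organ_names: list[str]
    segment_names: list[str]
    plasma: np.ndarray
    rbc: np.ndarray
    interstitial: np.ndarray
    cellular: np.ndarray
    arterial: int
    venous: int
    lumen_solid: np.ndarray
    lumen_dissolved: np.ndarray
    urine: int
    metabolite: int
    faeces: int
    n_states: int


def build_state_index(phys: PhysiologyParameters) -> StateIndex:
    n = len(phys.organs)
    m = len(phys.git)
    a = np.arange
    return StateIndex(
        organ_names=[o.name for o in phys.organs],
        segment_names=[s.name for s in phys.git],
        plasma=a(0, n),
        rbc=a(n, 2 * n),
        interstitial=a(2 * n, 3 * n),
        cellular=a(3 * n, 4 * n),
        arterial=4 * n,
        venous=4 * n + 1,
        lumen_solid=a(4 * n + 2, 4 * n + 2 + m),
        lumen_dissolved=a(4 * n + 2 + m, 4 * n + 2 + 2 * m),
        urine=4 * n + 2 + 2 * m,
        metabolite=4 * n + 2 + 2 * m + 1,
        faeces=4 * n + 2 + 2 * m + 2,
        n_states=4 * n + 2 + 2 * m + 3,
    )


@dataclass
class ODESystem:
    """Assembled state-space model: index, initial state, rate function."""

    index: StateIndex
    y0: np.ndarray
    rhs: Callable[[float, np.ndarray], np.ndarray]
    dose: float  # umol, total administered
    dosed_at: Callable[[float], float]  # umol administered by time t
    phys: PhysiologyParameters
    compound: CompoundProperties
    clearance: ClearanceSpec
    protocol: AdministrationProtocol

    def mass_closure_residual(self, t: float, y: np.ndarray) -> float:
        """|d(total mass)/dt - external input rate| at a given state."""
        dy = self.rhs(t, y)
        infusion = self.dose / self.protocol.infusion_duration if (
            self.protocol.route is Route.iv_infusion
            and t < self.protocol.infusion_duration
        ) else 0.0
        return abs(float(dy.sum()) - infusion)


@dataclass
class SimulationResult:
    """Concentration-time output plus cumulative sinks and solver metadata."""

    times: np.ndarray  # min
    states: np.ndarray  # (n_times, n_states), umol
    index: StateIndex
    dose: float  # umol
    system: ODESystem
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.states < NEGATIVE_FLOOR):
            worst = float(self.states.min())
            self.metadata.setdefault("negative_excursion", worst)
        self.states = np.clip(self.states, 0.0, None)

    # -- concentrations --------------------------------------------------

    def _pool_plasma_conc(self, pos: int, volume: float) -> np.ndarray:
        h = self.system.phys.haematocrit
        beta = (1.0 - h) + h * self.system.compound.blood_plasma_ratio
        return self.states[:, pos] / (volume * beta)

    @property
    def venous_plasma(self) -> np.ndarray:
        return self._pool_plasma_conc(self.index.venous, self.system.phys.venous_volume)

    @property
    def arterial_plasma(self) -> np.ndarray:
        return self._pool_plasma_conc(self.index.arterial, self.system.phys.arterial_volume)

    def tissue_concentration(self, organ: str) -> np.ndarray:
        """Whole-tissue concentration (all sub-compartments / organ volume)."""
        i = self.index.organ_names.index(organ)
        amount = (
            self.states[:, self.index.plasma[i]]
            + self.states[:, self.index.rbc[i]]
            + self.states[:, self.index.interstitial[i]]
            + self.states[:, self.index.cellular[i]]
        )
        return amount / self.system.phys.organ(organ).volume

    def concentration(self, compartment: str) -> np.ndarray:
        if compartment == "venous_plasma":
            return self.venous_plasma
        if compartment == "arterial_plasma":
            return self.arterial_plasma
        return self.tissue_concentration(compartment)

    @property
    def urine(self) -> np.ndarray:
        return self.states[:, self.index.urine]

    @property
    def metabolite(self) -> np.ndarray:
        return self.states[:, self.index.metabolite]

    @property
    def faeces(self) -> np.ndarray:
        return self.states[:, self.index.faeces]

    def lumen_total(self) -> np.ndarray:
        return (
            self.states[:, self.index.lumen_solid].sum(axis=1)
            + self.states[:, self.index.lumen_dissolved].sum(axis=1)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format results table (time_min, compartment, quantity, unit)."""
        rows = []
        for name in ("venous_plasma", "arterial_plasma"):
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "compartment": name,
                        "quantity": self.concentration(name),
                        "unit": "umol/L",
                    }
                )
            )
        for organ in self.index.organ_names:
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "compartment": organ,
                        "quantity": self.tissue_concentration(organ),
                        "unit": "umol/L",
                    }
                )
            )
        for sink in ("urine", "metabolite", "faeces"):
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "compartment": sink,
                        "quantity": getattr(self, sink),
                        "unit": "umol",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_ode_system(
    phys: PhysiologyParameters,
    compound: CompoundProperties,
    clearance: ClearanceSpec,
    protocol: AdministrationProtocol,
) -> ODESystem:
    """Assemble the whole-body ODE for one compound and protocol."""
    large = compound.size_class is SizeClass.large
    if large and protocol.route is Route.oral:
        raise ConfigurationError(
            "oral administration is not defined for large (pore-limited) molecules"
        )

    idx = build_state_index(phys)
    organs = phys.organs
    n = len(organs)
    names = idx.organ_names
    for required in ("lung", "liver", "kidney"):
        if required not in names:
            raise ConfigurationError(f"physiology must include a {required!r} organ")
    i_lung = names.index("lung")
    i_liver = names.index("liver")
    i_kidney = names.index("kidney")

    h = phys.haematocrit
    k_rbc_part = compound.blood_plasma_ratio
    beta = (1.0 - h) + h * k_rbc_part
    fu = compound.fu

    V = np.array([o.volume for o in organs])
    fv = np.array([o.fraction_vascular for o in organs])
    fi = np.array([o.fraction_interstitial for o in organs])
    fc = np.array([o.fraction_cellular for o in organs])
    V_pl = V * fv * (1.0 - h)
    V_rbc = np.maximum(V * fv * h, 1e-12)
    V_int = np.maximum(V * fi, 1e-12)
    V_cell = np.maximum(V * fc, 1e-12)

    Q = np.array([o.blood_flow for o in organs])
    portal = np.array([o.name in PORTAL_ORGANS for o in organs])
    CO = float(Q[~(np.arange(n) == i_lung)].sum())
    Q[i_lung] = CO
    Q_portal = float(Q[portal].sum())
    Q_out = Q.copy()
    Q_out[i_liver] = Q[i_liver] + Q_portal
    # direct-to-venous organs: everything systemic except portal organs, liver
    direct = np.ones(n, dtype=bool)
    direct[[i_lung, i_liver]] = False
    direct &= ~portal

    SA = np.array([o.exchange_surface_area for o in organs])
    if large:
        K_pore = np.array([o.hydraulic_conductivity for o in organs]) * SA  # L/min
        PS_pi = None
        PS_cell = np.zeros(n)
        Kp_cell = np.ones(n)
    else:
        perm = membrane_permeability(compound)
        kp = partition_coefficients(compound, phys)
        PS_pi = FLOW_EXCHANGE_FACTOR * Q  # L/min
        PS_cell = perm * SA  # L/min
        Kp_cell = np.array(
            [cellular_partition(kp.kp[o.name], o) for o in organs]
        )
        K_pore = None

    # clearance terms
    gfr_CL = clearance.gfr_fraction * phys.GFR_specific * phys.kidney_weight * fu
    sec_CL = clearance.tubular_secretion_CL
    hep_CL = clearance.hepatic_CL_total(phys)
    ref_u = clearance.reference_concentration == "unbound"
    ref_factor = fu if ref_u else 1.0
    V_liver = phys.organ("liver").volume
    enzymes = [(e.Vmax * e.E * V_liver, e.Km) for e in clearance.enzymes]

    # GIT lumen
    m = len(phys.git)
    k_tr = np.empty(m)
    get_hr = protocol.GET_hr if protocol.GET_hr is not None else phys.GET_hr
    for j, seg in enumerate(phys.git):
        k_tr[j] = 1.0 / (get_hr * 60.0) if j == 0 else 1.0 / seg.transit_time
    V_lumen = np.array([s.lumen_volume for s in phys.git])
    oral = protocol.route is Route.oral
    if oral:
        try:
            wall_idx = np.array(
                [names.index(SEGMENT_WALL_ORGAN[s.name]) for s in phys.git]
            )
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(
                f"oral dosing needs gut-wall organs for every GIT segment: {exc}"
            ) from exc
    else:
        wall_idx = np.zeros(m, dtype=int)
    if oral and not large:
        perm_abs = membrane_permeability(compound)
        P_eff = np.array(
            [perm_abs * neutral_fraction(compound, s.pH) for s in phys.git]
        )
        ESA = np.array([effective_surface_area(s) for s in phys.git])
        ka_lumen = P_eff * ESA / V_lumen  # 1/min, per segment
    else:
        ka_lumen = np.zeros(m)
    tablet = (
        oral
        and protocol.formulation is not None
        and protocol.formulation.kind is not FormulationKind.solution
    )
    DT = protocol.formulation.DT if tablet else 1.0
    DS = protocol.formulation.DS if tablet else 1.0

    dose = protocol.dose_umol(phys, compound)
    infusion = protocol.route is Route.iv_infusion
    inf_rate = dose / protocol.infusion_duration if infusion else 0.0
    inf_dur = protocol.infusion_duration if infusion else 0.0

    V_art = phys.arterial_volume
    V_ven = phys.venous_volume
    ip, ir, ii, ic = idx.plasma, idx.rbc, idx.interstitial, idx.cellular
    isol, idis = idx.lumen_solid, idx.lumen_dissolved
    i_art, i_ven = idx.arterial, idx.venous
    i_ur, i_met, i_fae = idx.urine, idx.metabolite, idx.faeces
    k_rbc_eq = RBC_EXCHANGE_RATE

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        C_pl = y[ip] / V_pl
        C_rbc = y[ir] / V_rbc
        C_int = y[ii] / V_int
        C_art_pl = y[i_art] / (V_art * beta)
        C_ven_pl = y[i_ven] / (V_ven * beta)

        # convective transport (plasma and RBC streams)
        in_pl = Q * (1.0 - h) * C_art_pl
        in_rbc = Q * h * k_rbc_part * C_art_pl
        in_pl[i_lung] = Q[i_lung] * (1.0 - h) * C_ven_pl
        in_rbc[i_lung] = Q[i_lung] * h * k_rbc_part * C_ven_pl
        out_pl = Q_out * (1.0 - h) * C_pl
        out_rbc = Q_out * h * C_rbc
        in_pl[i_liver] += out_pl[portal].sum()
        in_rbc[i_liver] += out_rbc[portal].sum()

        d_pl = in_pl - out_pl
        d_rbc = in_rbc - out_rbc
        dy[i_art] = out_pl[i_lung] + out_rbc[i_lung] - Q[i_lung] * beta * C_art_pl
        dy[i_ven] = (
            out_pl[direct].sum()
            + out_rbc[direct].sum()
            + out_pl[i_liver]
            + out_rbc[i_liver]
            - Q[i_lung] * beta * C_ven_pl
        )

        # RBC <-> plasma equilibration within organs
        j_rbc = k_rbc_eq * V_rbc * (k_rbc_part * C_pl - C_rbc)
        d_pl -= j_rbc
        d_rbc += j_rbc

        # distribution
        if large:
            j_pi = K_pore * (C_pl - C_int)
            d_pl -= j_pi
            d_int = j_pi
            d_cell = np.zeros_like(d_int)
        else:
            C_cell = y[ic] / V_cell
            j_pi = PS_pi * fu * (C_pl - C_int)
            j_ic = PS_cell * fu * (C_int - C_cell / Kp_cell)
            d_pl -= j_pi
            d_int = j_pi - j_ic
            d_cell = j_ic

        # renal elimination (kidney vascular plasma -> urine)
        c_kid = C_pl[i_kidney]
        renal = gfr_CL * c_kid + sec_CL * ref_factor * c_kid
        d_pl[i_kidney] -= renal
        dy[i_ur] = renal

        # hepatic elimination (liver vascular plasma -> metabolite)
        c_liv_ref = ref_factor * C_pl[i_liver]
        hep = hep_CL * c_liv_ref
        for vmax_v, km in enzymes:
            hep += vmax_v * c_liv_ref / (km + c_liv_ref)
        d_pl[i_liver] -= hep
        dy[i_met] = hep

        # GIT lumen: dissolution, transit, absorption
        if oral:
            S = y[isol]
            D = y[idis]
            if tablet:
                hz = weibull_hazard(t, DT, DS)
                diss = hz * S
            else:
                diss = np.zeros(m)
            tr_S = k_tr * S
            tr_D = k_tr * D
            absorbed = ka_lumen * D
            dS = -diss - tr_S
            dS[1:] += tr_S[:-1]
            dD = diss - tr_D - absorbed
            dD[1:] += tr_D[:-1]
            dy[isol] = dS
            dy[idis] = dD
            dy[i_fae] = tr_S[-1] + tr_D[-1]
            for j in range(m):
                d_pl[wall_idx[j]] += absorbed[j]

        if infusion and t < inf_dur:
            dy[i_ven] += inf_rate

        dy[ip] = d_pl
        dy[ir] = d_rbc
        dy[ii] = d_int
        dy[ic] = d_cell
        return dy

    y0 = apply_dose(protocol, np.zeros(idx.n_states), idx, phys, compound)

    def dosed_at(t: float) -> float:
        if infusion:
            return dose * min(t / inf_dur, 1.0)
        return dose

    return ODESystem(
        index=idx,
        y0=y0,
        rhs=rhs,
        dose=dose,
        dosed_at=dosed_at,
        phys=phys,
        compound=compound,
        clearance=clearance,
        protocol=protocol,
    )


def run_simulation(
    system: ODESystem,
    t_end: float,
    output_step: float = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the system to ``t_end`` with dense output on a fixed grid.

    The uniform grid is augmented with a geometric refinement over the
    first minutes so the rapid venous mixing transient after an i.v. bolus
    is resolved (trapezoidal AUCs would otherwise overweight the spike).
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    uniform = np.arange(0.0, t_end + 0.5 * output_step, output_step)
    uniform = uniform[uniform <= t_end]
    early = np.geomspace(1e-3, min(30.0, t_end / 2.0), 60)
    t_eval = np.unique(np.concatenate([uniform, early]))
    sol = solve_ivp(
        system.rhs,
        (0.0, float(t_end)),
        system.y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    meta = {
        "solver": method,
        "rtol": rtol,
        "atol": atol,
        "n_rhs_evaluations": int(sol.nfev),
        "n_steps": len(sol.t),
    }
    return SimulationResult(
        times=sol.t, states=sol.y.T, index=system.index, dose=system.dose,
        system=system, metadata=meta,
    )


def mass_balance_residual(result: SimulationResult) -> float:
    """Max over time of |dosed(t) - total mass(t)| / dose."""
    total = result.states.sum(axis=1)
    dosed = np.array([result.system.dosed_at(t) for t in result.times])
    return float(np.max(np.abs(dosed - total)) / result.dose)
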