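import numpy as np
import pytest

import rabbitpbpk as rp


@pytest.fixture(scope="session")
def default_phys():
    return rp.load_physiology()


@pytest.fixture(scope="session")
def catalogue():
    return rp.list_scenarios()


@pytest.fixture(scope="session")
def sim_cache(catalogue):
    """Memoized scenario simulations shared across the suite."""
    cache: dict[tuple[str, str], rp.SimulationResult] = {}

    def run(scenario_id: str, mode: str = "optimized") -> rp.SimulationResult:
        key = (scenario_id, mode)
        if key not in cache:
            cache[key] = rp.simulate_scenario(catalogue[scenario_id], mode=mode)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def table1():
    return rp.table1_fixture()


def one_compartment_setup(CL: float = 0.01):
    """Reduced body (three fast-perfused organs) that behaves one-compartment.

    With very fast perfusion and a large permeability override, all
    compartments equilibrate within a couple of minutes and the venous
    profile decays as C0*exp(-k t) with k = CL / V_eff, where the effective
    volume V_eff follows from the parameters alone (independent oracle).
    """
    doc = rp.physiology.default_physiology_document()
    doc["organs"] = [o for o in doc["organs"] if o["name"] in ("lung", "liver", "kidney")]
    for o in doc["organs"]:
        o["specific_blood_flow"] = 500.0
    phys = rp.load_physiology(doc, merge_defaults=False)
    comp = rp.CompoundProperties(
        name="probe", MW=300.0, logP=0.0, fu=1.0, permeability_override=10.0
    )
    clr = rp.ClearanceSpec(
        gfr_fraction=0.0, hepatic_CL_firstorder=CL, reference_concentration="total"
    )
    prot = rp.AdministrationProtocol(route="iv_bolus", dose=10.0, dose_unit="mg")
    kp = rp.partition_coefficients(comp, phys)
    v_eff = phys.arterial_volume + phys.venous_volume
    for o in phys.organs:
        kpc = rp.compound.cellular_partition(kp.kp[o.name], o)
        v_eff += o.volume * (
            o.fraction_vascular + o.fraction_interstitial + o.fraction_cellular * kpc
        )
    system = rp.build_ode_system(phys, comp, clr, prot)
    return system, v_eff


@pytest.fixture(scope="session")
def low_extraction_iv():
    """Whole-body i.v. bolus with one small linear clearance (AUC = D/CL)."""
    phys = rp.load_physiology()
    comp = rp.CompoundProperties(name="probe", MW=300.0, logP=0.0, fu=1.0)
    CL = 3e-4
    clr = rp.ClearanceSpec(
        gfr_fraction=0.0, hepatic_CL_firstorder=CL, reference_concentration="total"
    )
    prot = rp.AdministrationProtocol(route="iv_bolus", dose=10.0, dose_unit="mg")
    system = rp.build_ode_system(phys, comp, clr, prot)
    result = rp.run_simulation(system, t_end=20000.0, output_step=10.0)
    return system, result, CL


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def one_compartment_scenario(default_phys):
    """Synthetic scenario that reduces to one compartment (AUC = D/CL).

    Very fast perfusion plus a large permeability override collapse the
    whole body into a single well-mixed volume; the venous AUC then equals
    Dose/CL up to O(CL/Q) corrections of ~1e-4.
    """
    overrides = {
        f"physiology.organs.{o.name}.specific_blood_flow": 500.0
        for o in default_phys.organs
    }
    return rp.Scenario(
        id="one_compartment_reduction",
        description="synthetic fast-exchange body for closed-form oracles",
        body_weight=2.5,
        compound=rp.CompoundProperties(
            name="probe", MW=300.0, logP=0.0, fu=1.0, permeability_override=10.0
        ),
        clearance=rp.ClearanceSpec(
            gfr_fraction=0.0,
            hepatic_CL_firstorder=0.01,
            reference_concentration="total",
        ),
        protocol=rp.AdministrationProtocol(route="iv_bolus", dose=10.0, dose_unit="mg"),
        physiology_overrides=overrides,
        t_end_min=4000.0,
        output_step_min=2.0,
    )
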