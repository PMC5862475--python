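"""Whole-body ODE assembly, integration fidelity, and conservation."""

import numpy as np
import pytest

import rabbitpbpk as rp
from rabbitpbpk.engine import ConfigurationError, build_state_index
from tests.conftest import one_compartment_setup


class TestAssembly:
    def test_state_dimension_counts_all_compartments(self, default_phys):
        # 14 organs * 4 sub-compartments + arterial/venous + 5 segments * 2
        # luminal pools + 3 sinks
        idx = build_state_index(default_phys)
        assert idx.n_states == 14 * 4 + 2 + 5 * 2 + 3 == 71

    def test_zero_dose_system_stays_identically_zero(self, default_phys):
        comp = rp.CompoundProperties(name="x", MW=300.0, logP=0.0, fu=0.9)
        clr = rp.ClearanceSpec(hepatic_CL_firstorder=0.01)
        prot = rp.AdministrationProtocol(route="iv_bolus", dose=1.0, dose_unit="mg")
        system = rp.build_ode_system(default_phys, comp, clr, prot)
        system.y0[:] = 0.0
        res = rp.run_simulation(system, t_end=100.0, output_step=5.0)
        assert np.all(res.states == 0.0)

    def test_large_molecule_cellular_pools_stay_empty(self, sim_cache):
        res = sim_cache("inulin_iv_200")
        assert np.all(res.states[:, res.index.cellular] == 0.0)
        assert np.all(res.states[:, res.index.rbc] == 0.0)  # plasma-confined

    def test_oral_large_molecule_rejected(self, default_phys):
        comp = rp.CompoundProperties(
            name="big", MW=5000.0, logP=-4.0, fu=1.0, size_class="large",
            solubility=10.0,
        )
        prot = rp.AdministrationProtocol(
            route="oral", dose=10.0, dose_unit="mg", formulation={"kind": "solution"}
        )
        with pytest.raises(ConfigurationError):
            rp.build_ode_system(default_phys, comp, rp.ClearanceSpec(), prot)

    def test_rate_function_closes_mass(self, catalogue):
        system = rp.scenarios.build_scenario_system(catalogue["caffeine_iv_4"])
        y = system.y0 + 1e-3
        assert system.mass_closure_residual(10.0, y) < 1e-10


class TestIntegrationFidelity:
    def test_one_compartment_reduction_matches_exponential(self):
        system, v_eff = one_compartment_setup(CL=0.01)
        res = rp.run_simulation(system, t_end=100.0, output_step=0.5)
        k = 0.01 / v_eff
        c0 = system.dose / v_eff
        mask = (res.times >= 5.0) & (res.times <= 70.0)
        pred = c0 * np.exp(-k * res.times[mask])
        rel = np.abs(res.venous_plasma[mask] - pred) / pred
        assert rel.max() < 1e-3

    def test_halving_tolerances_barely_moves_auc(self, catalogue):
        sc = catalogue["caffeine_iv_4"]
        a1 = rp.simulation_metrics(
            rp.simulate_scenario(sc, rtol=1e-8, atol=1e-10)
        ).AUC
        a2 = rp.simulation_metrics(
            rp.simulate_scenario(sc, rtol=5e-9, atol=5e-11)
        ).AUC
        assert abs(a1 - a2) / a1 < 1e-3

    def test_infusion_delivers_dose_over_duration(self, default_phys):
        comp = rp.CompoundProperties(name="x", MW=300.0, logP=0.0, fu=1.0)
        clr = rp.ClearanceSpec(gfr_fraction=0.0, hepatic_CL_firstorder=0.005)
        prot = rp.AdministrationProtocol(
            route="iv_infusion", dose=10.0, dose_unit="mg", infusion_duration=60.0
        )
        system = rp.build_ode_system(default_phys, comp, clr, prot)
        res = rp.run_simulation(system, t_end=240.0, output_step=1.0)
        total = res.states.sum(axis=1)
        i30 = np.searchsorted(res.times, 30.0)
        assert total[i30] == pytest.approx(system.dose / 2.0, rel=1e-5)
        assert total[-1] == pytest.approx(system.dose, rel=1e-8)


class TestConservationAndInvariance:
    def test_mass_balance_for_every_packaged_scenario(self, catalogue, sim_cache):
        for sid in catalogue:
            res = sim_cache(sid)
            assert rp.mass_balance_residual(res) < 1e-3, sid

    def test_corrupted_result_is_flagged(self, sim_cache):
        res = sim_cache("caffeine_iv_4")
        broken = rp.SimulationResult(
            times=res.times,
            states=res.states * 1.5,
            index=res.index,
            dose=res.dose,
            system=res.system,
        )
        assert rp.mass_balance_residual(broken) > 1e-3

    def test_dose_linearity_for_linear_configuration(self, catalogue):
        sc = catalogue["inulin_iv_200"]
        r1 = rp.simulate_scenario(sc)
        r2 = rp.simulate_scenario(sc, dose_scale=2.0)
        a1 = rp.simulation_metrics(r1, extrapolate=False).AUC
        a2 = rp.simulation_metrics(r2, extrapolate=False).AUC
        assert a2 / a1 == pytest.approx(2.0, rel=1e-6)

    def test_saturable_kinetics_break_dose_linearity(self, catalogue):
        # paracetamol runs near its Km: doubling the dose more than doubles AUC
        sc = catalogue["paracetamol_iv_35"]
        a1 = rp.simulation_metrics(rp.simulate_scenario(sc), extrapolate=False).AUC
        a2 = rp.simulation_metrics(
            rp.simulate_scenario(sc, dose_scale=2.0), extrapolate=False
        ).AUC
        assert a2 > 2.05 * a1

    def test_organ_declaration_order_is_irrelevant(self):
        doc = rp.physiology.default_physiology_document()
        comp = rp.CompoundProperties(name="x", MW=300.0, logP=0.3, fu=0.8)
        clr = rp.ClearanceSpec(gfr_fraction=1.0, hepatic_CL_firstorder=0.01)
        prot = rp.AdministrationProtocol(route="iv_bolus", dose=5.0, dose_unit="mg")

        res = []
        for order in (1, -1):
            shuffled = dict(doc)
            shuffled["organs"] = doc["organs"][::order]
            phys = rp.load_physiology(shuffled, merge_defaults=False)
            system = rp.build_ode_system(phys, comp, clr, prot)
            res.append(rp.run_simulation(system, t_end=300.0, output_step=1.0))
        assert np.allclose(res[0].venous_plasma, res[1].venous_plasma, rtol=1e-6)
        assert np.allclose(
            res[0].tissue_concentration("liver"),
            res[1].tissue_concentration("liver"),
            rtol=1e-6,
        )

    def test_negative_floor_clipping(self, sim_cache):
        res = sim_cache("inulin_iv_200")
        assert np.all(res.states >= 0.0)
        assert np.all(np.diff(res.times) > 0)


class TestResultExport:
    def test_long_format_frame(self, sim_cache):
        df = sim_cache("caffeine_iv_4").to_frame()
        assert set(df.columns) == {"time_min", "compartment", "quantity", "unit"}
        assert "venous_plasma" in set(df["compartment"])
        assert "urine" in set(df["compartment"])
        assert set(df["unit"]) == {"umol/L", "umol"}
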