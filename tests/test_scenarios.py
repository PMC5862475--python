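"""Scenario catalogue, reference table fixture, synthetic data generator."""

import hashlib
from importlib import resources

import numpy as np
import pytest

import rabbitpbpk as rp
from rabbitpbpk.scenarios import DomainError, build_inputs, get_path, set_path


class TestCatalogue:
    def test_catalogue_covers_all_six_compounds_and_routes(self, catalogue):
        assert len(catalogue) >= 10
        compounds = {sc.compound.name for sc in catalogue.values()}
        assert compounds == {
            "inulin", "caffeine", "ofloxacin", "theophylline", "paracetamol",
            "acyclovir",
        }
        kinds = {
            sc.protocol.formulation.kind.value
            for sc in catalogue.values()
            if sc.compound.name == "paracetamol" and sc.protocol.route.value == "oral"
        }
        assert kinds == {"solution", "rapid_tablet", "conventional_tablet"}

    def test_inulin_is_a_pore_limited_large_molecule(self, catalogue):
        for sid, sc in catalogue.items():
            if sc.compound.name == "inulin":
                assert sc.compound.size_class.value == "large"
                assert "pore_limited" in sc.tags

    def test_study_body_weights(self, catalogue):
        assert catalogue["caffeine_iv_4"].body_weight == 3.5
        assert catalogue["inulin_iv_40"].body_weight == 2.85
        assert catalogue["theophylline_iv_15"].body_weight == 3.15
        assert catalogue["acyclovir_po_300"].body_weight == 3.6

    def test_every_scenario_simulates_under_default_tolerances(self, catalogue, sim_cache):
        for sid in catalogue:
            res = sim_cache(sid)
            assert res.times[-1] == pytest.approx(catalogue[sid].t_end_min)
            assert np.isfinite(res.venous_plasma).all()

    def test_unknown_scenario_id_lists_catalogue(self):
        with pytest.raises(KeyError, match="available"):
            rp.load_scenario("nope")


class TestReferenceTable:
    def test_sixteen_rows_with_known_cells(self, table1):
        assert len(table1) == 16
        plasma = table1[table1["tissue_administration"] == "Plasma/i.v."].iloc[0]
        assert (plasma["auc_observed"], plasma["auc_predicted"], plasma["auc_optimized"]) == (
            6901.24, 9383.03, 7564.91,
        )
        caffeine = table1[table1["compound"] == "caffeine"].iloc[0]
        assert (caffeine["auc_observed"], caffeine["auc_predicted"], caffeine["auc_optimized"]) == (
            5432.82, 7747.60, 5739.40,
        )
        assert table1["auc_optimized"].isna().sum() == 2  # the 40/60 mg/kg rows

    def test_fixture_checksum_guards_verbatim_values(self):
        text = resources.files("rabbitpbpk.data").joinpath("table1.csv").read_bytes()
        assert hashlib.sha256(text).hexdigest() == (
            "63c76dc055f55f0359a240027883e1daeaa0ea591b6818f2b12585582b600f3c"
        )

    def test_every_row_maps_to_one_scenario_and_compartment(self, table1, catalogue):
        for _, row in table1.iterrows():
            sc = catalogue[row["scenario_id"]]
            comp = row["compartment"]
            if comp != "venous_plasma":
                assert comp in [o.name for o in build_inputs(sc).physiology.organs]
        assert not table1.duplicated(["scenario_id", "compartment"]).any()


class TestOverridePaths:
    def test_get_and_set_by_name_and_index(self, catalogue):
        inp = build_inputs(catalogue["caffeine_iv_4"], mode="predicted")
        doc = {
            "physiology": inp.physiology.model_dump(),
            "clearance": inp.clearance.model_dump(),
        }
        assert get_path(doc, "clearance.enzymes.0.Km") == 400.0
        set_path(doc, "physiology.organs.kidney.volume", 0.02)
        assert get_path(doc, "physiology.organs.kidney.volume") == 0.02

    def test_fraction_override_rebalances_cellular(self, catalogue):
        inp = build_inputs(
            catalogue["inulin_iv_200"],
            extra_overrides={"physiology.organs.lung.fraction_interstitial": 0.40},
        )
        lung = inp.physiology.organ("lung")
        assert lung.fraction_interstitial == 0.40
        total = lung.fraction_vascular + lung.fraction_interstitial + lung.fraction_cellular
        assert total == pytest.approx(1.0)

    def test_predicted_vs_optimized_modes(self, catalogue):
        sc = catalogue["caffeine_iv_4"]
        pred = build_inputs(sc, mode="predicted")
        opt = build_inputs(sc, mode="optimized")
        assert (pred.compound.fu, pred.clearance.enzymes[0].Km) == (0.7, 400.0)
        assert (opt.compound.fu, opt.clearance.enzymes[0].Km) == (0.8, 300.0)

    def test_baseline_physiology_untouched_by_overrides(self, catalogue):
        build_inputs(
            catalogue["inulin_iv_200"],
            extra_overrides={"physiology.GFR_specific": 1.5},
        )
        assert rp.load_physiology().GFR_specific == 0.6


class TestSyntheticData:
    def test_zero_noise_reproduces_simulation(self, catalogue, sim_cache):
        sc = catalogue["caffeine_iv_4"]
        res = sim_cache("caffeine_iv_4")
        obs = rp.generate_observed_data(sc, [10.0, 60.0, 360.0], 0.0, seed=1, result=res)
        expected = np.interp([10.0, 60.0, 360.0], res.times, res.venous_plasma)
        assert np.allclose(obs.concentrations, expected)

    def test_same_seed_same_dataset(self, catalogue, sim_cache):
        sc = catalogue["caffeine_iv_4"]
        res = sim_cache("caffeine_iv_4")
        a = rp.generate_observed_data(sc, [10.0, 60.0], 0.15, seed=7, result=res)
        b = rp.generate_observed_data(sc, [10.0, 60.0], 0.15, seed=7, result=res)
        c = rp.generate_observed_data(sc, [10.0, 60.0], 0.15, seed=8, result=res)
        assert a.concentrations == b.concentrations
        assert a.concentrations != c.concentrations

    def test_noise_model_cv_is_calibrated(self, catalogue, sim_cache):
        # Monte-Carlo check: many replicate draws at one time point show the
        # requested coefficient of variation
        sc = catalogue["caffeine_iv_4"]
        res = sim_cache("caffeine_iv_4")
        draws = np.array(
            [
                rp.generate_observed_data(sc, [60.0], 0.15, seed=s, result=res).concentrations[0]
                for s in range(10_000)
            ]
        )
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(0.15, rel=0.05)

    def test_sampling_outside_horizon_rejected(self, catalogue, sim_cache):
        sc = catalogue["caffeine_iv_4"]
        res = sim_cache("caffeine_iv_4")
        with pytest.raises(DomainError):
            rp.generate_observed_data(sc, [1e6], 0.1, seed=1, result=res)
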