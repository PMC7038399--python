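"""Algorithm registry, predictor/response evaluation, and the Kd chain."""

import math

import numpy as np
import pandas as pd
import pytest

from lakeowt.owt import OWT_CLASSES, UNCLASSIFIED
from lakeowt.retrieval import (PRODUCTS, Kd490Model, RegistryError,
                               ResponseForm, builtin_registry, eval_predictor,
                               kd490, kdpar_from_kd490, retrieve,
                               retrieve_scene, sd_from_kdpar)
from lakeowt.spectra import SceneStack, column_name
from lakeowt.synthetic import (SceneSpec, generate_scene, quadrant_labels,
                               reference_library)
from lakeowt.owt import classify_scene


class TestRegistry:
    def test_forty_entries_complete(self, registry):
        assert len(registry) == 40
        for sensor in ("MSI", "OLCI"):
            for product in PRODUCTS:
                for owt in OWT_CLASSES:
                    registry.get(sensor, product, owt)  # must resolve

    def test_msi_brown_chl_lookup(self, registry):
        spec = registry.get("MSI", "chl", "Brown")
        assert spec.source == "TOA"
        assert spec.predictor.replace(" ", "") == "R705/R665"
        assert spec.response.form == "linear"
        assert spec.response.coeffs == (293.5, -263.4)

    def test_olci_moderate_cdom_lookup(self, registry):
        spec = registry.get("OLCI", "cdom400", "Moderate")
        assert spec.source == "C2RCC"
        assert spec.predictor.replace(" ", "") == "R665/R490"
        assert spec.response.form == "exponential"
        assert spec.response.coeffs == (9.4, -0.67)

    def test_duplicate_entry_rejected(self, registry):
        from lakeowt.retrieval import Registry
        specs = list(registry) + [registry.get("MSI", "chl", "Clear")]
        with pytest.raises(RegistryError, match="duplicate"):
            Registry(specs)

    def test_unknown_band_rejected(self):
        from lakeowt.retrieval import AlgorithmSpec
        with pytest.raises(RegistryError, match="R999"):
            AlgorithmSpec("MSI", "chl", "Clear", "TOA", "R999/R665",
                          ResponseForm("linear", (1.0, 0.0)))

    def test_coefficient_recovery_all_entries(self, registry):
        """Least squares on a noise-free predictor grid returns every
        registry coefficient to relative 1e-6 (log-space for power/exp)."""
        for spec in registry:
            lo, hi = spec.sim_range
            x = np.linspace(lo, hi, 50)
            y = np.array([spec.response(v) for v in x])
            assert np.all(np.isfinite(y)), spec.key
            c = spec.response.coeffs
            if spec.response.form == "linear":
                fit = np.polyfit(x, y, 1)
                assert np.allclose(fit, c, rtol=1e-6), spec.key
            elif spec.response.form == "quadratic":
                fit = np.polyfit(x, y, 2)
                assert np.allclose(fit, c, rtol=1e-6), spec.key
            elif spec.response.form == "power":
                b, loga = np.polyfit(np.log(x), np.log(y), 1)
                assert math.exp(loga) == pytest.approx(c[0], rel=1e-6), spec.key
                assert b == pytest.approx(c[1], rel=1e-6), spec.key
            else:  # exponential
                b, loga = np.polyfit(x, np.log(y), 1)
                assert math.exp(loga) == pytest.approx(c[0], rel=1e-6), spec.key
                assert b == pytest.approx(c[1], rel=1e-6), spec.key


class TestPredictors:
    def test_ratio(self):
        assert eval_predictor("R705/R665", {"R705": 0.02, "R665": 0.01}) == 2.0

    def test_ratio_difference_symmetry(self):
        env = {"R740": 0.02, "R705": 0.02, "R665": 0.02}
        assert eval_predictor("R740/R705 - R740/R665", env) == 0.0

    def test_peak_height_hand_value(self):
        env = {"R709": 0.010, "R665": 0.008, "R754": 0.006}
        assert eval_predictor("R709 - (R665 + R754)/2", env) == pytest.approx(0.003)

    def test_nan_propagates(self):
        out = eval_predictor("R705/R665", {"R705": float("nan"), "R665": 0.01})
        assert math.isnan(out)

    def test_division_by_zero_is_missing(self):
        assert math.isnan(eval_predictor("R705/R665", {"R705": 0.02, "R665": 0.0}))


class TestResponses:
    def test_msi_brown_chl_at_unit_ratio(self, registry):
        spec = registry.get("MSI", "chl", "Brown")
        assert spec.response(1.0) == pytest.approx(30.1)

    def test_power_form_rejects_nonpositive(self):
        f = ResponseForm("power", (2.0, -1.0))
        assert math.isnan(f(0.0)) and math.isnan(f(-1.0))

    def test_quadratic_domain_restriction(self, registry):
        spec = registry.get("MSI", "cdom400", "Brown")  # domain (0.5, 3.0)
        assert math.isfinite(spec.response(1.5))
        assert math.isnan(spec.response(10.0))


class TestKdChain:
    def test_kdpar_intercept_at_zero(self):
        assert kdpar_from_kd490(0.0) == pytest.approx(0.3291)

    def test_sd_prefactor_at_unit_kdpar(self):
        assert sd_from_kdpar(1.0) == pytest.approx(1.6941)

    def test_chain_monotonicity(self):
        kd = np.linspace(0.05, 5.0, 200)
        kp = np.array([kdpar_from_kd490(v) for v in kd])
        sd = np.array([sd_from_kdpar(v) for v in kp])
        assert np.all(np.diff(kp) > 0)
        assert np.all(np.diff(sd) < 0)

    def test_degenerate_model_is_constant(self):
        m = Kd490Model(c0=-0.5, c1=0.0, c2=0.0)
        assert m.evaluate(0.01, 0.05, 0.02) == pytest.approx(10 ** -0.5)

    def test_monotone_in_red_band(self):
        m = Kd490Model()
        row = {"TOA_R490": 0.02, "TOA_R560": 0.03}
        vals = [m.evaluate(0.02, 0.03, r) for r in np.linspace(0.005, 0.1, 40)]
        assert np.all(np.diff(vals) > 0)

    def test_sensor_binds_its_red_band(self):
        m = Kd490Model()
        msi_row = pd.Series({"TOA_R490": 0.02, "TOA_R560": 0.03, "TOA_R705": 0.02})
        olci_row = pd.Series({"TOA_R490": 0.02, "TOA_R560": 0.03, "TOA_R709": 0.02})
        assert kd490(msi_row, "MSI", "TOA") == pytest.approx(
            kd490(olci_row, "OLCI", "TOA"))
        # MSI row lacking R705 cannot evaluate
        assert math.isnan(kd490(olci_row, "MSI", "TOA"))

    def test_nonpositive_band_is_missing(self):
        m = Kd490Model()
        assert math.isnan(m.evaluate(-0.01, 0.03, 0.02))


class TestRetrieve:
    def test_msi_brown_chl_from_ratio(self, registry):
        row = pd.Series({"TOA_R705": 0.02, "TOA_R665": 0.01})
        out = retrieve(row, "Brown", "MSI", registry)
        assert out["chl"].value == pytest.approx(293.5 * 2.0 - 263.4)  # 323.6
        assert out["chl"].source == "TOA"

    def test_msi_moderate_tsm_from_processor_field(self, registry):
        row = pd.Series({"C2RCC_conc_tsm": 10.0})
        out = retrieve(row, "Moderate", "MSI", registry)
        assert out["tsm"].value == pytest.approx(-0.91 * 10.0 + 39.29)  # 30.19

    def test_missing_field_leaves_other_products(self, registry):
        row = pd.Series({
            "TOA_R665": 0.03, "TOA_R709": 0.028, "TOA_R754": 0.02,
            "C2RCC_R665": 0.02, "C2RCC_R490": 0.015,
        })
        out = retrieve(row, "Moderate", "OLCI", registry)
        assert math.isnan(out["tsm"].value)  # needs C2RCC NIR bands
        assert "missing" in out["tsm"].diagnostic
        assert math.isfinite(out["chl"].value)
        assert math.isfinite(out["cdom400"].value)

    def test_unclassified_gives_all_missing_with_reason(self, registry):
        row = pd.Series({"TOA_R705": 0.02, "TOA_R665": 0.01})
        out = retrieve(row, UNCLASSIFIED, "MSI", registry)
        for p in PRODUCTS:
            assert math.isnan(out[p].value)
            assert "unclassified" in out[p].diagnostic.lower()


class TestRetrieveScene:
    def test_uniform_scene_constant_products(self, registry, msi_lib):
        spec = SceneSpec(np.full((3, 3), "Brown", dtype=object), jitter=0.0, seed=1)
        stack, truth = generate_scene(spec, "MSI")
        grids = retrieve_scene(stack, truth, "MSI", registry)
        chl = grids["chl"]
        assert np.all(np.isfinite(chl))
        assert np.allclose(chl, chl[0, 0])

    def test_two_owt_halves_switch_formula(self, registry, msi_lib):
        labels = np.full((2, 4), "Turbid", dtype=object)
        labels[:, 2:] = "Brown"
        spec = SceneSpec(labels, jitter=0.0, seed=2)
        stack, truth = generate_scene(spec, "MSI")
        grids = retrieve_scene(stack, truth, "MSI", registry)
        # same band stack, different formulas across the boundary
        assert not np.isclose(grids["chl"][0, 0], grids["chl"][0, 3])

    def test_equivalent_to_pixelwise_retrieve(self, registry, rng):
        from lakeowt.spectra import band_set_for
        bs = band_set_for("MSI")
        data = rng.uniform(0.005, 0.08, (len(bs.names), 3, 3))
        stack = SceneStack("MSI", "TOA", bs.names, data)
        labels = np.array(rng.choice(OWT_CLASSES, size=(3, 3)), dtype=object)
        grids = retrieve_scene(stack, labels, "MSI", registry)
        for iy in range(3):
            for ix in range(3):
                row = pd.Series(data[:, iy, ix],
                                index=[column_name("TOA", b) for b in bs.names])
                ref = retrieve(row, labels[iy, ix], "MSI", registry)
                for p in PRODUCTS:
                    got, want = grids[p][iy, ix], ref[p].value
                    assert (math.isnan(got) and math.isnan(want)) or \
                        got == pytest.approx(want)

    def test_all_unclassified_scene_all_missing(self, registry, rng):
        from lakeowt.spectra import band_set_for
        bs = band_set_for("MSI")
        data = rng.uniform(0.005, 0.08, (len(bs.names), 2, 2))
        stack = SceneStack("MSI", "TOA", bs.names, data)
        labels = np.full((2, 2), UNCLASSIFIED, dtype=object)
        grids = retrieve_scene(stack, labels, "MSI", registry)
        for p in PRODUCTS:
            assert np.all(np.isnan(grids[p]))

    def test_shape_mismatch_rejected(self, registry, rng):
        from lakeowt.spectra import band_set_for
        bs = band_set_for("MSI")
        stack = SceneStack("MSI", "TOA", bs.names,
                           rng.uniform(0.01, 0.05, (len(bs.names), 2, 2)))
        with pytest.raises(ValueError, match="match"):
            retrieve_scene(stack, np.full((3, 3), "Clear", dtype=object),
                           "MSI", registry)
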