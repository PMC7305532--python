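import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from orthoforce import (CorrectionCoefficients, CorrectionFactorModel,
                        DeviationRecord, EFFECTIVE_MATERIALS,
                        OFFSET_WIRE_SUBSTITUTION, SimulationConfig,
                        builtin_table1, compose_KF, correction_rates,
                        eval_printed_K, fit_correction_functions, generate,
                        parse_code, printed_coefficients, theoretical_force)
from orthoforce.calibration import ExtrapolationWarning, FitError
from orthoforce.dataset import MeasurementTable

REF = parse_code("S16162010")


def identity_coefficients():
    """All percent terms zero: every K is exactly 1."""
    return CorrectionCoefficients(
        variant="printed", kfl=(0.0, 0.0), kfa=(0.0, 0.0, 0.0),
        kfs=(0.0, 0.0), kfm=(0.0, 0.0), base=(1.0, 1.0, 1.0),
        reference={"code": "S16162010", "l_mm": 20.0, "a_mm": 10.0,
                   "second_moment": REF.second_moment,
                   "elastic_modulus": REF.elastic_modulus})


class TestDeviationRecords:
    def test_equal_forces_zero_rates(self):
        r = DeviationRecord("S16162010", 1.0, 0.5, 0.5)
        assert r.deviation_rate == 0.0
        assert r.correction_rate == 0.0

    def test_halved_experimental(self):
        r = DeviationRecord("S16162010", 1.0, 0.64, 0.32)
        assert r.deviation_rate == pytest.approx(-100.0)
        assert r.correction_rate == pytest.approx(-50.0)

    @given(st.floats(0.01, 20.0), st.floats(0.01, 20.0))
    def test_rate_identity(self, f_theo, f_exp):
        r = DeviationRecord("X", 1.0, f_theo, f_exp)
        assert (1 + r.correction_rate / 100) * (1 - r.deviation_rate / 100) \
            == pytest.approx(1.0, rel=1e-12)

    def test_zero_force_cells_excluded(self):
        idx = pd.Index([0.5, 1.0], name="displacement_mm")
        table = MeasurementTable(pd.DataFrame({"S16162010": [0.0, 0.66]}, index=idx))
        records = correction_rates(table, lambda c, d: theoretical_force(REF, d))
        assert [r.displacement_mm for r in records] == [1.0]


class TestPrintedCoefficients:
    def test_anchorage_root(self):
        # -2.2245 l + 62.561 = 0 at l = 28.124 mm
        assert eval_printed_K("l", 62.561 / 2.2245) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_directions(self):
        assert eval_printed_K("l", 20) > eval_printed_K("l", 26)
        assert eval_printed_K("S", 1.34e-15) > eval_printed_K("S", 5.06e-15)
        assert eval_printed_K("M", 7.0e10) > eval_printed_K("M", 8.0e10)

    def test_offset_quadratic_minimum_near_9mm(self):
        a_grid = np.linspace(7, 10, 301)
        vals = [eval_printed_K("a", a) for a in a_grid]
        assert a_grid[int(np.argmin(vals))] == pytest.approx(9.0, abs=0.05)

    def test_unknown_parameter(self):
        with pytest.raises(ValueError):
            eval_printed_K("x", 1.0)

    def test_nonpositive_second_moment_rejected(self):
        with pytest.raises(ValueError):
            printed_coefficients().k_section(0.0)


class TestComposeKF:
    def test_base_cancellation_at_reference(self, printed):
        assert compose_KF(REF, printed) == pytest.approx(
            printed.k_anchorage(20.0), rel=1e-12)
        assert compose_KF(REF, printed) == pytest.approx(1.18071, abs=1e-5)

    def test_material_only_change(self, printed):
        aus = parse_code("A16162010")
        expected = (printed.k_anchorage(20.0)
                    * printed.k_material(1.57e11) / printed.k_material(1.79e11))
        assert compose_KF(aus, printed) == pytest.approx(expected, rel=1e-12)

    def test_extrapolation_warns_but_returns(self, printed):
        wide = parse_code("S16163010")  # l = 30 mm, outside [20, 26]
        with pytest.warns(ExtrapolationWarning):
            kf = compose_KF(wide, printed)
        assert np.isfinite(kf)

    def test_no_warning_inside_ranges(self, printed):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", ExtrapolationWarning)
            compose_KF(parse_code("S16162210"), printed)


class TestFitOnReferenceTable:
    def test_group_classification(self, reference_model):
        g = reference_model.groups
        assert g["anchorage"] == ["S16162010", "S16162210", "S16162410", "S16162610"]
        assert g["offset"] == ["S16162010", "S16162009", "S16162008", "S20102007"]
        assert g["section"] == ["S16162010", "S18252010", "S00162010"]
        assert g["material"] == ["S16162010", "A16162010"]

    def test_anchorage_correction_decreases_with_span(self, fitted_results):
        c = fitted_results.coefficients
        assert c.kfl[0] < 0
        # brute-force sign check: measured/theoretical ratio falls with l
        rates = fitted_results.archwire_rates
        assert rates["S16162010"] > rates["S16162610"]

    def test_material_group_is_exactly_determined(self, fitted_results):
        diag = fitted_results.coefficients.diagnostics["material"]
        assert diag["dof"] == 0
        assert max(abs(r) for r in diag["residuals"]) < 1e-9

    def test_refit_slope_matches_published_anchorage_function(self, fitted_results):
        # under the effective moduli the refit reproduces the published slope
        p1, p0 = fitted_results.coefficients.kfl
        assert p1 == pytest.approx(-2.2245, abs=0.01)
        assert p0 == pytest.approx(62.561, abs=1.0)

    def test_refit_offset_function_matches_published(self, fitted_results):
        q2, q1, q0 = fitted_results.coefficients.kfa
        assert q2 == pytest.approx(8.555, rel=0.01)
        assert q1 == pytest.approx(-153.941, rel=0.01)
        assert q0 == pytest.approx(703.031, rel=0.01)

    def test_fit_error_names_missing_group(self, table1):
        frame = table1.frame.drop(columns=["A16162010"])
        with pytest.raises(FitError, match="material"):
            CorrectionFactorModel(MeasurementTable(frame),
                                  material_library=EFFECTIVE_MATERIALS,
                                  substitutions=OFFSET_WIRE_SUBSTITUTION).fit()

    def test_literal_offset_wire_warns_about_contamination(self, table1):
        with pytest.warns(UserWarning, match="contaminates"):
            CorrectionFactorModel(table1, material_library=EFFECTIVE_MATERIALS)

    def test_functional_wrapper_equals_model_fit(self, table1, fitted_results):
        coeffs = fit_correction_functions(
            table1, "printed", material_library=EFFECTIVE_MATERIALS,
            substitutions=OFFSET_WIRE_SUBSTITUTION)
        assert coeffs.kfl == fitted_results.coefficients.kfl
        assert coeffs.kfa == fitted_results.coefficients.kfa

    def test_summary_mentions_all_functions(self, measured_results):
        text = measured_results.summary()
        for token in ("K_Fl", "K_Fa", "K_FS", "K_FM", "base values", "printed"):
            assert token in text


class TestBaseModes:
    def test_fitted_base_cancels_at_reference(self, fitted_results):
        c = fitted_results.coefficients
        assert compose_KF(REF_EFF, c) == pytest.approx(c.k_anchorage(20.0), rel=1e-12)

    def test_measured_base_uses_reference_rate(self, measured_results):
        c = measured_results.coefficients
        k0 = 1 + measured_results.archwire_rates["S16162010"] / 100
        assert c.base == pytest.approx((k0, k0, k0))

    def test_base_modes_share_coefficients(self, fitted_results, measured_results):
        assert fitted_results.coefficients.kfl == measured_results.coefficients.kfl
        assert fitted_results.coefficients.kfs == measured_results.coefficients.kfs


REF_EFF = parse_code("S16162010", EFFECTIVE_MATERIALS)


class TestNoiselessRecovery:
    def test_exact_recovery_from_model_class(self):
        cfg = SimulationConfig(sigma=0.0, seed=3)
        table = generate(cfg)
        fitted = CorrectionFactorModel(
            table, variant="printed",
            material_library=cfg.material_library).fit().coefficients
        truth = cfg.coefficients.normalized()
        est = fitted.normalized()
        for group in ("kfl", "kfa", "kfs", "kfm"):
            for t, e in zip(getattr(truth, group), getattr(est, group)):
                assert e == pytest.approx(t, rel=1e-6)


class TestSerialization:
    def test_json_round_trip(self, measured_results, tmp_path):
        c = measured_results.coefficients
        path = tmp_path / "coeffs.json"
        c.save(path)
        loaded = CorrectionCoefficients.load(path)
        assert loaded.kfl == pytest.approx(c.kfl)
        assert loaded.base == pytest.approx(c.base)
        assert loaded.variant == c.variant
        assert loaded.base_mode == c.base_mode
        assert loaded.fit_ranges["a_mm"] == c.fit_ranges["a_mm"]
        # the payload is valid JSON with the four coefficient sets
        payload = json.loads(path.read_text())
        assert set(payload) >= {"kfl", "kfa", "kfs", "kfm", "base", "variant"}

    def test_normalization_preserves_composition(self, fitted_results):
        c = fitted_results.coefficients
        n = c.normalized()
        for code in ("S16162010", "S16162410", "S16162008", "S00162010", "A16162010"):
            spec = parse_code(code, EFFECTIVE_MATERIALS,
                              substitutions=OFFSET_WIRE_SUBSTITUTION)
            assert compose_KF(spec, n) == pytest.approx(compose_KF(spec, c), rel=1e-12)
        assert n.base[0] == pytest.approx(n.k_offset(10.0), rel=1e-12)

    def test_invalid_enum_fields_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(identity_coefficients(), base_mode="other")
        with pytest.raises(ValueError):
            dataclasses.replace(identity_coefficients(), convention="other")
        with pytest.raises(ValueError):
            dataclasses.replace(identity_coefficients(), variant="other")
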