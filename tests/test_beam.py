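import numpy as np
import pytest
from hypothesis import given, strategies as st

from orthoforce import (LoadCase, bending_moment, deflection_profile,
                        load_for_displacement, parse_code, theoretical_force)
from _helpers import integrate_deflection, oracle_force, random_spec

REF = parse_code("S16162010")


class TestBendingMoment:
    def test_vanishes_at_both_supports(self):
        assert bending_moment(0.0, 1.0, REF.geometry) == pytest.approx(0.0)
        assert bending_moment(0.02, 1.0, REF.geometry) == pytest.approx(0.0, abs=1e-15)

    def test_value_at_load_point(self):
        # (P b / l) x = (1 * 0.01 / 0.02) * 0.01
        assert bending_moment(0.01, 1.0, REF.geometry) == pytest.approx(0.005)

    @given(st.floats(0.001, 0.039))
    def test_branches_agree_at_load_point(self, a):
        geom = parse_code("S16162010").geometry
        geom = type(geom)(0.04, a)
        left = geom.offset_distance * (1 - 1e-12)
        right = geom.offset_distance * (1 + 1e-12)
        assert bending_moment(left, 2.0, geom) == pytest.approx(
            bending_moment(right, 2.0, geom), rel=1e-9)

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            bending_moment(-1e-6, 1.0, REF.geometry)
        with pytest.raises(ValueError):
            bending_moment(0.021, 1.0, REF.geometry)


class TestDeflectionProfile:
    def test_boundary_conditions(self):
        prof = deflection_profile(LoadCase(REF, 1.0))
        assert prof.deflection[0] == pytest.approx(0.0, abs=1e-18)
        assert prof.deflection[-1] == pytest.approx(0.0, abs=1e-12)

    def test_load_point_deflection_closed_form(self):
        # |v(a)| = P a^2 b^2 / (3 E I l) for the reference wire, P = 1 N
        prof = deflection_profile(LoadCase(REF, 1.0))
        idx = int(np.argmin(np.abs(prof.positions - REF.offset_distance)))
        assert abs(prof.deflection[idx]) == pytest.approx(4.096e-4, rel=1e-3)
        assert LoadCase(REF, 1.0).displacement == pytest.approx(4.096e-4, rel=1e-3)

    def test_branch_continuity_at_load_point(self):
        # both closed-form branches, written out independently, agree at x=a
        rng = np.random.default_rng(7)
        for _ in range(10):
            spec = random_spec(rng)
            P = float(rng.uniform(0.1, 5.0))
            E, I = spec.elastic_modulus, spec.second_moment
            l, a, b = (spec.anchorage_distance, spec.offset_distance,
                       spec.mesial_distance)
            left = -(P * b * a) / (6 * E * I * l) * (l**2 - a**2 - b**2)
            right = -(P * b) / (6 * E * I * l) * (
                (l / b) * (a - a)**3 + (l**2 - b**2) * a - a**3)
            assert left == pytest.approx(right, rel=1e-12)
            prof = deflection_profile(LoadCase(spec, P))
            idx = int(np.argmin(np.abs(prof.positions - a)))
            assert prof.deflection[idx] == pytest.approx(left, rel=1e-9)

    def test_matches_integration_oracle(self):
        case = LoadCase(REF, 1.5)
        prof = deflection_profile(case, num=2001)
        x_o, v_o = integrate_deflection(REF, 1.5)
        v_interp = np.interp(prof.positions, x_o, v_o)
        scale = np.max(np.abs(v_o))
        assert np.max(np.abs(prof.deflection - v_interp)) < 0.005 * scale

    def test_csv_export(self, tmp_path):
        prof = deflection_profile(LoadCase(REF, 1.0), num=11)
        out = tmp_path / "profile.csv"
        prof.to_csv(out)
        data = np.loadtxt(out, delimiter=",", skiprows=1)
        assert data.shape[1] == 2
        assert data[0, 0] == pytest.approx(0.0)
        assert data[-1, 0] == pytest.approx(20.0)


class TestTheoreticalForce:
    def test_printed_reference_value(self):
        assert theoretical_force(REF, 1.0, "printed") == pytest.approx(1.2208, rel=2e-4)

    def test_rederived_is_twice_printed_for_central_load(self):
        printed = theoretical_force(REF, 1.0, "printed")
        rederived = theoretical_force(REF, 1.0, "rederived")
        assert rederived == pytest.approx(2.4415, rel=2e-4)
        assert rederived == pytest.approx(2 * printed, rel=1e-12)

    def test_zero_displacement_zero_force(self):
        for variant in ("printed", "rederived"):
            assert theoretical_force(REF, 0.0, variant) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            theoretical_force(REF, -0.1)
        with pytest.raises(ValueError):
            theoretical_force(REF, 1.0, "bogus")

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    def test_superposition(self, d1, d2):
        f = lambda d: theoretical_force(REF, d, "rederived")
        assert f(d1) + f(d2) == pytest.approx(f(d1 + d2), rel=1e-9)

    def test_monotone_in_span_at_fixed_ratio(self):
        forces = []
        for l_mm in (16, 20, 24, 28, 32):
            spec = parse_code(f"S1616{l_mm:02d}{l_mm // 2:02d}")
            forces.append(theoretical_force(spec, 1.0))
        assert all(a > b for a, b in zip(forces, forces[1:]))

    def test_monotone_in_stiffness(self):
        base = theoretical_force(REF, 1.0)
        stiffer_e = parse_code("S16162010",
                               {"S": type(REF.material)("x", 2.0e11)})
        bigger_i = parse_code("S18182010")
        assert theoretical_force(stiffer_e, 1.0) > base
        assert theoretical_force(bigger_i, 1.0) > base

    def test_load_for_displacement_round_trip(self):
        case = load_for_displacement(REF, 2.5)
        assert case.displacement == pytest.approx(2.5e-3, rel=1e-12)
        assert case.load == pytest.approx(theoretical_force(REF, 2.5, "rederived"))

    def test_force_recovered_from_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            spec = random_spec(rng)
            d_mm = float(rng.uniform(0.2, 5.0))
            assert theoretical_force(spec, d_mm, "rederived") == pytest.approx(
                oracle_force(spec, d_mm), rel=0.005)
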