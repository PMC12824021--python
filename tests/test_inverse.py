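"""Triple-loop inverse estimation: geometry, inner loop, cohort runs."""

import math

import numpy as np
import pytest

from aortivo.constitutive import MaterialParams
from aortivo.inverse import (
    IterationConfig,
    SubjectRecord,
    inner_loop,
    run_setting,
    triple_loop,
    zero_pressure_geometry,
)
from aortivo.synth import CohortSpec, generate_subject
from aortivo import fixtures


@pytest.fixture(scope="module")
def virtual():
    """One feasible virtual subject with known ground truth."""
    rec, params, s_true = generate_subject(CohortSpec(n_subjects=1, seed=11), 0)
    return rec, params, s_true


class TestZeroPressureGeometry:
    def test_unit_shrinkage_radius(self):
        sub = SubjectRecord(
            id="X", pressure_sys=120, pressure_dia=80, perimeter_min=12.0,
            perimeter_max=12.62, thickness=2.0, reference_perimeter=12.62,
        )
        geom = zero_pressure_geometry(sub, 1.0)
        assert geom.inner_radius_0 == pytest.approx(126.2 / (2 * math.pi), abs=5e-3)

    def test_radius_linear_in_shrinkage(self):
        sub = SubjectRecord(
            id="X", pressure_sys=120, pressure_dia=80, perimeter_min=11.0,
            perimeter_max=12.0, thickness=2.0,
        )
        g1 = zero_pressure_geometry(sub, 1.0)
        g2 = zero_pressure_geometry(sub, 0.5)
        assert g2.inner_radius_0 == pytest.approx(0.5 * g1.inner_radius_0)

    def test_wall_area_conserved_under_axial_shrink(self):
        """Zero-pressure wall area = in vivo area * lambda_z, so the wall
        thickens when the tube is shrunk back."""
        sub = SubjectRecord(
            id="X", pressure_sys=120, pressure_dia=80, perimeter_min=11.0,
            perimeter_max=12.0, thickness=2.0, axial_stretch=1.25,
        )
        r_iv = 120.0 / (2 * math.pi)
        area_iv = math.pi * ((r_iv + 2.0) ** 2 - r_iv**2)
        geom = zero_pressure_geometry(sub, 0.8)
        area_0 = math.pi * (
            (geom.inner_radius_0 + geom.thickness_0) ** 2 - geom.inner_radius_0**2
        )
        assert area_0 == pytest.approx(area_iv * 1.25, rel=1e-12)
        assert geom.thickness_0 > sub.thickness

    def test_shrinkage_out_of_range(self):
        sub = SubjectRecord(
            id="X", pressure_sys=120, pressure_dia=80, perimeter_min=11.0,
            perimeter_max=12.0, thickness=2.0,
        )
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                zero_pressure_geometry(sub, bad)


class TestInnerLoop:
    def test_round_trip_recovery(self, virtual):
        """Initialized at the generating parameters the inner loop returns
        k = 1 and the true shrinkage."""
        rec, params, s_true = virtual
        res = inner_loop(rec, params)
        assert res.feasible
        assert res.k == pytest.approx(1.0, abs=0.01)
        assert res.S == pytest.approx(s_true, rel=0.005)

    def test_scale_equivariance_of_solution_set(self, virtual):
        """Pre-scaling the stress-like triple by 2 halves k root-for-root
        and leaves the products c1 k, D1 k, K1 k unchanged.  The solution
        set can contain two (S, k) pairs; roots are matched by S."""
        rec, params, _ = virtual
        r1 = inner_loop(rec, params)
        r2 = inner_loop(rec, params.scaled(2.0))
        assert r1.feasible and r2.feasible
        assert len(r1.roots) == len(r2.roots)
        for (s1, k1), (s2, k2) in zip(r1.roots, r2.roots):
            assert s2 == pytest.approx(s1, rel=1e-9)
            assert k2 == pytest.approx(k1 / 2.0, rel=1e-6)
            assert 2.0 * k2 * params.c1 == pytest.approx(k1 * params.c1, rel=1e-6)

    def test_degenerate_subject_infeasible(self, ad1_params):
        """No cyclic distension but a pressure difference: k -> infinity."""
        sub = SubjectRecord(
            id="X", pressure_sys=120, pressure_dia=80, perimeter_min=10.0,
            perimeter_max=10.0, thickness=2.0,
        )
        res = inner_loop(sub, ad1_params)
        assert not res.feasible

    def test_perimeters_reproduced_at_solution(self, virtual):
        from aortivo.inverse import _perimeter_at
        from aortivo.tube import mmhg_to_kpa

        rec, params, _ = virtual
        res = inner_loop(rec, params)
        trial = params.scaled(res.k)
        per_dia = _perimeter_at(rec, trial, res.S, mmhg_to_kpa(rec.pressure_dia))
        per_sys = _perimeter_at(rec, trial, res.S, mmhg_to_kpa(rec.pressure_sys))
        assert per_dia == pytest.approx(rec.perimeter_min, rel=1e-5)
        assert per_sys == pytest.approx(rec.perimeter_max, rel=1e-5)


class TestTripleLoop:
    def test_feasible_guess_skips_corrections(self, virtual):
        rec, params, _ = virtual
        res = triple_loop(rec, params)
        assert res.middle_iterations == 0
        assert res.outer_iterations == 0
        assert res.inner_iterations >= 1

    def test_constraints_always_satisfied(self):
        """Every reported solution has 0 < S <= 1 and k > 0."""
        spec = CohortSpec(n_subjects=6, seed=3)
        for i in range(spec.n_subjects):
            rec, params, _ = generate_subject(spec, i)
            res = triple_loop(rec, params)
            assert 0.0 < res.S <= 1.0
            assert res.k > 0.0

    def test_misfit_initial_angle_still_terminates(self, virtual):
        """Initial guess with the fiber angle off by 10 degrees: the loops
        converge to a feasible solution with matched perimeters."""
        rec, params, _ = virtual
        shifted = MaterialParams(
            c1=params.c1, D1=params.D1, D2=params.D2, K1=params.K1, K2=params.K2,
            theta=min(params.theta + 10.0, 44.0),
        )
        res = triple_loop(rec, shifted)
        assert res.feasible
        assert 0.0 < res.S <= 1.0 and res.k > 0.0

    def test_fixed_point_property(self, virtual):
        """Re-running with the recovered parameters returns k = 1 and the
        same shrinkage."""
        rec, params, _ = virtual
        first = triple_loop(rec, params)
        second = triple_loop(rec, first.final_params)
        assert second.k == pytest.approx(1.0, abs=1e-5)
        assert second.S == pytest.approx(first.S, rel=1e-6)

    def test_final_D2_unchanged(self, virtual):
        rec, params, _ = virtual
        res = triple_loop(rec, params)
        assert res.final_params.D2 == params.D2


class TestRunSetting:
    def test_m02_initial_guess_is_ad1(self, exvivo_params):
        assert fixtures.load_initial_guess("M02") == exvivo_params["AD1"]

    def test_m03_initial_guess_matches_published_perturbation(self):
        p = fixtures.load_initial_guess("M03")
        assert p.c1 == pytest.approx(2.6373)
        assert p.D1 == pytest.approx(15.2031)
        assert p.D2 == pytest.approx(0.9696)
        assert p.K1 == pytest.approx(2.2732)
        assert p.K2 == pytest.approx(0.9018)
        assert p.theta == pytest.approx(5.82)

    def test_empty_cohort(self):
        df = run_setting([], "M02")
        assert len(df) == 0

    def test_m01_requires_exvivo_table(self, cohort):
        with pytest.raises(ValueError, match="ex vivo"):
            run_setting(cohort, "M01", ex_vivo_params=None)

    def test_synthetic_cohort_truth_initial(self):
        """Initialized at the truth, every feasible subject has k ~ 1."""
        spec = CohortSpec(n_subjects=4, seed=21)
        subs, truths = [], {}
        for i in range(4):
            rec, params, _ = generate_subject(spec, i)
            subs.append(rec)
            truths[rec.id] = params
        df = run_setting(subs, "M01", ex_vivo_params=truths)
        ok = df[df["feasible"]]
        assert len(ok) == 4
        np.testing.assert_allclose(ok["k"], 1.0, atol=0.01)
        # homogeneity link: in vivo / ex vivo modulus ratio equals k
        np.testing.assert_allclose(
            ok["YMc_kPa"] / ok["YMc_exvivo_kPa"], ok["k"], rtol=1e-8
        )

    def test_clinical_cohort_m02_runs(self, cohort, exvivo_params):
        """The packaged clinical cohort under the common initial guess:
        rows for all ten subjects, constraints satisfied where feasible."""
        df = run_setting(cohort, "M02", ex_vivo_params=exvivo_params)
        assert len(df) == 10
        ok = df[df["feasible"]]
        assert len(ok) >= 8
        assert ((ok["S_pct"] > 0) & (ok["S_pct"] <= 100)).all()
        assert (ok["k"] > 0).all()


class TestSubjectRecord:
    def test_pressure_ordering_enforced(self):
        with pytest.raises(ValueError):
            SubjectRecord(
                id="X", pressure_sys=80, pressure_dia=90, perimeter_min=10.0,
                perimeter_max=11.0, thickness=2.0,
            )

    def test_dict_round_trip(self):
        sub = SubjectRecord(
            id="X", pressure_sys=120, pressure_dia=80, perimeter_min=10.0,
            perimeter_max=11.0, thickness=2.0,
        )
        assert SubjectRecord.from_dict(sub.to_dict()) == sub
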