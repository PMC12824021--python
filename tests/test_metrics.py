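"""Stiffness summaries and exact nonparametric statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortivo.metrics import (
    anisotropy_index,
    effect_size_r,
    effective_young_modulus,
    median_iqr,
    perimeter_change,
    relative_error,
    wilcoxon_exact,
)


class TestEffectiveYoungModulus:
    def test_linear_input_recovers_slope(self, isotropic_params, monkeypatch):
        import aortivo.metrics as metrics

        def fake_curve(params, direction, protocol, grid):
            g = np.linspace(1.0, 1.3, 31) if grid is None else grid
            return np.column_stack([g, 100.0 * (g - 1.0)])

        monkeypatch.setattr(metrics, "stress_stretch_curve", fake_curve)
        assert metrics.effective_young_modulus(isotropic_params) == pytest.approx(100.0)

    def test_homogeneity(self, ad1_params):
        e1 = effective_young_modulus(ad1_params, "c")
        e2 = effective_young_modulus(ad1_params.scaled(2.5), "c")
        assert e2 == pytest.approx(2.5 * e1, rel=1e-10)

    def test_least_squares_oracle_on_dense_grid(self, ad1_params):
        """The closed-form anchored slope equals an independent lstsq solve
        of the through-origin regression on a 10^4-point grid."""
        from aortivo.constitutive import stress_stretch_curve

        grid = np.linspace(1.0, 1.3, 10000)
        got = effective_young_modulus(ad1_params, "c", "equibiaxial", grid)
        curve = stress_stretch_curve(ad1_params, "c", "equibiaxial", grid)
        design = (curve[:, 0] - 1.0).reshape(-1, 1)
        slope, *_ = np.linalg.lstsq(design, curve[:, 1], rcond=None)
        assert got == pytest.approx(float(slope[0]), rel=1e-3)

    def test_grid_refinement_is_stable(self, ad1_params):
        """Refining the default grid changes the modulus only mildly (the
        estimator is a grid-weighted fit of a nonlinear curve)."""
        coarse = effective_young_modulus(ad1_params, "c", "equibiaxial")
        dense = effective_young_modulus(
            ad1_params, "c", "equibiaxial", np.linspace(1.0, 1.3, 3001)
        )
        assert coarse == pytest.approx(dense, rel=0.02)

    def test_circumferential_stiffer_for_small_angle(self, ad1_params):
        """Fibers nearly circumferential (5.56 deg): YMc > YMa."""
        ymc = effective_young_modulus(ad1_params, "c")
        yma = effective_young_modulus(ad1_params, "a")
        assert ymc > yma


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "ymc,yma,expected",
        [(181.46, 142.92, 0.24), (3413.61, 142.87, 1.84), (100.0, 100.0, 0.0)],
    )
    def test_anisotropy_index_worked_values(self, ymc, yma, expected):
        assert round(anisotropy_index(ymc, yma), 2) == pytest.approx(expected)

    def test_anisotropy_antisymmetry(self):
        assert anisotropy_index(3.0, 1.0) == pytest.approx(-anisotropy_index(1.0, 3.0))

    @given(a=st.floats(0.1, 1e4), b=st.floats(0.1, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_anisotropy_bounded(self, a, b):
        ai = anisotropy_index(a, b)
        assert -2.0 < ai < 2.0
        if a == b:
            assert ai == 0.0

    @pytest.mark.parametrize(
        "est,ref,expected", [(126.38, 181.46, -30.35), (5.0, 5.0, 0.0), (8.0, 4.0, 100.0)]
    )
    def test_relative_error(self, est, ref, expected):
        assert relative_error(est, ref) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "mn,mx,expected", [(10.58, 12.96, 22.5), (8.50, 9.69, 14.00), (7.0, 7.0, 0.0)]
    )
    def test_perimeter_change(self, mn, mx, expected):
        assert perimeter_change(mn, mx) == pytest.approx(expected, abs=5e-2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            anisotropy_index(-1.0, 1.0)
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)
        with pytest.raises(ValueError):
            perimeter_change(0.0, 1.0)


class TestMedianIqr:
    def test_published_re_column(self, stiffness_table):
        """The circumferential relative-error column reproduces the printed
        median and quartiles."""
        med, q1, q3 = median_iqr(stiffness_table["RE_YMc_pct"])
        assert round(med, 2) == pytest.approx(-14.50)
        assert round(q1, 2) == pytest.approx(-19.66)
        assert round(q3, 2) == pytest.approx(-6.67)

    def test_single_value(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_sort_and_interpolate_oracle(self, values):
        """Quantiles equal explicit interpolation at positions 1 + (n-1) q."""
        med, q1, q3 = median_iqr(values)
        s = sorted(values)
        n = len(s)

        def interp(q):
            pos = (n - 1) * q
            lo = int(np.floor(pos))
            hi = min(lo + 1, n - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert med == pytest.approx(interp(0.5), abs=1e-9)
        assert q1 == pytest.approx(interp(0.25), abs=1e-9)
        assert q3 == pytest.approx(interp(0.75), abs=1e-9)


def _brute_force_wilcoxon(d, alternative):
    """Full 2^n enumeration oracle with average ranks."""
    d = np.asarray([x for x in d if x != 0.0])
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    W = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if alternative == "less" and w <= W + 1e-9:
            count += 1
        elif alternative == "greater" and w >= W - 1e-9:
            count += 1
    return W, count / 2**n


class TestWilcoxonExact:
    def test_circumferential_moduli_comparison(self, stiffness_table):
        """In vivo YMc uniformly below ex vivo: W = 0, p = 1/1024, r ~ 0.98."""
        t = wilcoxon_exact(
            stiffness_table["YMc_invivo"], stiffness_table["YMc_exvivo"], "less"
        )
        assert t.W == 0.0
        assert t.p == pytest.approx(1.0 / 1024.0)
        assert round(t.r, 2) == pytest.approx(0.98)

    def test_axial_moduli_comparison(self, stiffness_table):
        """Two positive differences (AD3, AD4): W = 8, p = 25/1024, r ~ 0.62."""
        t = wilcoxon_exact(
            stiffness_table["YMa_invivo"], stiffness_table["YMa_exvivo"], "less"
        )
        assert t.W == 8.0
        assert t.p == pytest.approx(25.0 / 1024.0)
        assert round(t.r, 2) == pytest.approx(0.62)

    def test_all_positive_small_sample(self):
        t = wilcoxon_exact([4.0, 5.0, 6.0], [1.0, 2.0, 3.0], "less")
        assert t.W == 6.0
        assert t.p == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        t = wilcoxon_exact([1.0, 2.0, 5.0], [1.0, 2.0, 3.0], "greater")
        assert t.n == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_exact([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("alternative", ["less", "greater"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_enumeration_oracle(self, seed, alternative):
        """Exact p equals full 2^n sign enumeration, ties included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding forces ties
        d = d[d != 0.0]
        if d.size == 0:
            d = np.array([0.5])
        t = wilcoxon_exact(d, np.zeros_like(d), alternative)
        W, p = _brute_force_wilcoxon(d, alternative)
        assert t.W == pytest.approx(W)
        assert t.p == pytest.approx(p, abs=1e-12)


class TestEffectSize:
    @pytest.mark.parametrize(
        "p,n,expected", [(25 / 1024, 10, 0.62), (1 / 1024, 10, 0.98), (2 / 1024, 10, 0.913)]
    )
    def test_published_values(self, p, n, expected):
        assert effect_size_r(p, n) == pytest.approx(expected, abs=5e-3)

    def test_p_half_is_zero(self):
        for n in (1, 10, 25):
            assert effect_size_r(0.5, n) == pytest.approx(0.0, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            effect_size_r(0.0, 10)
        with pytest.raises(ValueError):
            effect_size_r(1.0, 10)
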