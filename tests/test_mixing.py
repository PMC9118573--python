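"""Excess area and excess Gibbs free energy of binary films."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monofilm import (
    Isotherm,
    excess_area,
    excess_gibbs,
    excess_profile,
    resample_by_pressure,
)
from monofilm.errors import AlignmentError, RangeError
from monofilm.mixing import AVOGADRO, GIBBS_UNIT, AreaOfPressure
from monofilm.synthetic import (
    ExcessFn,
    MixtureSpec,
    generate_isotherm,
    generate_mixture,
    isotherm_preset,
    true_excess_gibbs,
)


def _linear_branch(intercept=70.0, slope=2.0, n=100):
    area = np.linspace(intercept - 0.05, intercept - 25.0, n)
    return Isotherm(area=area, pressure=slope * (intercept - area))


def _mixture(excess_fn=None, x1=0.5, pi_max=25.0, step=0.1):
    spec = MixtureSpec(
        end1=isotherm_preset("pc183_20C"),
        end2=isotherm_preset("pc183_hcs_20C"),
        x1=x1,
        excess_fn=excess_fn or ExcessFn(),
        pi_max=pi_max,
        step=step,
    )
    mix, (e1, e2), truth = generate_mixture(spec)
    return (
        resample_by_pressure(mix, pi_max, step),
        resample_by_pressure(e1, pi_max, step),
        resample_by_pressure(e2, pi_max, step),
        truth,
    )


class TestResample:
    def test_linear_branch_inverts_exactly(self):
        curve = resample_by_pressure(_linear_branch(), pi_max=20.0)
        i = int(np.argmin(np.abs(curve.grid - 10.0)))
        assert curve.grid[i] == pytest.approx(10.0)
        assert curve.areas[i] == pytest.approx(65.0, abs=1e-9)

    def test_beyond_collapse_is_range_error(self):
        iso, _ = generate_isotherm(isotherm_preset("pc183_20C"))
        with pytest.raises(RangeError, match="achievable"):
            resample_by_pressure(iso, pi_max=60.0)

    def test_large_zero_gap_refused(self):
        area = np.linspace(68.0, 50.0, 50)
        iso = Isotherm(area=area, pressure=4.0 + 2.0 * (68.0 - area))
        with pytest.raises(RangeError, match="extend"):
            resample_by_pressure(iso, pi_max=20.0)

    def test_grid_refinement_converges(self):
        coarse = _mixture(ExcessFn("half_sine", 2.5), step=0.1)
        fine = _mixture(ExcessFn("half_sine", 2.5), step=0.01)
        dg_coarse = excess_gibbs(*coarse[:3], x1=0.5, pi2=25.0)
        dg_fine = excess_gibbs(*fine[:3], x1=0.5, pi2=25.0)
        assert dg_coarse == pytest.approx(dg_fine, rel=1e-3)


class TestExcessArea:
    def test_hand_arithmetic(self):
        grid = np.linspace(0.0, 25.0, 251)
        mix = AreaOfPressure(grid, np.full(251, 70.0))
        e1 = AreaOfPressure(grid, np.full(251, 72.0))
        e2 = AreaOfPressure(grid, np.full(251, 66.0))
        assert excess_area(mix, e1, e2, x1=0.5, at_pi=10.0) == pytest.approx(1.0)

    def test_endmember_identity(self):
        grid = np.linspace(0.0, 20.0, 201)
        a1 = AreaOfPressure(grid, 80.0 - 1.5 * grid)
        a2 = AreaOfPressure(grid, 60.0 - 1.0 * grid)
        for pi in (0.0, 5.0, 20.0):
            assert excess_area(a1, a1, a2, x1=1.0, at_pi=pi) == pytest.approx(0.0)

    def test_ideal_weighted_sum_is_zero_everywhere(self):
        grid = np.linspace(0.0, 20.0, 201)
        a1 = AreaOfPressure(grid, 80.0 - 1.5 * grid)
        a2 = AreaOfPressure(grid, 60.0 - 1.0 * grid)
        mix = AreaOfPressure(grid, 0.3 * a1.areas + 0.7 * a2.areas)
        for pi in (0.0, 7.0, 20.0):
            assert excess_area(mix, a1, a2, x1=0.3, at_pi=pi) == pytest.approx(0.0)

    def test_mismatched_grids_rejected(self):
        a = AreaOfPressure(np.linspace(0, 10, 101), np.full(101, 50.0))
        b = AreaOfPressure(np.linspace(0, 10, 51), np.full(51, 50.0))
        with pytest.raises(AlignmentError):
            excess_area(a, a, b, x1=0.5, at_pi=5.0)


class TestExcessGibbs:
    def test_constant_excess_closed_form(self):
        # constant 2 A^2 over [0, 25 mN/m]: N_A * c * pi2 = 6.02214076 * 50
        mix, e1, e2, _ = _mixture(ExcessFn("constant", 2.0))
        dg = excess_gibbs(mix, e1, e2, x1=0.5, pi2=25.0)
        assert dg == pytest.approx(301.107038, rel=5e-3)

    def test_ideal_mixture_is_zero(self):
        mix, e1, e2, _ = _mixture(ExcessFn("zero"), x1=0.3)
        for pi2 in (5.0, 10.0, 25.0):
            assert abs(excess_gibbs(mix, e1, e2, x1=0.3, pi2=pi2)) < 1e-9

    def test_trapezoid_matches_fine_riemann_oracle(self):
        fn = ExcessFn("half_sine", -3.0, 25.0)
        mix, e1, e2, _ = _mixture(fn)
        dg = excess_gibbs(mix, e1, e2, x1=0.5, pi2=25.0)
        oracle = true_excess_gibbs(fn, 25.0)
        assert dg < 0
        assert dg == pytest.approx(oracle, rel=5e-3)

    def test_fundamental_theorem_consistency(self):
        # d(dG)/dpi2 should recover N_A * excess_area(pi2)
        fn = ExcessFn("half_sine", 2.0, 25.0)
        mix, e1, e2, _ = _mixture(fn)
        pi2, h = 12.0, 0.5
        deriv = (
            excess_gibbs(mix, e1, e2, 0.5, pi2 + h)
            - excess_gibbs(mix, e1, e2, 0.5, pi2 - h)
        ) / (2 * h)
        expected = GIBBS_UNIT * excess_area(mix, e1, e2, 0.5, pi2)
        assert deriv == pytest.approx(expected, rel=0.01)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(x1=st.floats(min_value=0.1, max_value=0.9))
    def test_swap_symmetry(self, x1):
        mix, e1, e2, _ = _mixture(ExcessFn("half_sine", 1.5), x1=x1)
        forward = excess_gibbs(mix, e1, e2, x1=x1, pi2=20.0)
        swapped = excess_gibbs(mix, e2, e1, x1=1.0 - x1, pi2=20.0)
        assert forward == pytest.approx(swapped, rel=1e-9, abs=1e-9)


class TestExcessProfile:
    def test_four_pressures_monotone_for_single_signed_excess(self):
        mix, e1, e2, _ = _mixture(ExcessFn("constant", 2.0))
        profile = excess_profile(mix, e1, e2, x1=0.5)
        assert len(profile.entries) == 4
        dgs = [e.delta_g_exc for e in profile.entries]
        assert all(b > a > 0 for a, b in zip(dgs, dgs[1:]))
        assert all(e.interaction == "repulsive" for e in profile.entries)

    def test_zero_pressure_only(self):
        mix, e1, e2, _ = _mixture(ExcessFn("constant", 2.0))
        profile = excess_profile(mix, e1, e2, x1=0.5, pressures=[0.0])
        (entry,) = profile.entries
        assert entry.delta_g_exc == pytest.approx(0.0, abs=1e-12)

    def test_negative_excess_flagged_attractive(self):
        mix, e1, e2, _ = _mixture(ExcessFn("constant", -1.5))
        profile = excess_profile(mix, e1, e2, x1=0.5)
        assert all(e.delta_g_exc < 0 for e in profile.entries)
        assert all(e.interaction == "attractive" for e in profile.entries)


def test_gibbs_unit_constant():
    # 1 A^2 mN/m = 1e-23 J; per mole: N_A * 1e-23
    assert GIBBS_UNIT == pytest.approx(AVOGADRO * 1e-23)
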