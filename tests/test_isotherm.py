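"""Isotherm container, I/O, smoothing, modulus and feature extraction."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monofilm import (
    Composition,
    Isotherm,
    compression_modulus,
    detect_collapse,
    detect_plateau,
    detection_curve,
    extract_features,
    limiting_area,
    read_isotherm,
    smooth_isotherm,
    write_isotherm,
)
from monofilm.errors import (
    DomainError,
    FormatError,
    ParameterError,
    ParseError,
    ValidationError,
)
from monofilm.synthetic import generate_isotherm, isotherm_preset


# --------------------------------------------------------------------------- #
# container invariants


class TestIsothermContainer:
    def test_canonicalises_expansion_order(self):
        area = np.linspace(50.0, 70.0, 21)  # increasing: expansion order
        pressure = 2.0 * (70.0 - area)
        iso = Isotherm(area=area, pressure=pressure)
        assert iso.area[0] > iso.area[-1]
        rev = Isotherm(area=area[::-1].copy(), pressure=pressure[::-1].copy())
        assert iso == rev

    def test_duplicate_abscissa_rejected(self):
        area = np.linspace(70.0, 50.0, 12)
        area[5] = area[6] = 55.0
        with pytest.raises(ValidationError, match="duplicate"):
            Isotherm(area=area, pressure=np.ones(12))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="at least 10"):
            Isotherm(area=np.linspace(70, 60, 9), pressure=np.zeros(9))

    @pytest.mark.parametrize(
        "bad_area,bad_pressure",
        [(lambda a: -a, lambda p: p), (lambda a: a, lambda p: p - 10.0)],
        ids=["negative_area", "pressure_below_baseline"],
    )
    def test_physical_bounds(self, bad_area, bad_pressure):
        area = np.linspace(70.0, 50.0, 12)
        with pytest.raises(ValidationError):
            Isotherm(area=bad_area(area), pressure=bad_pressure(np.ones(12)))

    def test_composition_fractions_validated(self):
        with pytest.raises(ValidationError):
            Composition((("PC 18:3", 0.9), ("CS", 0.2)))
        comp = Composition((("PC 18:3", 0.8), ("CS", 0.15), ("HCS", 0.05)))
        assert comp.x_cs == pytest.approx(0.75)
        assert Composition((("PC 18:3", 1.0),)).x_cs is None


class TestIsothermIO:
    def test_round_trip_identity(self, tmp_path):
        area = np.linspace(70.0, 50.0, 12)
        iso = Isotherm(
            area=area,
            pressure=2.0 * (70.0 - area),
            temperature=10.0,
            composition=Composition((("PC 16:0", 0.8), ("HCS", 0.2))),
            label="demo",
            replicate_id=3,
        )
        path = tmp_path / "iso.csv"
        write_isotherm(iso, path)
        back = read_isotherm(path)
        assert back == iso

    def test_reader_canonicalises_increasing_tables(self):
        rows = "\n".join(f"{a},{2 * (70 - a)}" for a in np.linspace(50, 70, 15))
        text = "area_A2,pressure_mN_m\n" + rows
        iso = read_isotherm(io.StringIO(text))
        rev = read_isotherm(io.StringIO(text))
        assert iso == rev
        assert iso.area[0] > iso.area[-1]

    def test_missing_column_named(self):
        text = "area_A2,pi\n70,0\n"
        with pytest.raises(FormatError, match="pressure_mN_m"):
            read_isotherm(io.StringIO(text))

    def test_non_numeric_cell_reports_row(self):
        rows = [f"{70 - i},{i}" for i in range(12)]
        rows[4] = "oops,4"
        text = "area_A2,pressure_mN_m\n" + "\n".join(rows)
        with pytest.raises(ParseError, match="row 4"):
            read_isotherm(io.StringIO(text))


# --------------------------------------------------------------------------- #
# smoothing


class TestSmoothing:
    def test_polynomial_exactness(self, linear_isotherm):
        for window in (5, 11, 21):
            out = smooth_isotherm(linear_isotherm, window=window, degree=2)
            np.testing.assert_allclose(out.pressure, linear_isotherm.pressure, atol=1e-9)
            np.testing.assert_array_equal(out.area, linear_isotherm.area)

    @pytest.mark.parametrize("window,degree", [(1, 0), (4, 2), (9999, 2), (5, 5)])
    def test_bad_parameters_rejected(self, linear_isotherm, window, degree):
        with pytest.raises(ParameterError):
            smooth_isotherm(linear_isotherm, window=window, degree=degree)

    def test_noise_reduction_against_known_line(self):
        rng = np.random.default_rng(11)
        area = np.linspace(69.75, 55.0, 200)
        truth = 2.0 * (70.0 - area)
        noisy = truth + rng.normal(0.0, 0.1, area.size)
        iso = Isotherm(area=area, pressure=noisy)
        out = smooth_isotherm(iso, window=11, degree=2)
        rms_raw = np.sqrt(np.mean((noisy - truth) ** 2))
        rms_smooth = np.sqrt(np.mean((out.pressure - truth) ** 2))
        assert rms_smooth < rms_raw


# --------------------------------------------------------------------------- #
# compression modulus


class TestCompressionModulus:
    def test_ideal_gas_modulus_equals_pressure(self, ideal_gas_isotherm):
        curve = compression_modulus(ideal_gas_isotherm)
        interior = slice(1, -1)
        np.testing.assert_allclose(
            curve.cs_inv[interior], curve.pressure[interior], rtol=0.01
        )

    def test_linear_branch_hand_value(self):
        # put A = 60 exactly on the grid: cs_inv = -A dpi/dA = 2 * 60
        area = np.linspace(69.0, 51.0, 37)
        iso = Isotherm(area=area, pressure=2.0 * (70.0 - area))
        curve = compression_modulus(iso)
        i = int(np.argmin(np.abs(area - 60.0)))
        assert area[i] == pytest.approx(60.0)
        assert curve.cs_inv[i] == pytest.approx(120.0)

    def test_constant_pressure_gives_zero(self):
        area = np.linspace(70.0, 50.0, 30)
        iso = Isotherm(area=area, pressure=np.full(30, 5.0))
        curve = compression_modulus(iso)
        np.testing.assert_allclose(curve.cs_inv, 0.0, atol=1e-12)


# --------------------------------------------------------------------------- #
# collapse, plateau, limiting area


class TestCollapse:
    def test_noiseless_preset_round_trip(self, pc183_noiseless):
        iso, truth = pc183_noiseless
        smoothed, curve = detection_curve(iso)
        result = detect_collapse(smoothed, curve)
        assert result.detected
        assert result.pi_coll == pytest.approx(
            truth.values["pi_coll_true"], abs=0.2
        )

    def test_monotone_curve_reports_absence(self, ideal_gas_isotherm):
        smoothed, curve = detection_curve(ideal_gas_isotherm)
        result = detect_collapse(smoothed, curve)
        assert not result.detected
        assert result.pi_coll == pytest.approx(ideal_gas_isotherm.pressure[-1], abs=0.01)

    def test_noisy_recovery_rate(self):
        hits = 0
        for seed in range(30):
            spec = isotherm_preset("pc183_20C", sigma_pi=0.1, seed=seed)
            iso, truth = generate_isotherm(spec)
            smoothed, curve = detection_curve(iso)
            result = detect_collapse(smoothed, curve)
            hits += abs(result.pi_coll - truth.values["pi_coll_true"]) <= 0.5
        assert hits >= 29


class TestPlateau:
    def test_noiseless_preset_round_trip(self):
        spec = isotherm_preset("pc160_cs075_10C")
        iso, truth = generate_isotherm(spec)
        feats = extract_features(iso)
        assert feats.plateau_detected
        assert feats.pi_plateau == pytest.approx(23.2, abs=0.05)

    def test_absent_when_no_plateau(self, pc183_noiseless):
        iso, _ = pc183_noiseless
        feats = extract_features(iso)
        assert not feats.plateau_detected
        assert feats.pi_plateau is None

    def test_flat_region_adjacent_to_collapse_is_collapse_not_plateau(self):
        # LE tail rising to a near-flat region followed directly by a
        # post-collapse decline: no condensed branch after the valley
        a_tail = np.linspace(90.0, 60.0, 400)
        p_tail = 24.0 * np.exp(-(a_tail - 60.0) / 8.0)
        a_flat = np.linspace(60.0, 50.0, 150)[1:]
        p_flat = 24.0 + 0.05 * (60.0 - a_flat)
        a_post = np.linspace(50.0, 44.0, 80)[1:]
        p_post = p_flat[-1] + 0.3 * (a_post - 50.0)
        iso = Isotherm(
            area=np.concatenate([a_tail, a_flat, a_post]),
            pressure=np.concatenate([p_tail, p_flat, p_post]),
        )
        feats = extract_features(iso)
        assert feats.collapse_detected
        assert not feats.plateau_detected


class TestLimitingArea:
    def test_affine_branch_recovers_intercept_exactly(self, linear_isotherm):
        curve = compression_modulus(linear_isotherm)
        a_lim, _ = limiting_area(linear_isotherm, curve)
        assert a_lim == pytest.approx(70.0, abs=1e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        intercept=st.floats(min_value=40.0, max_value=120.0),
        slope=st.floats(min_value=0.5, max_value=8.0),
    )
    def test_any_affine_isotherm_is_exact(self, intercept, slope):
        area = np.linspace(intercept - 0.25, intercept - 20.0, 60)
        iso = Isotherm(area=area, pressure=slope * (intercept - area))
        a_lim, _ = limiting_area(iso, compression_modulus(iso))
        assert a_lim == pytest.approx(intercept, abs=1e-6)

    def test_zero_pressure_at_maximum_returns_that_area(self):
        area = np.linspace(70.0, 50.0, 41)
        iso = Isotherm(area=area, pressure=2.0 * (70.0 - area))
        curve = compression_modulus(iso)
        # modulus 2A is maximal at the first point, where pi = 0
        a_lim, i_star = limiting_area(iso, curve)
        assert i_star == 0
        assert a_lim == pytest.approx(area[0])

    def test_degenerate_curve_rejected(self):
        area = np.linspace(70.0, 50.0, 30)
        iso = Isotherm(area=area, pressure=np.full(30, 5.0))
        with pytest.raises(DomainError):
            limiting_area(iso, compression_modulus(iso))


# --------------------------------------------------------------------------- #
# full pipeline


class TestExtractFeatures:
    @pytest.mark.parametrize(
        "preset",
        [
            "pc183_20C",
            "pc183_30C",
            "pc183_hcs_20C",
            "pc183_pc160_20C",
            "pc160_10C",
            "pc160_20C",
            "pc160_30C",
            "pc160_cs_20C",
            "pc160_cs075_10C",
        ],
    )
    def test_noiseless_recovery_all_presets(self, preset):
        iso, truth = generate_isotherm(isotherm_preset(preset))
        tv = truth.values
        feats = extract_features(iso)
        assert feats.a_lim == pytest.approx(tv["A_lim_true"], abs=0.05)
        assert feats.pi_coll == pytest.approx(tv["pi_coll_true"], abs=0.5)
        assert feats.cs_inv_max == pytest.approx(tv["cs_inv_max_true"], rel=0.05)
        if tv["pi_plateau_true"] is None:
            assert feats.pi_plateau is None
        else:
            assert feats.pi_plateau == pytest.approx(tv["pi_plateau_true"], abs=0.5)
            assert feats.pi_plateau < feats.pi_coll

    def test_deterministic(self, pc160_noiseless):
        iso, _ = pc160_noiseless
        assert extract_features(iso) == extract_features(iso)

    def test_invariant_to_row_reversal(self, pc160_noiseless):
        iso, _ = pc160_noiseless
        rev = Isotherm(
            area=iso.area[::-1].copy(),
            pressure=iso.pressure[::-1].copy(),
            temperature=iso.temperature,
        )
        assert extract_features(rev) == extract_features(iso)

    def test_stable_under_factor_two_subsampling(self, pc160_noiseless):
        iso, _ = pc160_noiseless
        sub = Isotherm(area=iso.area[::2].copy(), pressure=iso.pressure[::2].copy())
        f_full = extract_features(iso)
        f_sub = extract_features(sub)
        grid = 2.0 * float(np.max(np.abs(np.diff(sub.pressure))))
        assert abs(f_sub.a_lim - f_full.a_lim) <= 2.0 * abs(iso.area[0] - iso.area[2])
        assert abs(f_sub.pi_coll - f_full.pi_coll) <= grid
        assert abs(f_sub.pi_plateau - f_full.pi_plateau) <= grid

    def test_ideal_gas_yields_no_collapse_no_plateau_finite_alim(
        self, ideal_gas_isotherm
    ):
        feats = extract_features(ideal_gas_isotherm)
        assert not feats.collapse_detected
        assert not feats.plateau_detected
        # steepest tangent is at the smallest area A*: A_lim = 2 A* for pi A = kT
        assert feats.a_lim == pytest.approx(2.0 * ideal_gas_isotherm.area[-1], rel=0.05)
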