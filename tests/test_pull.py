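"""Rupture detection, pull-parameter extraction, tangent modulus, row statistics."""

import numpy as np
import pytest
from scipy.integrate import quad

from fibremech import (
    FibreModel,
    StressStrainCurve,
    detect_rupture,
    extract_pull_parameters,
    generate_pull_trace,
    row_statistics,
    tangent_modulus,
    trace_to_curve,
)
from fibremech.errors import InvalidParameterError


def _linear_curve(E=2e6, eps_r=2.5, n=300):
    strain = np.linspace(0.0, eps_r, n)
    return StressStrainCurve(strain=strain, stress=E * strain, rupture_index=n - 1)


class TestDetectRupture:
    def test_imposed_instant_rupture_found_within_one_sample(self, instrument):
        model = FibreModel(noise_sd=0.01)
        trace = generate_pull_trace(model, instrument, seed=3, rupture_strain=2.5)
        curve = trace_to_curve(trace.y_um, trace.lateral_V, instrument.ke,
                               instrument.cross_section, instrument.well)
        idx = detect_rupture(curve)
        assert idx is not None
        d_eps = np.max(np.diff(curve.strain))
        assert abs(curve.strain[idx] - 2.5) <= d_eps

    def test_strictly_increasing_curve_has_no_rupture(self):
        assert detect_rupture(_linear_curve()) is None

    def test_pure_noise_never_flags_rupture(self, instrument):
        # zero-stiffness fibre: the lateral channel is noise only
        # amplitude kept below the 0.05 MPa background-distinguishable level
        model = FibreModel(E_low=0.0, E_high=0.0, noise_sd=0.0, noise_floor_V=0.001)
        fp = 0
        for seed in range(100):
            trace = generate_pull_trace(model, instrument, seed=seed, rupture_strain=2.9)
            curve = trace_to_curve(trace.y_um, trace.lateral_V, instrument.ke,
                                   instrument.cross_section, instrument.well)
            if detect_rupture(curve) is not None:
                fp += 1
        assert fp == 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            detect_rupture(_linear_curve(n=10))


class TestExtractPullParameters:
    def test_linear_closed_form(self):
        E, eps_r = 2e6, 2.5
        p = extract_pull_parameters(_linear_curve(E, eps_r))
        assert p.rupture_stress == pytest.approx(E * eps_r, rel=1e-12)
        assert p.extensibility == pytest.approx(eps_r, rel=1e-12)
        assert p.toughness == pytest.approx(E * eps_r**2 / 2.0, rel=1e-6)
        assert p.modulus1 == pytest.approx(E, rel=1e-9)
        assert p.modulus2 == pytest.approx(E, rel=1e-9)
        assert p.stiffening_ratio == pytest.approx(1.0, rel=1e-9)

    def test_bilinear_stiffening_ratio(self):
        # slopes E then 3E above strain 2, rupture at 3
        E, knee, eps_r = 1e6, 2.0, 3.0
        strain = np.linspace(0.0, eps_r, 400)
        stress = np.where(strain < knee, E * strain, E * knee + 3 * E * (strain - knee))
        curve = StressStrainCurve(strain=strain, stress=stress, rupture_index=399)
        p = extract_pull_parameters(curve)
        assert p.stiffening_ratio == pytest.approx(3.0, rel=0.02)

    def test_toughness_matches_adaptive_quadrature(self):
        # σ = ε² sampled on the instrument's strain grid (0.1 μm/s at 10 Hz)
        from fibremech import pull_geometry

        d = np.arange(0.0, 20.0, 0.01)
        strain, _ = pull_geometry(d)
        strain = strain[strain <= 2.0]
        curve = StressStrainCurve(strain=strain, stress=strain**2,
                                  rupture_index=len(strain) - 1)
        p = extract_pull_parameters(curve)
        oracle, _ = quad(lambda e: e**2, 0.0, strain[-1])
        assert p.toughness == pytest.approx(oracle, rel=1e-3)

    def test_intact_curve_rejected(self):
        curve = _linear_curve()
        curve.rupture_index = None
        with pytest.raises(InvalidParameterError):
            extract_pull_parameters(curve)

    def test_short_window_flagged_undefined(self):
        # rupture at strain 0.25: the modulus-1 window [0.1, ext−Δ] is empty
        curve = _linear_curve(eps_r=0.25, n=30)
        p = extract_pull_parameters(curve)
        assert np.isnan(p.modulus1)
        assert "modulus1_undefined" in p.flags


class TestTangentModulus:
    def test_linear_curve_constant_tangent(self):
        E = 2e6
        tm = tangent_modulus(_linear_curve(E))
        np.testing.assert_allclose(tm.tangent, E, rtol=1e-9)

    def test_quadratic_curve_tracks_analytic_derivative(self):
        strain = np.linspace(0.0, 2.0, 2000)
        curve = StressStrainCurve(strain=strain, stress=strain**2,
                                  rupture_index=len(strain) - 1)
        tm = tangent_modulus(curve, window=50)
        # smoothing a linear derivative is exact in the interior; edges shrink
        err = np.abs(tm.tangent - 2.0 * tm.strain)
        half_width_strain = 25 * (strain[1] - strain[0])
        assert np.max(err) <= 2.0 * half_width_strain + 1e-9

    def test_short_curve_warns_and_still_returns(self):
        strain = np.linspace(0.0, 1.0, 49)
        curve = StressStrainCurve(strain=strain, stress=3e6 * strain)
        with pytest.warns(UserWarning):
            tm = tangent_modulus(curve, window=50)
        assert len(tm.tangent) == 49

    def test_tangent_average_matches_modulus1_on_linear_region(self):
        E = 2e6
        curve = _linear_curve(E)
        p = extract_pull_parameters(curve)
        tm = tangent_modulus(curve)
        sel = (tm.strain >= 0.1) & (tm.strain <= 1.5)
        assert np.mean(tm.tangent[sel]) == pytest.approx(p.modulus1, rel=0.05)


class TestRowStatistics:
    def test_two_fibre_closed_form(self):
        strain = np.linspace(0.0, 3.0, 301)
        c1 = StressStrainCurve(strain=strain, stress=1.0 * strain, rupture_index=300)
        c2 = StressStrainCurve(strain=strain, stress=2.0 * strain, rupture_index=300)
        df = row_statistics([c1, c2], step=0.5)
        np.testing.assert_allclose(df["mean"], 1.5 * df["strain"], rtol=1e-9)
        np.testing.assert_allclose(df["sem"], 0.5 * df["strain"], rtol=1e-9, atol=1e-12)

    def test_identical_fibres_zero_sem(self):
        strain = np.linspace(0.0, 2.0, 201)
        curves = [
            StressStrainCurve(strain=strain, stress=2e6 * strain, rupture_index=200)
            for _ in range(5)
        ]
        df = row_statistics(curves)
        np.testing.assert_allclose(df["sem"], 0.0, atol=1e-9)

    def test_ruptured_fibres_drop_out(self):
        strain = np.linspace(0.0, 3.0, 301)
        ruptured = StressStrainCurve(strain=strain, stress=strain, rupture_index=200)  # ε = 2
        intact = StressStrainCurve(strain=strain, stress=strain, rupture_index=300)
        df = row_statistics([ruptured, intact], step=0.5)
        assert int(df.loc[df["strain"] == 1.5, "n"].iloc[0]) == 2
        assert int(df.loc[df["strain"] == 2.5, "n"].iloc[0]) == 1

    def test_empty_collection_rejected(self):
        with pytest.raises(InvalidParameterError):
            row_statistics([])
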