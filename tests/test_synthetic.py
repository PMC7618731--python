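"""Generator determinism, closed forms and analysis roundtrips."""

import numpy as np
import pytest

from fibremech import (
    FibreModel,
    constitutive_stress,
    detect_rupture,
    extract_pull_parameters,
    fold_change_table,
    generate_cohort,
    generate_pull_trace,
    generate_relaxation_trace,
    pull_geometry,
    segment_phases,
    segments,
    trace_to_curve,
)
from fibremech.errors import InvalidParameterError
from fibremech.synthetic import PRESETS, hold_decay


class TestConstitutiveLaw:
    def test_zero_strain_zero_stress(self, fibre_model):
        assert constitutive_stress(fibre_model, 0.0) == 0.0

    def test_limiting_slopes(self, fibre_model):
        # well below the knee the slope is E_low; well above, E_high
        lo = (constitutive_stress(fibre_model, 0.6) - constitutive_stress(fibre_model, 0.5)) / 0.1
        hi = (constitutive_stress(fibre_model, 3.5) - constitutive_stress(fibre_model, 3.4)) / 0.1
        assert lo == pytest.approx(fibre_model.E_low, rel=1e-4)
        assert hi == pytest.approx(fibre_model.E_high, rel=1e-3)

    def test_linear_when_moduli_equal(self):
        m = FibreModel(E_low=2e6, E_high=2e6)
        eps = np.linspace(0, 3, 50)
        np.testing.assert_allclose(constitutive_stress(m, eps), 2e6 * eps, rtol=1e-12)


class TestDeterminism:
    def test_same_seed_bit_identical(self, fibre_model, instrument):
        a = generate_pull_trace(fibre_model, instrument, seed=42)
        b = generate_pull_trace(fibre_model, instrument, seed=42)
        np.testing.assert_array_equal(a.lateral_V, b.lateral_V)
        np.testing.assert_array_equal(a.y_um, b.y_um)

    def test_different_seed_differs(self, fibre_model, instrument):
        a = generate_pull_trace(fibre_model, instrument, seed=1)
        b = generate_pull_trace(fibre_model, instrument, seed=2)
        assert not np.array_equal(a.lateral_V, b.lateral_V)

    def test_cohort_reproducible(self, instrument):
        t1, g1 = generate_cohort(n_per_group=2, seed=7, instrument=instrument)
        t2, g2 = generate_cohort(n_per_group=2, seed=7, instrument=instrument)
        np.testing.assert_array_equal(t1[0].lateral_V, t2[0].lateral_V)
        assert g1.equals(g2)

    def test_empty_cohort(self, instrument):
        traces, truth = generate_cohort(n_per_group=0, seed=1, instrument=instrument)
        assert traces == [] and len(truth) == 0


class TestPullRoundtrip:
    def test_noise_free_linear_law_recovers_modulus(self, instrument):
        model = FibreModel(E_low=2e6, E_high=2e6, noise_sd=0.0)
        trace = generate_pull_trace(model, instrument, seed=0, rupture_strain=2.9)
        curve = trace_to_curve(trace.y_um, trace.lateral_V, instrument.ke,
                               instrument.cross_section, instrument.well)
        curve.rupture_index = detect_rupture(curve)
        p = extract_pull_parameters(curve)
        assert p.modulus1 == pytest.approx(2e6, rel=1e-3)

    def test_zero_stiffness_gives_noise_only_signal(self, instrument):
        model = FibreModel(E_low=0.0, E_high=0.0, noise_sd=0.0,
                           noise_floor_V=0.003, drift_amplitude_V=0.05)
        trace = generate_pull_trace(model, instrument, seed=1, rupture_strain=2.9)
        drift = 0.05 * (trace.time - trace.time[0]) / (trace.time[-1] - trace.time[0])
        residual = trace.lateral_V - drift
        assert np.max(np.abs(residual)) < 5 * 0.003  # noise floor only

    def test_imposed_rupture_strain_detected(self, instrument):
        model = FibreModel(noise_sd=0.01)
        trace = generate_pull_trace(model, instrument, seed=11, rupture_strain=2.65)
        curve = trace_to_curve(trace.y_um, trace.lateral_V, instrument.ke,
                               instrument.cross_section, instrument.well)
        idx = detect_rupture(curve)
        assert abs(curve.strain[idx] - 2.65) <= np.max(np.diff(curve.strain))


class TestRelaxationTrace:
    def test_flat_holds_when_purely_elastic(self, instrument):
        model = FibreModel(relax_offset_fraction=1.0, noise_sd=0.0)
        trace = generate_relaxation_trace(model, instrument, seed=0)
        labelled = segment_phases(trace)
        for phase, i, j in segments(labelled):
            if phase == "hold":
                assert np.ptp(trace.lateral_V[i:j]) < 1e-12 * np.max(np.abs(trace.lateral_V))

    def test_hold_decay_matches_closed_form_exactly(self, instrument):
        # reconstruct stress from the noise-free lateral channel and compare
        # with the analytic offset-plus-two-exponential law
        model = FibreModel(noise_sd=0.0)
        trace = generate_relaxation_trace(model, instrument, seed=0)
        labelled = segment_phases(trace)
        holds = [(i, j) for p, i, j in segments(labelled) if p == "hold"]
        assert holds
        i, j = holds[2]
        while i > 0 and abs(trace.y_um[i - 1] - trace.y_um[i]) < 1e-9:
            i -= 1
        d = trace.y_um[i]
        strain, sin_alpha = pull_geometry(d, instrument.well)
        stress = trace.lateral_V[i:j] * instrument.ke / (2 * sin_alpha) / instrument.cross_section.area
        t = trace.time[i:j] - trace.time[i]
        expected = hold_decay(model, constitutive_stress(model, strain), t)
        np.testing.assert_allclose(stress, expected, rtol=1e-12)


class TestCohortRecovery:
    def test_extensibility_fold_change_recovered_through_pipeline(self, instrument):
        # planted 0.882 extensibility ratio survives the full raw-trace pipeline
        presets = [PRESETS["wt-x"], PRESETS["a220-x"]]
        traces, truth = generate_cohort(presets, n_per_group=25, seed=3,
                                        instrument=instrument, mode="pull")
        rows = []
        for trace in traces:
            curve = trace_to_curve(trace.y_um, trace.lateral_V, instrument.ke,
                                   instrument.cross_section, instrument.well)
            curve.rupture_index = detect_rupture(curve)
            p = extract_pull_parameters(curve)
            rows.append({"variant": trace.metadata["label"], "crosslinked": True,
                         "extensibility": p.extensibility})
        import pandas as pd

        table = fold_change_table(pd.DataFrame(rows), ["extensibility"])
        # 2×SEM of the ratio at n = 25 with sd 0.25 around mean 2.9
        band = 2.0 * np.sqrt(2) * 0.25 / np.sqrt(25) / 2.9
        assert table.loc["extensibility", "a220X/WTX"] == pytest.approx(0.882, abs=band)

    def test_presets_carry_provenance(self):
        for preset in PRESETS.values():
            assert preset.provenance  # every preset documents its parameter sources
            assert "tau1" in preset.provenance

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            FibreModel(tau1=10.0, tau2=5.0)
        with pytest.raises(InvalidParameterError):
            FibreModel(relax_offset_fraction=0.0)
        with pytest.raises(InvalidParameterError):
            FibreModel(rupture_strain_mean=1.0, stiffening_onset=2.0)
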