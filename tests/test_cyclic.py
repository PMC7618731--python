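"""Drift correction, characteristic strain, Loss% and hysteresis for cyclic pulls."""

import numpy as np
import pytest

from fibremech import (
    Cycle,
    FibreModel,
    RawTrace,
    analyze_cyclic_trace,
    characteristic_strain,
    correct_drift,
    generate_cyclic_trace,
    hysteresis_percent,
    loss_percent,
)
from fibremech.errors import BaselineError, InvalidParameterError


def _cycle(pull_stress_fn, release_stress_fn=None, peak=2.0, n=200, index=1):
    strain = np.linspace(0.0, peak, n)
    release = release_stress_fn(strain) if release_stress_fn else pull_stress_fn(strain)
    return Cycle(
        index_in_step=index, target_strain=peak,
        pull_strain=strain, pull_stress=pull_stress_fn(strain),
        release_strain=strain[::-1], release_stress=release[::-1],
    )


class TestCorrectDrift:
    def test_zero_drift_is_identity(self, fibre_model, instrument):
        trace = generate_cyclic_trace(FibreModel(noise_sd=0.0), instrument, seed=1)
        corrected = correct_drift(trace)
        np.testing.assert_allclose(corrected.lateral_V, trace.lateral_V, atol=1e-12)

    def test_pure_linear_drift_removed(self):
        # no fibre engaged: the cantilever sits at home while the signal drifts
        t = np.arange(0.0, 60.0, 0.1)
        drift = 0.2 * t / t[-1]
        trace = RawTrace(time=t, y_um=np.zeros_like(t), lateral_V=drift)
        corrected = correct_drift(trace)
        assert np.max(np.abs(corrected.lateral_V)) < 1e-6

    def test_idempotent(self, instrument):
        model = FibreModel(noise_sd=0.005, drift_amplitude_V=0.15)
        trace = generate_cyclic_trace(model, instrument, seed=4)
        once = correct_drift(trace)
        twice = correct_drift(once)
        np.testing.assert_allclose(twice.lateral_V, once.lateral_V, atol=1e-9)

    def test_metrics_robust_to_drift(self, instrument):
        # 0.15 V slow drift: all downstream metrics within 2 % of the no-drift run
        kwargs = dict(noise_sd=0.0)
        clean = generate_cyclic_trace(FibreModel(**kwargs), instrument, seed=7)
        drifty = generate_cyclic_trace(
            FibreModel(drift_amplitude_V=0.15, **kwargs), instrument, seed=7
        )
        df_clean = analyze_cyclic_trace(clean, instrument.ke, instrument.cross_section)
        df_drift = analyze_cyclic_trace(drifty, instrument.ke, instrument.cross_section)
        for col in ("characteristic_strain", "loss_percent", "hysteresis_percent"):
            a = df_clean[col].to_numpy()
            b = df_drift[col].to_numpy()
            mask = np.isfinite(a)
            np.testing.assert_allclose(b[mask], a[mask], rtol=0.02, atol=0.01)

    def test_no_dwells_raises(self):
        t = np.arange(0.0, 30.0, 0.1)
        trace = RawTrace(time=t, y_um=0.1 * t + 1.0, lateral_V=np.zeros_like(t))
        with pytest.raises(BaselineError):
            correct_drift(trace)


class TestCharacteristicStrain:
    def test_linear_crossing(self):
        c = _cycle(lambda e: 0.1e6 * e)
        assert characteristic_strain(c) == pytest.approx(0.5, rel=1e-9)

    def test_never_crossed_is_undefined(self):
        c = _cycle(lambda e: np.full_like(e, 0.03e6))
        assert np.isnan(characteristic_strain(c))

    def test_empty_pull_rejected(self):
        c = Cycle(1, 1.0, np.array([]), np.array([]), np.array([]), np.array([]))
        with pytest.raises(InvalidParameterError):
            characteristic_strain(c)

    def test_tracks_imposed_permanent_elongation(self, instrument):
        # parameters chosen so ~0.9 permanent strain enters the final step
        model = FibreModel(noise_sd=0.005, permanent_elongation_rate=0.6,
                           yield_strain=0.4, elongation_per_cycle=0.6)
        trace = generate_cyclic_trace(model, instrument, seed=5)
        truth = trace.metadata["cycles_true"]
        p_in_last_step = truth[6]["p_in"]
        assert 0.85 <= p_in_last_step <= 0.95
        df = analyze_cyclic_trace(trace, instrument.ke, instrument.cross_section)
        measured = df.iloc[6]["characteristic_strain"]
        assert measured == pytest.approx(p_in_last_step, abs=0.05)


class TestLossPercent:
    def test_identical_cycles_no_loss(self):
        cycles = [_cycle(lambda e: 1e6 * e, index=i + 1) for i in range(3)]
        df = loss_percent(cycles)
        np.testing.assert_allclose(df["retained_percent"], 100.0, rtol=1e-9)
        np.testing.assert_allclose(df["loss_percent"], 0.0, atol=1e-9)

    def test_imposed_softening_recovered(self):
        # cycle 2 pull scaled to 50 % of cycle 1 → retained 50, loss 50
        c1 = _cycle(lambda e: 1e6 * e, index=1)
        c2 = _cycle(lambda e: 0.5e6 * e, index=2)
        df = loss_percent([c1, c2])
        assert df.iloc[0]["retained_percent"] == pytest.approx(50.0, rel=1e-9)
        assert df.iloc[0]["loss_percent"] == pytest.approx(50.0, rel=1e-9)

    def test_twenty_percent_softening(self):
        c1 = _cycle(lambda e: 1e6 * e**2, index=1)
        c2 = _cycle(lambda e: 0.8e6 * e**2, index=2)
        df = loss_percent([c1, c2])
        assert df.iloc[0]["loss_percent"] == pytest.approx(20.0, rel=1e-6)

    def test_zero_first_pull_flagged(self):
        c1 = _cycle(lambda e: np.zeros_like(e), index=1)
        c2 = _cycle(lambda e: 1e6 * e, index=2)
        df = loss_percent([c1, c2])
        assert np.isnan(df.iloc[0]["loss_percent"])
        assert df.iloc[0]["flag"] == "zero_first_pull_area"


class TestHysteresis:
    def test_elastic_retrace_zero(self):
        c = _cycle(lambda e: 1e6 * e)
        assert hysteresis_percent(c) == pytest.approx(0.0, abs=1e-9)

    def test_zero_release_full_dissipation(self):
        c = _cycle(lambda e: 1e6 * e, release_stress_fn=lambda e: np.zeros_like(e))
        assert hysteresis_percent(c) == pytest.approx(100.0, rel=1e-9)

    def test_generator_hysteresis_decreases_within_steps(self, instrument):
        model = FibreModel(noise_sd=0.005)
        trace = generate_cyclic_trace(model, instrument, seed=2)
        df = analyze_cyclic_trace(trace, instrument.ke, instrument.cross_section)
        for _, step in df.groupby("step"):
            h = step.sort_values("cycle")["hysteresis_percent"].to_numpy()
            assert np.all(np.diff(h) < 0)

    def test_characteristic_strain_nondecreasing_for_softening_fibre(self, instrument):
        model = FibreModel(noise_sd=0.005)
        trace = generate_cyclic_trace(model, instrument, seed=9)
        df = analyze_cyclic_trace(trace, instrument.ke, instrument.cross_section)
        cs = df["characteristic_strain"].to_numpy()
        assert np.all(np.diff(cs) >= -0.02)

    def test_recoverable_fibre_shows_no_permanent_strain(self, instrument):
        model = FibreModel(noise_sd=0.0, permanent_elongation_rate=0.0, dissipation=0.0)
        trace = generate_cyclic_trace(model, instrument, seed=1)
        df = analyze_cyclic_trace(trace, instrument.ke, instrument.cross_section)
        assert np.all(df["characteristic_strain"] < 0.05)
        assert np.all(np.abs(df["hysteresis_percent"]) < 1.0)
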