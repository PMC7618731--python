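"""Synthetic fibre + instrument simulator: the inverse of the analysis pipeline.

Every analysis stage is tested against traces generated here from a known
ground truth. The fibre model is deliberately phenomenological — it
emulates what the instrument records, not the protofibril-level
mechanism:

* a strain-stiffening constitutive curve: two linear branches of modulus
  ``E_low`` and ``E_high`` blended smoothly (softplus knee) at the
  stiffening onset, terminated by instantaneous rupture at a per-fibre
  rupture strain drawn from a truncated normal;
* hold-phase stress decay with an offset plus two exponentials,
  σ(t) = σ_peak·[f0 + (1−f0)·(f_fast·e^(−t/τ1) + (1−f_fast)·e^(−t/τ2))],
  so the offset fraction ``f0`` maps exactly onto the measured elastic
  proportion and ``f_fast`` onto the fast-relaxation contribution;
* instrument geometry and schedule: 10 μm wells, lateral pulling at
  0.1 μm/s sampled at 10 points/s, 2 μm strain steps with 2-minute holds;
* measurement imperfections: multiplicative Gaussian noise on the lateral
  signal, an optional additive noise floor, and an optional slow linear
  drift;
* cyclic mode: permanent elongation accumulating toward a yield-rule
  target, plus a dissipation factor scaling the release branch.

All randomness flows from one seed; per-fibre substreams are derived by
counter, so cohorts are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .mechanics import FibreCrossSection, WellGeometry, pull_geometry
from .trace_io import RawTrace


@dataclass
class Instrument:
    """Calibrated instrument state used both to generate and to analyse."""

    ke: float = 1e-7  # N/V; puts rupture-level signals in the observed volt range
    cross_section: FibreCrossSection = field(
        default_factory=lambda: FibreCrossSection(height=180e-9, width=180e-9)
    )
    well: WellGeometry = field(default_factory=WellGeometry)
    sample_rate: float = 10.0  # samples/s
    pull_speed_um_s: float = 0.1


@dataclass
class FibreModel:
    """Ground-truth fibre parameters for the simulator."""

    E_low: float = 2e6  # Pa, pre-stiffening modulus
    E_high: float = 8e6  # Pa, post-stiffening modulus
    stiffening_onset: float = 2.0  # strain at the knee
    stiffening_width: float = 0.1  # knee smoothing width (strain)
    rupture_strain_mean: float = 2.9
    rupture_strain_sd: float = 0.25
    relax_offset_fraction: float = 0.568  # f0: elastic proportion of a hold
    relax_fast_fraction: float = 0.35  # f_fast: fast share of the decaying part
    tau1: float = 7.3  # s
    tau2: float = 90.4  # s
    permanent_elongation_rate: float = 0.35  # strain retained per unit peak strain past yield
    yield_strain: float = 0.4
    elongation_per_cycle: float = 0.6  # fraction of the remaining gap closed each cycle
    dissipation: float = 0.2  # release-branch scaling producing hysteresis
    noise_sd: float = 0.01  # relative (multiplicative) lateral noise
    noise_floor_V: float = 0.0  # additive lateral noise
    drift_amplitude_V: float = 0.0  # linear drift over the trace duration

    def __post_init__(self) -> None:
        if not (0 < self.relax_offset_fraction <= 1):
            raise InvalidParameterError("relax_offset_fraction must be in (0, 1]")
        if not (0 <= self.relax_fast_fraction <= 1):
            raise InvalidParameterError("relax_fast_fraction must be in [0, 1]")
        if not (0 < self.tau1 < self.tau2):
            raise InvalidParameterError("need 0 < tau1 < tau2")
        if not (self.rupture_strain_mean > self.stiffening_onset):
            raise InvalidParameterError("rupture strain must exceed the stiffening onset")


@dataclass
class VariantPreset:
    """A labelled fibre-model parameter set with per-parameter provenance.

    ``provenance`` maps parameter names to a note saying whether the
    default was taken from reported cohort values or is an arbitrary
    package default.
    """

    label: str
    crosslinked: bool
    model: FibreModel
    provenance: dict[str, str] = field(default_factory=dict)


def _softplus(x):
    return np.logaddexp(0.0, x)


def constitutive_stress(model: FibreModel, strain):
    """Smoothed-bilinear engineering stress [Pa] at the given strain(s).

    Integrates a tangent modulus that blends E_low into E_high through a
    logistic step of width ``stiffening_width`` centred on the
    stiffening onset; σ(0) = 0 exactly.
    """
    eps = np.asarray(strain, dtype=float)
    w = model.stiffening_width
    dE = model.E_high - model.E_low
    knee = _softplus((eps - model.stiffening_onset) / w) - _softplus(
        -model.stiffening_onset / w
    )
    sigma = model.E_low * eps + dE * w * knee
    return float(sigma) if np.ndim(strain) == 0 else sigma


@dataclass
class StepSchedule:
    """Incremental-pull protocol: Y steps of ``step_um`` followed by holds."""

    step_um: float = 2.0
    hold_s: float = 120.0
    n_steps: int = 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _lateral_from_stress(sigma, sin_alpha, instrument: Instrument):
    """Invert the force pipeline: L_v = σ·A·2·sin α / k_e."""
    return np.asarray(sigma) * instrument.cross_section.area * 2.0 * np.asarray(sin_alpha) / instrument.ke


def _add_imperfections(lateral, time, model: FibreModel, rng: np.random.Generator):
    out = np.asarray(lateral, float).copy()
    if model.noise_sd > 0:
        out = out * (1.0 + model.noise_sd * rng.standard_normal(out.shape))
    if model.noise_floor_V > 0:
        out = out + model.noise_floor_V * rng.standard_normal(out.shape)
    if model.drift_amplitude_V != 0 and time[-1] > time[0]:
        out = out + model.drift_amplitude_V * (time - time[0]) / (time[-1] - time[0])
    return out


def draw_rupture_strain(model: FibreModel, rng: np.random.Generator) -> float:
    """Per-fibre rupture strain: normal, truncated above the stiffening onset."""
    for _ in range(1000):
        eps_r = model.rupture_strain_mean + model.rupture_strain_sd * rng.standard_normal()
        if eps_r > model.stiffening_onset:
            return float(eps_r)
    raise InvalidParameterError("rupture-strain truncation rejected 1000 draws")


def generate_pull_trace(
    model: FibreModel,
    instrument: Instrument | None = None,
    seed: int = 0,
    rupture_strain: float | None = None,
    overshoot_um: float = 2.0,
) -> RawTrace:
    """One continuous pull to rupture.

    The Y-position ramps at the pull speed; quasi-static stress follows
    the constitutive curve up to the rupture strain, beyond which the
    fibre signal drops instantly to zero (noise and drift remain). The
    drawn rupture strain is recorded in the trace metadata.
    """
    instrument = instrument or Instrument()
    rng = _rng(seed, 0)
    eps_r = draw_rupture_strain(model, rng) if rupture_strain is None else float(rupture_strain)
    a = instrument.well.half_width_um
    d_rupture = a * np.sqrt((1.0 + eps_r) ** 2 - 1.0)
    dt = 1.0 / instrument.sample_rate
    d_per_sample = instrument.pull_speed_um_s * dt
    n = int(np.ceil((d_rupture + overshoot_um) / d_per_sample)) + 1
    d = np.arange(n) * d_per_sample
    time = np.arange(n) * dt
    strain, sin_alpha = pull_geometry(d, instrument.well)
    sigma = constitutive_stress(model, strain)
    sigma[strain >= eps_r] = 0.0
    lateral = _lateral_from_stress(sigma, sin_alpha, instrument)
    lateral = _add_imperfections(lateral, time, model, rng)
    return RawTrace(
        time=time, y_um=d, lateral_V=lateral,
        sample_rate=instrument.sample_rate,
        metadata={"mode": "pull", "rupture_strain_true": eps_r, "seed": seed},
    )


def hold_decay(model: FibreModel, sigma_peak: float, t: np.ndarray) -> np.ndarray:
    """Closed-form hold-phase stress decay from the peak stress.

    σ(t) = σ_peak·[f0 + (1−f0)·(f_fast·e^(−t/τ1) + (1−f_fast)·e^(−t/τ2))],
    so σ(0) = σ_peak and σ(∞) = f0·σ_peak exactly.
    """
    f0 = model.relax_offset_fraction
    ff = model.relax_fast_fraction
    return sigma_peak * (
        f0 + (1.0 - f0) * (ff * np.exp(-t / model.tau1) + (1.0 - ff) * np.exp(-t / model.tau2))
    )


def generate_relaxation_trace(
    model: FibreModel,
    instrument: Instrument | None = None,
    schedule: StepSchedule | None = None,
    seed: int = 0,
) -> RawTrace:
    """Incremental pull: 2 μm Y-steps, each followed by a 2-minute hold.

    Pull segments follow the constitutive curve quasi-statically; each
    hold decays from its entry stress by the closed-form offset-plus-two-
    exponential law (noise-free before the instrument imperfections are
    applied).
    """
    instrument = instrument or Instrument()
    schedule = schedule or StepSchedule()
    rng = _rng(seed, 0)
    dt = 1.0 / instrument.sample_rate
    d_per_sample = instrument.pull_speed_um_s * dt

    d_parts: list[np.ndarray] = [np.array([0.0])]
    sigma_parts: list[np.ndarray] = [np.array([0.0])]
    d_now = 0.0
    for _ in range(schedule.n_steps):
        d_next = d_now + schedule.step_um
        n_pull = int(round(schedule.step_um / d_per_sample))
        d_seg = d_now + np.arange(1, n_pull + 1) * d_per_sample
        strain_seg, _ = pull_geometry(d_seg, instrument.well)
        sigma_parts.append(constitutive_stress(model, strain_seg))
        d_parts.append(d_seg)
        n_hold = int(round(schedule.hold_s * instrument.sample_rate))
        t_hold = np.arange(1, n_hold + 1) * dt
        eps_hold, _ = pull_geometry(d_next, instrument.well)
        sigma_peak = constitutive_stress(model, eps_hold)
        # decay clock starts at the last pull sample (the peak)
        sigma_parts.append(hold_decay(model, sigma_peak, t_hold))
        d_parts.append(np.full(n_hold, d_next))
        d_now = d_next
    d = np.concatenate(d_parts)
    sigma = np.concatenate(sigma_parts)
    time = np.arange(len(d)) * dt
    _, sin_alpha = pull_geometry(d, instrument.well)
    lateral = _lateral_from_stress(sigma, sin_alpha, instrument)
    lateral = _add_imperfections(lateral, time, model, rng)
    return RawTrace(
        time=time, y_um=d, lateral_V=lateral,
        sample_rate=instrument.sample_rate,
        metadata={
            "mode": "relaxation", "seed": seed,
            "tau1_true": model.tau1, "tau2_true": model.tau2,
            "f0_true": model.relax_offset_fraction,
            "f_fast_true": model.relax_fast_fraction,
            "n_steps": schedule.n_steps,
        },
    )


def generate_cyclic_trace(
    model: FibreModel,
    instrument: Instrument | None = None,
    targets: tuple[float, ...] = (1, 1, 1, 2, 2, 2, 3, 3, 3),
    seed: int = 0,
    dwell_s: float = 2.0,
) -> RawTrace:
    """Cyclic protocol: pull to each target strain and release, at ±0.1 μm/s.

    Permanent elongation ``p`` relaxes toward the yield-rule target
    p* = rate·(ε_peak − yield)+ by a fixed fraction per cycle, the pull
    branch follows the constitutive curve shifted by the entering ``p``,
    and the release branch is the shifted curve (with the cycle's updated
    ``p``) scaled by (1 − dissipation). Zero-strain dwells between cycles
    anchor drift correction. Per-cycle ground truth (p in/out, peak
    strain) is stored in the metadata.
    """
    if any(b < a for a, b in zip(targets, targets[1:])):
        raise InvalidParameterError("cyclic targets must be non-decreasing")
    instrument = instrument or Instrument()
    rng = _rng(seed, 0)
    a = instrument.well.half_width_um
    dt = 1.0 / instrument.sample_rate
    d_per_sample = instrument.pull_speed_um_s * dt
    n_dwell = int(round(dwell_s * instrument.sample_rate))

    d_parts: list[np.ndarray] = [np.zeros(n_dwell)]
    sigma_parts: list[np.ndarray] = [np.zeros(n_dwell)]
    p = 0.0
    truth = []
    for eps_t in targets:
        d_t = a * np.sqrt((1.0 + eps_t) ** 2 - 1.0)
        n_ramp = int(np.ceil(d_t / d_per_sample))
        d_up = np.arange(1, n_ramp + 1) * d_per_sample
        strain_up, _ = pull_geometry(d_up, instrument.well)
        p_in = p
        sigma_up = constitutive_stress(model, np.maximum(strain_up - p_in, 0.0))
        sigma_up[strain_up <= p_in] = 0.0
        peak = float(strain_up[-1])
        p_target = model.permanent_elongation_rate * max(0.0, peak - model.yield_strain)
        p = p + model.elongation_per_cycle * max(0.0, p_target - p)
        d_down = d_up[::-1][1:]
        strain_down, _ = pull_geometry(d_down, instrument.well)
        sigma_down = (1.0 - model.dissipation) * constitutive_stress(
            model, np.maximum(strain_down - p, 0.0)
        )
        sigma_down[strain_down <= p] = 0.0
        truth.append({"target": float(eps_t), "peak_strain": peak, "p_in": p_in, "p_out": p})
        d_parts += [d_up, d_down, np.zeros(n_dwell)]
        sigma_parts += [sigma_up, sigma_down, np.zeros(n_dwell)]
    d = np.concatenate(d_parts)
    sigma = np.concatenate(sigma_parts)
    time = np.arange(len(d)) * dt
    _, sin_alpha = pull_geometry(d, instrument.well)
    lateral = _lateral_from_stress(sigma, sin_alpha, instrument)
    lateral = _add_imperfections(lateral, time, model, rng)
    return RawTrace(
        time=time, y_um=d, lateral_V=lateral,
        sample_rate=instrument.sample_rate,
        metadata={"mode": "cyclic", "seed": seed, "cycles_true": truth},
    )


def _preset(label: str, crosslinked: bool, ext_ratio: float, f_fast: float,
            f_fast_note: str) -> VariantPreset:
    model = FibreModel(
        rupture_strain_mean=2.9 * ext_ratio,
        relax_fast_fraction=f_fast,
    )
    return VariantPreset(
        label=label, crosslinked=crosslinked, model=model,
        provenance={
            "rupture_strain_mean": f"2.9 (arbitrary baseline) x {ext_ratio} reported extensibility ratio",
            "tau1": "reported cohort mean 7.3 s",
            "tau2": "reported cohort mean 90.4 s",
            "relax_offset_fraction": "reported cohort mean elastic proportion 56.8 %",
            "relax_fast_fraction": f_fast_note,
            "E_low": "arbitrary default (MPa-range low-strain modulus)",
            "E_high": "arbitrary default (post-stiffening modulus)",
        },
    )


#: Crosslinked variant presets. Extensibility means follow the reported
#: ratio-over-WT values; relaxation parameters follow the reported cohort
#: means; remaining parameters are package defaults.
PRESETS: dict[str, VariantPreset] = {
    "wt-x": _preset("WT", True, 1.0, 0.35, "arbitrary default (no WT value reported)"),
    "a390-x": _preset("a390", True, 1.009, 0.35, "arbitrary default"),
    "a220-x": _preset("a220", True, 0.882, 0.16, "reported ~16 % fast contribution"),
}

#: Default cohort sizes per variant label (crosslinked cohorts).
DEFAULT_COHORT_SIZES = {"WT": 26, "a390": 20, "a220": 23}


def generate_cohort(
    presets: list[VariantPreset] | None = None,
    n_per_group: dict[str, int] | int | None = None,
    seed: int = 0,
    mode: str = "pull",
    instrument: Instrument | None = None,
    schedule: StepSchedule | None = None,
) -> tuple[list[RawTrace], pd.DataFrame]:
    """Generate a cohort of traces plus its ground-truth table.

    ``mode`` is ``pull``, ``relaxation`` or ``cyclic``. Cohort sizes
    default to the reported crosslinked cohort (WT 26, a390 20, a220 23).
    Each fibre uses a substream keyed by (group index, fibre index), so
    the cohort is reproducible and order-independent given ``seed``.
    """
    presets = presets if presets is not None else list(PRESETS.values())
    instrument = instrument or Instrument()
    traces: list[RawTrace] = []
    rows = []
    for g, preset in enumerate(presets):
        if isinstance(n_per_group, int):
            n = n_per_group
        elif isinstance(n_per_group, dict):
            n = n_per_group[preset.label]
        else:
            n = DEFAULT_COHORT_SIZES.get(preset.label, 20)
        for i in range(n):
            fibre_seed_rng = _rng(seed, g, i)
            model = preset.model
            row = {
                "fibre_id": f"{preset.label}-{i:03d}",
                "label": preset.label,
                "crosslinked": preset.crosslinked,
                "E_low": model.E_low, "E_high": model.E_high,
                "tau1": model.tau1, "tau2": model.tau2,
                "f0": model.relax_offset_fraction,
                "f_fast": model.relax_fast_fraction,
            }
            if mode == "pull":
                eps_r = draw_rupture_strain(model, fibre_seed_rng)
                trace = generate_pull_trace(
                    model, instrument, seed=_sub_seed(seed, g, i), rupture_strain=eps_r
                )
                row["rupture_strain"] = eps_r
            elif mode == "relaxation":
                trace = generate_relaxation_trace(
                    model, instrument, schedule=schedule, seed=_sub_seed(seed, g, i)
                )
            elif mode == "cyclic":
                trace = generate_cyclic_trace(model, instrument, seed=_sub_seed(seed, g, i))
            else:
                raise InvalidParameterError(f"unknown cohort mode {mode!r}")
            trace.metadata.update(fibre_id=row["fibre_id"], label=preset.label,
                                  crosslinked=preset.crosslinked)
            traces.append(trace)
            rows.append(row)
    return traces, pd.DataFrame(rows)


def _sub_seed(seed: int, g: int, i: int) -> int:
    """Deterministic per-fibre sub-seed below 2^31."""
    return int(np.random.SeedSequence(seed, spawn_key=(g, i)).generate_state(1)[0] % (2**31 - 1))


def relaxation_recovery_preset(
    f_fast: float = 0.35,
    noise_sd: float = 0.01,
) -> FibreModel:
    """Fibre model whose hold decays are planted at the reported cohort
    means (τ1 = 7.3 s, τ2 = 90.4 s, elastic proportion 56.8 %), used for
    parameter-recovery experiments."""
    return FibreModel(
        tau1=7.3, tau2=90.4, relax_offset_fraction=0.568,
        relax_fast_fraction=f_fast, noise_sd=noise_sd,
    )
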