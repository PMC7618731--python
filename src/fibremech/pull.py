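"""Continuous-pull analysis: rupture detection and stress–strain parameters.

From each fibre's engineering stress–strain curve five scalar parameters
are extracted:

* **rupture stress** — the maximal stress, at the detected rupture;
* **extensibility**  — the strain at rupture;
* **toughness**      — the strain-integral of stress up to rupture
  (energy per unit volume);
* **modulus 1**      — the low-strain slope (fit window ε ∈ [0.1, 1.5]);
* **modulus 2**      — the post-stiffening slope just before rupture
  (fit window the final 0.3 strain).

The stiffening ratio modulus2/modulus1 and the pointwise tangent modulus
(smoothed first derivative) characterise strain stiffening.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .mechanics import StressStrainCurve

log = logging.getLogger(__name__)

#: Minimum peak stress [Pa] for a drop to count as rupture. Set at the
#: 0.05 MPa level below which the signal is indistinguishable from
#: background fluctuations, so pure-noise traces never flag a rupture.
DEFAULT_MIN_PEAK_PA = 0.05e6


@dataclass
class PullParameters:
    """Scalar parameters of one ruptured fibre pull. NaN marks parameters
    that could not be determined; ``flags`` says why."""

    rupture_stress: float
    extensibility: float
    toughness: float
    modulus1: float
    modulus2: float
    flags: list[str] = field(default_factory=list)

    @property
    def stiffening_ratio(self) -> float:
        return self.modulus2 / self.modulus1


@dataclass
class TangentModulusCurve:
    strain: np.ndarray
    tangent: np.ndarray


def detect_rupture(
    curve: StressStrainCurve,
    drop_fraction: float = 0.5,
    window: int = 5,
    min_peak: float = DEFAULT_MIN_PEAK_PA,
) -> int | None:
    """Index of the last sample before the first rupture-like stress drop.

    A rupture is the first sample whose stress lies more than
    ``drop_fraction`` below the maximum of the preceding ``window``
    samples, provided that local maximum exceeds ``min_peak``. Returns
    the index of the last sample before the drop, or None when the curve
    never drops (absence of rupture is a valid outcome).
    """
    if len(curve) < 20:
        raise InvalidParameterError("need at least 20 samples to detect rupture")
    stress = curve.stress
    for i in range(1, len(stress)):
        lo = max(0, i - window)
        peak = float(np.max(stress[lo:i]))
        if peak > min_peak and stress[i] < (1.0 - drop_fraction) * peak:
            return i - 1
    return None


def extract_pull_parameters(
    curve: StressStrainCurve,
    eps_min1: float = 0.1,
    eps_max1: float = 1.5,
    delta2: float = 0.3,
    min_window_points: int = 5,
) -> PullParameters:
    """Extract the rupture/stiffening parameter set from one curve.

    Requires a detected rupture (``curve.rupture_index`` set, e.g. by
    :func:`detect_rupture`; fibres that slipped or ruptured before
    stiffening are excluded upstream). Toughness is the trapezoidal
    integral of stress over strain on [0, extensibility], with the origin
    (0, 0) prepended when the curve starts at nonzero strain. The modulus
    windows shrink (with a logged warning) when the curve is too short;
    a window with fewer than ``min_window_points`` samples yields NaN and
    a flag.
    """
    r = curve.rupture_index
    if r is None:
        raise InvalidParameterError(
            "curve has no rupture index; run detect_rupture (intact fibres are excluded)"
        )
    strain = curve.strain[: r + 1]
    stress = curve.stress[: r + 1]
    flags: list[str] = []

    extensibility = float(strain[r])
    rupture_stress = float(stress[r])

    xs, ys = strain, stress
    if xs[0] > 0:
        xs = np.concatenate([[0.0], xs])
        ys = np.concatenate([[0.0], ys])
    toughness = float(np.trapezoid(ys, xs))

    hi1 = min(eps_max1, extensibility - delta2)
    if hi1 < eps_max1:
        log.warning("modulus-1 window shrunk to [%.3g, %.3g]", eps_min1, hi1)
        flags.append("modulus1_window_shrunk")
    modulus1 = _window_slope(strain, stress, eps_min1, hi1, min_window_points)
    if np.isnan(modulus1):
        flags.append("modulus1_undefined")

    lo2 = max(extensibility - delta2, 0.0)
    modulus2 = _window_slope(strain, stress, lo2, extensibility, min_window_points)
    if np.isnan(modulus2):
        flags.append("modulus2_undefined")

    return PullParameters(
        rupture_stress=rupture_stress,
        extensibility=extensibility,
        toughness=toughness,
        modulus1=modulus1,
        modulus2=modulus2,
        flags=flags,
    )


def _window_slope(strain, stress, lo, hi, min_points) -> float:
    """Free-intercept least-squares slope of stress vs strain on [lo, hi]."""
    mask = (strain >= lo) & (strain <= hi)
    if int(mask.sum()) < min_points:
        return float("nan")
    return float(np.polyfit(strain[mask], stress[mask], 1)[0])


def tangent_modulus(curve: StressStrainCurve, window: int = 50) -> TangentModulusCurve:
    """Smoothed pointwise stiffness dσ/dε along the curve.

    Centred finite-difference derivative followed by a ``window``-sample
    adjacent average (the window shrinks symmetrically at the edges).
    The curve is truncated at rupture when a rupture index is set.
    """
    stop = len(curve) if curve.rupture_index is None else curve.rupture_index + 1
    strain = curve.strain[:stop]
    stress = curve.stress[:stop]
    if len(strain) < 2:
        raise InvalidParameterError("need at least 2 samples for a tangent modulus")
    if len(strain) < window:
        warnings.warn(
            f"only {len(strain)} samples for a {window}-sample smoothing window; shrinking",
            stacklevel=2,
        )
    deriv = np.gradient(stress, strain)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(deriv)])
    n = len(deriv)
    smoothed = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        smoothed[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return TangentModulusCurve(strain=strain, tangent=smoothed)


def row_statistics(
    curves: list[StressStrainCurve],
    strain_grid: np.ndarray | None = None,
    step: float = 0.01,
) -> pd.DataFrame:
    """Mean ± SEM stress across fibres on a common strain grid.

    At each grid strain the statistics pool only fibres still intact
    there (extensibility ≥ grid strain — ruptured fibres drop out, so
    ``n`` decreases along the grid). Stress is linearly interpolated
    between samples, with the origin prepended so low grid strains are
    covered. Returns columns ``strain, mean, sem, n``.
    """
    if not curves:
        raise InvalidParameterError("row statistics need at least one curve")
    limits = []
    for c in curves:
        stop = len(c) - 1 if c.rupture_index is None else c.rupture_index
        limits.append(c.strain[stop])
    if strain_grid is None:
        strain_grid = np.arange(0.0, max(limits) + step / 2, step)
    rows = []
    for g in strain_grid:
        vals = []
        for c, lim in zip(curves, limits):
            if lim >= g:
                stop = len(c) if c.rupture_index is None else c.rupture_index + 1
                xs = np.concatenate([[0.0], c.strain[:stop]])
                ys = np.concatenate([[0.0], c.stress[:stop]])
                vals.append(np.interp(g, xs, ys))
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        rows.append((float(g), mean, sem, n))
    return pd.DataFrame(rows, columns=["strain", "mean", "sem", "n"])
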