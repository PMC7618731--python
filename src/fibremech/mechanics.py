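"""Geometry and force/stress conversion for lateral fibre pulling.

A fibre is suspended across a well of width ``2a`` (10 μm wells, so
a = 5 μm) and pulled sideways at its midpoint by the cantilever tip. When
the tip has moved a lateral distance ``d`` from the fibre axis, each half
of the fibre spans ``L' = sqrt(a² + d²)`` and makes an angle ``α`` with
its original axis, with ``sin α = d/L'``. Engineering strain and the
fibre-axis force follow from elementary statics:

    ε = (L' − a)/a            F = L_v·k_e / (2·sin α)

where ``L_v`` is the lateral photodiode signal [V] and ``k_e`` [N/V] the
effective lateral spring constant. Engineering stress divides by the
ellipsoidal cross-section ``A = π·h_f·w_f/4`` measured on the ruptured
fibre ends by contact-mode imaging (fibre thinning during the pull cannot
be observed, so the cross-section is held fixed).

Two strain conventions are supported: ``geometric`` (above, the default)
and ``literal`` in which the recorded Y-position channel is read
directly as the half-length, ε = (l' − a)/a. The convention in use is
always recorded in downstream metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import GeometrySingularError, InvalidGeometryError, InvalidParameterError

Convention = Literal["geometric", "literal"]

#: Mask threshold for the pulling angle: sin α at the displacement where the
#: geometric strain reaches 0.02. Below this angle the 1/sin α factor
#: amplifies noise without bound and the force is treated as undefined.
DEFAULT_SIN_ALPHA_FLOOR = float(np.sqrt(1.0 - 1.0 / 1.02**2))


@dataclass
class WellGeometry:
    """Striated-substrate well geometry. ``half_width_um`` defaults to 5
    (10 μm wide wells)."""

    half_width_um: float = 5.0
    convention: Convention = "geometric"

    def __post_init__(self) -> None:
        if not (self.half_width_um > 0):
            raise InvalidGeometryError("well half-width must be > 0")
        if self.convention not in ("geometric", "literal"):
            raise InvalidParameterError(f"unknown strain convention {self.convention!r}")


@dataclass
class FibreCrossSection:
    """Elliptical fibre cross-section from the post-rupture contact scan.

    ``height`` and ``width`` in metres (width measured at half height to
    compensate tip broadening — done upstream; values are inputs here).
    """

    height: float
    width: float

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.width > 0):
            raise InvalidGeometryError("fibre height and width must be > 0")

    @property
    def area(self) -> float:
        """Cross-sectional area A = π·h·w/4 [m²]."""
        return np.pi * self.height * self.width / 4.0


def pull_geometry(d_um, geom: WellGeometry | None = None):
    """Strain and sin α from the cantilever Y-channel value(s) [μm].

    Under the ``geometric`` convention ``d_um`` is the lateral pull
    distance; under ``literal`` it is read as the instantaneous
    half-length ``l'`` and strain is (l' − a)/a. Returns ``(strain,
    sin_alpha)`` with the same shape as the input.
    """
    geom = geom or WellGeometry()
    d = np.asarray(d_um, dtype=float)
    if np.any(d < 0):
        raise InvalidParameterError("pull distance must be non-negative")
    a = geom.half_width_um
    if geom.convention == "geometric":
        half_len = np.sqrt(a**2 + d**2)
        strain = (half_len - a) / a
        with np.errstate(invalid="ignore"):
            sin_alpha = np.where(half_len > 0, d / half_len, 0.0)
    else:  # literal: channel value is the half-length itself
        half_len = d
        strain = (half_len - a) / a
        lateral = np.sqrt(np.maximum(half_len**2 - a**2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(half_len > 0, lateral / np.maximum(half_len, a), 0.0)
    if np.ndim(d_um) == 0:
        return float(strain), float(sin_alpha)
    return strain, sin_alpha


def force_from_lateral(
    lateral_V,
    ke: float,
    sin_alpha,
    sin_alpha_floor: float = DEFAULT_SIN_ALPHA_FLOOR,
):
    """Fibre-axis force F = L_v·k_e/(2·sin α) [N].

    Raises :class:`GeometrySingularError` if any ``sin_alpha`` is at or
    below the floor — at zero deflection angle the lateral signal carries
    no information about the axial force. (Inside trace processing such
    samples are masked instead; see :func:`trace_to_curve`.)
    """
    if not (ke > 0):
        raise InvalidParameterError("ke must be > 0")
    s = np.asarray(sin_alpha, dtype=float)
    if np.any(s <= sin_alpha_floor):
        raise GeometrySingularError(
            f"sin(alpha) at or below floor {sin_alpha_floor:.4g}; force undefined"
        )
    f = np.asarray(lateral_V, dtype=float) * ke / (2.0 * s)
    return float(f) if np.ndim(lateral_V) == 0 and np.ndim(sin_alpha) == 0 else f


def stress_from_force(force_N, cs: FibreCrossSection):
    """Engineering stress σ = F/A = 4F/(π·h_f·w_f) [Pa]."""
    sigma = np.asarray(force_N, dtype=float) / cs.area
    return float(sigma) if np.ndim(force_N) == 0 else sigma


@dataclass
class StressStrainCurve:
    """Per-sample engineering stress vs strain for one fibre pull.

    ``strain`` is non-decreasing up to ``rupture_index`` (when set).
    Low-angle samples (sin α below the floor) are dropped at construction
    time, so the curve starts at a small but nonzero strain.
    """

    strain: np.ndarray
    stress: np.ndarray
    rupture_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise InvalidParameterError("strain and stress must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return len(self.strain)


def trace_to_curve(
    y_um: np.ndarray,
    lateral_V: np.ndarray,
    ke: float,
    cross_section: FibreCrossSection,
    well: WellGeometry | None = None,
    sin_alpha_floor: float = DEFAULT_SIN_ALPHA_FLOOR,
    metadata: dict | None = None,
) -> StressStrainCurve:
    """Convert raw (Y-position, lateral volts) samples to a stress–strain curve.

    Samples whose pulling angle is at or below ``sin_alpha_floor`` are
    masked (dropped), not errored: they occur legitimately at the start of
    every pull. The applied convention and floor are recorded in the
    curve metadata.
    """
    well = well or WellGeometry()
    strain, sin_alpha = pull_geometry(np.asarray(y_um, float), well)
    keep = sin_alpha > sin_alpha_floor
    force = np.asarray(lateral_V, float)[keep] * ke / (2.0 * sin_alpha[keep])
    stress = force / cross_section.area
    md = dict(metadata or {})
    md.setdefault("strain_convention", well.convention)
    md.setdefault("sin_alpha_floor", sin_alpha_floor)
    md.setdefault("n_masked_low_angle", int(np.sum(~keep)))
    return StressStrainCurve(strain=strain[keep], stress=stress, metadata=md)
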