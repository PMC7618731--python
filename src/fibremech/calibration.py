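"""Cantilever calibration for lateral force spectroscopy.

A rectangular silicon cantilever of width ``w``, length ``l``, thickness
``t`` and tip height ``h`` is characterised by its normal spring constant
``kn`` (from a thermal tune, taken as given) and its inverse optical lever
sensitivity ``InvOLS`` (slope of a deflection-vs-distance contact curve on
a hard surface). From these, the effective *lateral* spring constant
``k_e`` [N/V] converts lateral photodiode volts directly into newtons of
lateral force at the tip.

``k_e`` is the product of the lateral beam stiffness

    k_l = G·w·t³ / (3·l·(h + t/2))          [N/m]

and the lateral optical sensitivity

    S_l = E·(h + t/2)·InvOLS / (2·G·l)      [m/V]

in which both the silicon shear modulus ``G`` and the lever arm
``(h + t/2)`` cancel, leaving

    k_e = E·w·t³·InvOLS / (6·l²)            [N/V]

The cantilever thickness is recovered from the normal spring constant via
the rectangular-beam relation ``kn = E·w·t³/(4·l³)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateContactError,
    InvalidParameterError,
    MissingCalibrationError,
)

#: Elastic modulus of single-crystal silicon along a typical beam axis [Pa].
E_SILICON = 169e9
#: Shear modulus of silicon [Pa]. Cancels out of k_e; kept for the factored form.
G_SILICON = 50.9e9


@dataclass
class Cantilever:
    """Geometry and calibration state of one rectangular cantilever.

    All lengths in metres, moduli in pascal. ``thickness``, ``invols`` and
    ``ke`` may start unset and are filled in by :func:`calibrate`.
    """

    width: float
    length: float
    tip_height: float
    kn: float
    E_si: float = E_SILICON
    G_si: float = G_SILICON
    thickness: float | None = None
    invols: float | None = None
    ke: float | None = None

    def __post_init__(self) -> None:
        for name in ("width", "length", "tip_height", "kn", "E_si", "G_si"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidParameterError(f"cantilever {name} must be > 0, got {v!r}")
        if self.thickness is not None:
            if not (self.thickness > 0):
                raise InvalidParameterError("thickness must be > 0")
            if not (self.thickness < self.tip_height):
                raise InvalidParameterError(
                    "beam thickness must be smaller than the tip height"
                )


@dataclass
class ContactCurve:
    """Deflection-vs-distance curve recorded pressing the tip on glass.

    ``distance`` [m] and ``deflection`` [V] must have equal length;
    ``contact_window`` is the (start, stop) index range of the in-contact
    linear region (half-open, like a slice).
    """

    distance: np.ndarray
    deflection: np.ndarray
    contact_window: tuple[int, int]

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.distance.shape != self.deflection.shape or self.distance.ndim != 1:
            raise InvalidParameterError("distance and deflection must be equal-length 1-D arrays")
        i, j = self.contact_window
        if not (0 <= i < j <= len(self.distance)):
            raise InvalidParameterError("contact_window must be a non-empty index range")


def cantilever_thickness(kn: float, length: float, E_si: float, width: float) -> float:
    """Beam thickness [m] from the normal spring constant.

    Inverts ``kn = E·w·t³/(4·l³)``:  t = (4·kn·l³/(E·w))^(1/3).
    """
    for name, v in (("kn", kn), ("length", length), ("E_si", E_si), ("width", width)):
        if not (v > 0):
            raise InvalidParameterError(f"{name} must be > 0, got {v!r}")
    return float(np.cbrt(4.0 * kn * length**3 / (E_si * width)))


def detect_contact_window(
    distance: np.ndarray, deflection: np.ndarray, r2_threshold: float = 0.999
) -> tuple[int, int]:
    """Longest suffix of the curve whose linear fit has R² ≥ ``r2_threshold``.

    Contact curves approach the surface first (flat baseline) and end in
    the linear in-contact ramp, so the contact region is a suffix.
    """
    distance = np.asarray(distance, float)
    deflection = np.asarray(deflection, float)
    n = len(distance)
    best: tuple[int, int] | None = None
    for start in range(n - 2, -1, -1):
        x = distance[start:]
        y = deflection[start:]
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            break
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= r2_threshold:
            best = (start, n)
        else:
            break
    if best is None:
        raise DegenerateContactError("no linear suffix found at the requested R² threshold")
    return best


def fit_invols(curve: ContactCurve, slope_floor: float = 1e-3) -> float:
    """Inverse optical lever sensitivity [m/V] from a contact curve.

    Least-squares slope of deflection [V] vs distance [m] over the contact
    window has units V/m; InvOLS is its reciprocal, sign-normalised to be
    positive. ``slope_floor`` [V/m] guards against degenerate flat segments.
    """
    i, j = curve.contact_window
    if j - i < 2:
        raise InvalidParameterError("contact window must contain at least 2 points")
    x = curve.distance[i:j]
    y = curve.deflection[i:j]
    slope = float(np.polyfit(x, y, 1)[0])
    if abs(slope) < slope_floor:
        raise DegenerateContactError(
            f"contact slope {slope:.3g} V/m is below the floor {slope_floor:.3g}"
        )
    return 1.0 / abs(slope)


def lateral_stiffness(c: Cantilever) -> float:
    """Lateral beam stiffness k_l = G·w·t³/(3·l·(h + t/2)) [N/m].

    Intermediate quantity only: both G and the lever arm cancel in k_e,
    so k_l on its own is not calibration-authoritative.
    """
    t = _require(c.thickness, "thickness")
    return c.G_si * c.width * t**3 / (3.0 * c.length * (c.tip_height + t / 2.0))


def lateral_sensitivity(c: Cantilever) -> float:
    """Lateral optical sensitivity S_l = E·(h + t/2)·InvOLS/(2·G·l) [m/V]."""
    t = _require(c.thickness, "thickness")
    invols = _require(c.invols, "invols")
    return c.E_si * (c.tip_height + t / 2.0) * invols / (2.0 * c.G_si * c.length)


def effective_spring_constant(c: Cantilever) -> float:
    """Effective lateral spring constant k_e = k_l·S_l [N/V].

    Evaluates the reduced form E·w·t³·InvOLS/(6·l²); the shear modulus G
    cancels exactly, so k_e is independent of G_si.
    """
    t = _require(c.thickness, "thickness")
    invols = _require(c.invols, "invols")
    return c.E_si * c.width * t**3 * invols / (6.0 * c.length**2)


def calibrate(c: Cantilever, contact_curve: ContactCurve | None = None) -> Cantilever:
    """Return a copy of ``c`` with thickness, InvOLS and k_e filled in.

    Thickness is derived from ``kn`` if unset; InvOLS is fitted from
    ``contact_curve`` if unset.
    """
    t = c.thickness
    if t is None:
        t = cantilever_thickness(c.kn, c.length, c.E_si, c.width)
    invols = c.invols
    if invols is None:
        if contact_curve is None:
            raise MissingCalibrationError("InvOLS not set and no contact curve supplied")
        invols = fit_invols(contact_curve)
    out = replace(c, thickness=t, invols=invols)
    return replace(out, ke=effective_spring_constant(out))


def _require(value: float | None, name: str) -> float:
    if value is None or not (value > 0):
        raise MissingCalibrationError(f"cantilever {name} is not set or non-positive")
    return value
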