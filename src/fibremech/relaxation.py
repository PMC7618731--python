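"""Stress-relaxation (hold-phase) analysis.

During an incremental pull the fibre is held at fixed strain after each
2 μm step and the stress decays over the 2-minute hold. The decay is
decomposed into an offset plus two exponentials,

    σ(t) = σ0 + σ1·e^(−t/τ1) + σ2·e^(−t/τ2),        τ1 < τ2,

the generalized Kelvin picture: a spring (relaxed modulus E0 = σ0/ε) in
parallel with two Maxwell arms, a fast one (E1 = σ1/ε, time constant τ1)
and a slow one (E2 = σ2/ε, τ2). Each arm's viscous modulus is μ = E·τ.

Derived ratio metrics — the purely elastic proportion E0/Emax (equal to
σ0/σmax) and the relative contribution of fast relaxation E1/(E1+E2) —
are independent of the strain, the spring-constant calibration and the
cross-section, and so are free of the dominant measurement errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls
from scipy.signal import medfilt

from .errors import InvalidParameterError
from .mechanics import FibreCrossSection, WellGeometry, pull_geometry
from .trace_io import RawTrace, segment_phases, segments


@dataclass
class RelaxationFit:
    """Offset-plus-two-exponential decomposition of one hold phase."""

    strain: float
    sigma_max: float
    sigma0: float
    sigma1: float
    tau1: float
    sigma2: float
    tau2: float
    residual_norm: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        """Converged, non-degenerate fits enter group summaries."""
        return self.converged and not self.flags

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return (
            self.sigma0
            + self.sigma1 * np.exp(-t / self.tau1)
            + self.sigma2 * np.exp(-t / self.tau2)
        )


@dataclass
class ViscoelasticModuli:
    """Generalized-Kelvin moduli derived from one relaxation fit.

    ``elastic_proportion`` is E0/Emax in percent; ``fast_contribution``
    is E1/(E1+E2) as a fraction; μi = Ei·τi in Pa·s.
    """

    E0: float
    E1: float
    E2: float
    tau1: float
    tau2: float

    @property
    def Emax(self) -> float:
        return self.E0 + self.E1 + self.E2

    @property
    def elastic_proportion(self) -> float:
        return 100.0 * self.E0 / self.Emax

    @property
    def fast_contribution(self) -> float:
        decay = self.E1 + self.E2
        return float("nan") if decay == 0 else self.E1 / decay

    @property
    def mu1(self) -> float:
        return self.E1 * self.tau1

    @property
    def mu2(self) -> float:
        return self.E2 * self.tau2


def fit_double_exponential(
    time: np.ndarray,
    stress: np.ndarray,
    strain: float = float("nan"),
    prefilter: bool = True,
    tau_ratio_floor: float = 1.5,
    tol: float = 1e-10,
) -> RelaxationFit:
    """Bounded nonlinear least-squares fit of σ(t) = σ0 + σ1·e^(−t/τ1) + σ2·e^(−t/τ2).

    Time is re-zeroed at the first hold sample. Initialization: σ0 from
    the mean of the final 10 % of the hold; τ2 from the log-linear slope
    of (σ − σ0) over the last half; τ1 = τ2/10; amplitudes by
    non-negative linear least squares. All parameters are bounded ≥ 0 and
    the two components are sorted so τ1 < τ2 after the fit. σ_max is the
    first sample after an optional 3-sample median prefilter that
    suppresses single-sample spikes.

    Degenerate inputs (constant stress) return σ1 = σ2 = 0 with a
    ``degenerate`` flag; fits whose time constants fail τ2/τ1 ≥
    ``tau_ratio_floor`` are flagged ``single_exponential_like``. Flagged
    fits are excluded from group summaries (the exclusion is counted by
    the callers).
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(stress, dtype=float)
    if len(t) < 50:
        raise InvalidParameterError("hold too short: need at least 50 samples")
    t = t - t[0]
    if t[-1] < 10.0:
        raise InvalidParameterError("hold too short: need at least 10 s")
    y_filt = medfilt(y, 3) if prefilter else y
    sigma_max = float(y_filt[0])

    scale = float(np.max(np.abs(y))) or 1.0
    if float(np.ptp(y)) <= 1e-12 * scale:
        return RelaxationFit(
            strain=strain, sigma_max=sigma_max,
            sigma0=float(np.mean(y)), sigma1=0.0, tau1=1.0, sigma2=0.0, tau2=10.0,
            residual_norm=0.0, converged=True, flags=["degenerate"],
        )

    T = t[-1]

    def resid(p):
        s0, s1, lt1, s2, lt2 = p
        return s0 + s1 * np.exp(-t * np.exp(-lt1)) + s2 * np.exp(-t * np.exp(-lt2)) - y

    def solve(p0):
        # log-parameterized time constants keep them positive within bounds
        x0 = np.array([p0[0], p0[1], np.log(p0[2]), p0[3], np.log(p0[4])])
        return least_squares(
            resid, x0,
            bounds=([0, 0, np.log(1e-3), 0, np.log(1e-3)],
                    [np.inf, np.inf, np.log(1e3 * T), np.inf, np.log(1e3 * T)]),
            xtol=tol, ftol=tol, gtol=tol, max_nfev=2000,
        )

    # the analytic starting point can land in a merged single-exponential
    # local minimum on noisy holds, so a coarse (tau1, tau2) grid scan with
    # non-negative amplitudes provides a second start; keep the better fit
    sol = solve(_initial_guess(t, y))
    sol_grid = solve(_grid_guess(t, y))
    if sol_grid.cost < sol.cost:
        sol = sol_grid
    s0, s1, lt1, s2, lt2 = sol.x
    tau1, tau2 = float(np.exp(lt1)), float(np.exp(lt2))
    if tau1 > tau2:
        s1, s2 = s2, s1
        tau1, tau2 = tau2, tau1
    flags: list[str] = []
    if s1 + s2 <= 1e-9 * max(s0, scale):
        flags.append("degenerate")
    elif tau2 / tau1 < tau_ratio_floor:
        flags.append("single_exponential_like")
    return RelaxationFit(
        strain=strain, sigma_max=sigma_max,
        sigma0=float(s0), sigma1=float(s1), tau1=tau1,
        sigma2=float(s2), tau2=tau2,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success), flags=flags,
    )


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """(σ0, σ1, τ1, σ2, τ2) starting point for the nonlinear fit."""
    n = len(t)
    T = t[-1]
    s0 = float(np.mean(y[-max(n // 10, 2):]))
    half = y[n // 2:] - s0
    th = t[n // 2:]
    pos = half > 0
    if pos.sum() >= 5:
        slope = np.polyfit(th[pos], np.log(half[pos]), 1)[0]
        tau2 = -1.0 / slope if slope < 0 else T
    else:
        tau2 = T / 2.0
    tau2 = float(np.clip(tau2, 1e-2, 100 * T))
    tau1 = tau2 / 10.0
    design = np.column_stack([np.ones_like(t), np.exp(-t / tau1), np.exp(-t / tau2)])
    amps, _ = nnls(design, y)
    return float(amps[0]), float(amps[1]), tau1, float(amps[2]), tau2


def _grid_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Best (σ0, σ1, τ1, σ2, τ2) over a coarse log-spaced time-constant grid.

    For each admissible (τ1, τ2) pair the amplitudes are the exact
    non-negative linear least-squares solution, so the scan only has to
    get the time constants roughly right.
    """
    T = t[-1]
    taus = np.geomspace(T / 400.0, 2.0 * T, 10)
    best = None
    for i, tau1 in enumerate(taus):
        e1 = np.exp(-t / tau1)
        for tau2 in taus[i + 1:]:
            if tau2 < 3.0 * tau1:
                continue
            design = np.column_stack([np.ones_like(t), e1, np.exp(-t / tau2)])
            amps, rnorm = nnls(design, y)
            if best is None or rnorm < best[0]:
                best = (rnorm, float(amps[0]), float(amps[1]), float(tau1),
                        float(amps[2]), float(tau2))
    assert best is not None
    return best[1:]


def derive_moduli(fit: RelaxationFit, strain: float | None = None) -> ViscoelasticModuli:
    """Convert a fitted stress decomposition into generalized-Kelvin moduli.

    Each modulus is the corresponding stress amplitude over the hold
    strain, Ei = σi/ε; Emax = E0 + E1 + E2 reconstructs the t = 0 modulus.
    The ratio metrics are strain-independent (σ0/σmax needs no ε at all).
    """
    eps = fit.strain if strain is None else strain
    if not (eps > 0):
        raise InvalidParameterError(f"hold strain must be > 0, got {eps!r}")
    if not fit.converged:
        raise InvalidParameterError("cannot derive moduli from a non-converged fit")
    return ViscoelasticModuli(
        E0=fit.sigma0 / eps, E1=fit.sigma1 / eps, E2=fit.sigma2 / eps,
        tau1=fit.tau1, tau2=fit.tau2,
    )


METRICS = ("tau1", "tau2", "elastic_proportion", "fast_contribution", "mu1", "mu2")


def bin_by_strain(fits: list[RelaxationFit], width: float = 0.5) -> pd.DataFrame:
    """Mean ± SEM of each relaxation metric in strain bins [0, w), [w, 2w), …

    Flagged or non-converged fits are excluded (and counted in
    ``n_excluded`` on the returned frame's attrs). Bins whose strain is
    below 0.5 carry a ``low_strain_caveat`` flag: there the stress change
    over a hold approaches the sensitivity limit and fitted parameters
    are least certain.
    """
    usable = [f for f in fits if f.usable and f.strain > 0]
    n_excluded = len(fits) - len(usable)
    rows = []
    if usable:
        values = {m: [] for m in METRICS}
        strains = []
        for f in usable:
            m = derive_moduli(f)
            strains.append(f.strain)
            values["tau1"].append(m.tau1)
            values["tau2"].append(m.tau2)
            values["elastic_proportion"].append(m.elastic_proportion)
            values["fast_contribution"].append(m.fast_contribution)
            values["mu1"].append(m.mu1)
            values["mu2"].append(m.mu2)
        strains = np.asarray(strains)
        n_bins = int(np.floor(strains.max() / width)) + 1
        for b in range(n_bins):
            lo, hi = b * width, (b + 1) * width
            mask = (strains >= lo) & (strains < hi)
            row = {"bin_lo": lo, "bin_hi": hi, "n": int(mask.sum()),
                   "low_strain_caveat": hi <= 0.5}
            for m in METRICS:
                vals = np.asarray(values[m])[mask]
                row[f"{m}_mean"] = float(np.mean(vals)) if row["n"] else float("nan")
                row[f"{m}_sem"] = (
                    float(np.std(vals, ddof=1) / np.sqrt(row["n"])) if row["n"] >= 2 else float("nan")
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = n_excluded
    return df


def analyze_relaxation_trace(
    trace: RawTrace,
    ke: float,
    cross_section: FibreCrossSection,
    well: WellGeometry | None = None,
    min_hold_s: float = 10.0,
    **fit_kwargs,
) -> list[RelaxationFit]:
    """Segment an incremental-pull trace and fit every hold window.

    Converts each hold's lateral signal to stress at the (constant) hold
    strain, then runs :func:`fit_double_exponential`. Holds shorter than
    ``min_hold_s`` are skipped. Each hold window is extended backwards
    over trailing pull samples whose Y-position already equals the hold
    position: the centred-difference velocity smears the phase boundary
    by a sample, but the decay clock starts at the true peak.
    """
    well = well or WellGeometry()
    if trace.phase is None:
        trace = segment_phases(trace, require_holds=True)
    fits: list[RelaxationFit] = []
    for phase, i, j in segments(trace):
        if phase != "hold" or trace.time[j - 1] - trace.time[i] < min_hold_s:
            continue
        d = float(np.median(trace.y_um[i:j]))
        while i > 0 and abs(trace.y_um[i - 1] - d) < 1e-3:
            i -= 1
        strain, sin_alpha = pull_geometry(d, well)
        if sin_alpha <= 0:
            continue
        stress = trace.lateral_V[i:j] * ke / (2.0 * sin_alpha) / cross_section.area
        fits.append(
            fit_double_exponential(trace.time[i:j], stress, strain=strain, **fit_kwargs)
        )
    return fits
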