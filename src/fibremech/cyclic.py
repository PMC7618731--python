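"""Cyclic-pulling analysis: drift correction, permanent elongation and hysteresis.

The cyclic protocol pulls a fibre three times to strain 1, three times to
strain 2 and three times to strain 3, returning to zero strain after each
pull. Three per-cycle metrics quantify recovery and dissipation:

* **characteristic strain** — the strain at which the pull stress first
  exceeds 0.05 MPa, the level distinguishable from background
  fluctuations; it tracks the permanent elongation left by earlier cycles;
* **Loss%** — within each strain step, 100·(1 − AUC_i/AUC_1): how much of
  the first pull's work has been lost by cycle i (the retained ratio
  AUC_i/AUC_1·100 is reported alongside);
* **hysteresis area%** — 100·(AUC_pull − AUC_release)/AUC_pull per cycle,
  the dissipated fraction of the pull work.

A slow drift of the lateral signal (observed at 0.015–0.293 V against
2.26–8.02 V of fibre signal) is negligible for single pulls but would
contaminate permanent-deformation estimates, so cyclic traces are first
baseline-corrected using the zero-strain dwells between cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BaselineError, InvalidParameterError
from .mechanics import (
    DEFAULT_SIN_ALPHA_FLOOR,
    FibreCrossSection,
    WellGeometry,
    pull_geometry,
)
from .trace_io import RawTrace, segment_phases, segments

log = logging.getLogger(__name__)

#: Stress level distinguishable from background fluctuations [Pa].
CHARACTERISTIC_THRESHOLD_PA = 0.05e6

#: Drift magnitudes observed on the instrument [V]; corrections outside
#: this band trigger a QC warning.
DRIFT_QC_BAND_V = (0.015, 0.293)


@dataclass
class Cycle:
    """One pull/release cycle as stress-vs-strain branches."""

    index_in_step: int
    target_strain: float
    pull_strain: np.ndarray
    pull_stress: np.ndarray
    release_strain: np.ndarray
    release_stress: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def reached_strain(self) -> float:
        return float(np.max(self.pull_strain)) if len(self.pull_strain) else float("nan")

    @property
    def auc_pull(self) -> float:
        return _branch_area(self.pull_strain, self.pull_stress)

    @property
    def auc_release(self) -> float:
        return _branch_area(self.release_strain, self.release_stress)


def _branch_area(strain: np.ndarray, stress: np.ndarray) -> float:
    """Trapezoidal area under one branch, over ascending strain, with
    non-positive-stress samples excluded (release tails can dip to zero)."""
    if len(strain) < 2:
        return 0.0
    order = np.argsort(strain, kind="stable")
    x, y = strain[order], stress[order]
    keep = y > 0
    if keep.sum() < 2:
        return 0.0
    return float(np.trapezoid(y[keep], x[keep]))


def correct_drift(
    trace: RawTrace,
    home_tol_um: float = 0.1,
    min_dwell_s: float = 1.0,
) -> RawTrace:
    """Subtract a piecewise-linear lateral baseline anchored at zero-strain dwells.

    The baseline interpolates the median lateral value of each dwell
    (|y − y_home| < ``home_tol_um`` for at least ``min_dwell_s``), held
    constant beyond the first/last dwell. After correction the dwell
    medians are ≈ 0, so the operation is idempotent. The correction
    magnitude is logged and checked against the drift scale seen on the
    instrument (QC only, never an error).
    """
    if trace.phase is None:
        trace = segment_phases(trace)
    anchors_t, anchors_v = [], []
    chunk = max(int(round(5.0 * trace.sample_rate)), 2)  # ≤5 s anchor spacing
    for phase, i, j in segments(trace):
        if phase != "idle":
            continue
        if trace.time[j - 1] - trace.time[i] < min_dwell_s:
            continue
        # long dwells get several anchors so the baseline can bend inside them
        for k in range(i, j, chunk):
            stop = min(k + chunk, j)
            anchors_t.append(float(np.mean(trace.time[k:stop])))
            anchors_v.append(float(np.median(trace.lateral_V[k:stop])))
    if not anchors_t:
        raise BaselineError("no zero-strain dwell intervals found; cannot estimate baseline")
    baseline = np.interp(trace.time, anchors_t, anchors_v)
    if len(anchors_t) >= 2:
        # extend the outermost anchor slopes instead of holding flat, so a
        # steady drift is also removed before the first / after the last dwell
        t0, t1 = anchors_t[0], anchors_t[1]
        head = trace.time < t0
        baseline[head] = anchors_v[0] + (anchors_v[1] - anchors_v[0]) / (t1 - t0) * (
            trace.time[head] - t0
        )
        t0, t1 = anchors_t[-2], anchors_t[-1]
        tail = trace.time > t1
        baseline[tail] = anchors_v[-1] + (anchors_v[-1] - anchors_v[-2]) / (t1 - t0) * (
            trace.time[tail] - t1
        )
    magnitude = float(np.ptp(anchors_v)) if len(anchors_v) > 1 else abs(anchors_v[0])
    lo, hi = DRIFT_QC_BAND_V
    if magnitude > hi:
        log.warning("drift correction %.3g V exceeds the expected band %s", magnitude, DRIFT_QC_BAND_V)
    else:
        log.info("drift correction magnitude %.3g V", magnitude)
    md = dict(trace.metadata)
    md["drift_correction_V"] = magnitude
    return RawTrace(
        time=trace.time, y_um=trace.y_um,
        lateral_V=trace.lateral_V - baseline,
        sample_rate=trace.sample_rate, phase=trace.phase, metadata=md,
    )


def split_cycles(
    trace: RawTrace,
    ke: float,
    cross_section: FibreCrossSection,
    well: WellGeometry | None = None,
    sin_alpha_floor: float = DEFAULT_SIN_ALPHA_FLOOR,
    step_tolerance: float = 0.3,
) -> list[Cycle]:
    """Split a segmented cyclic trace into pull/release cycles.

    Consecutive (pull, release) segment pairs form cycles; cycles are
    grouped into strain steps by their reached strain (a new step starts
    when the peak strain exceeds the step's first peak by more than
    ``step_tolerance``). Samples below the angle floor are dropped from
    both branches.
    """
    well = well or WellGeometry()
    if trace.phase is None:
        trace = segment_phases(trace)

    def branch(i, j):
        strain, sin_alpha = pull_geometry(trace.y_um[i:j], well)
        keep = sin_alpha > sin_alpha_floor
        stress = (
            trace.lateral_V[i:j][keep] * ke / (2.0 * sin_alpha[keep]) / cross_section.area
        )
        return strain[keep], stress

    segs = segments(trace)
    cycles: list[Cycle] = []
    step_peak: float | None = None
    idx_in_step = 0
    k = 0
    while k < len(segs):
        phase, i, j = segs[k]
        if phase != "pull":
            k += 1
            continue
        ps, pv = branch(i, j)
        rs = rv = np.array([])
        k += 1
        # the centred-difference velocity is ~0 for a sample or two at the
        # turnaround, producing a spurious short hold between the branches
        while k < len(segs) and segs[k][0] in ("hold", "idle") and segs[k][2] - segs[k][1] <= 3:
            k += 1
        if k < len(segs) and segs[k][0] == "release":
            _, ri, rj = segs[k]
            rs, rv = branch(ri, rj)
            k += 1
        peak = float(np.max(ps)) if len(ps) else 0.0
        if step_peak is None or peak > step_peak + step_tolerance:
            step_peak = peak
            idx_in_step = 1
        else:
            idx_in_step += 1
        cycles.append(
            Cycle(
                index_in_step=idx_in_step,
                target_strain=step_peak,
                pull_strain=ps, pull_stress=pv,
                release_strain=rs, release_stress=rv,
            )
        )
    return cycles


def characteristic_strain(
    cycle: Cycle, threshold: float = CHARACTERISTIC_THRESHOLD_PA
) -> float:
    """Smallest strain at which the pull stress crosses ``threshold``.

    Linearly interpolated between the bracketing samples; NaN when the
    threshold is never reached.
    """
    strain, stress = cycle.pull_strain, cycle.pull_stress
    if len(strain) == 0:
        raise InvalidParameterError("cycle has an empty pull branch")
    above = np.nonzero(stress >= threshold)[0]
    if len(above) == 0:
        return float("nan")
    i = int(above[0])
    if i == 0:
        return float(strain[0])
    x0, x1 = strain[i - 1], strain[i]
    y0, y1 = stress[i - 1], stress[i]
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))


def loss_percent(step_cycles: list[Cycle]) -> pd.DataFrame:
    """Energy loss of cycles 2, 3… relative to the first pull of a strain step.

    Both conventions are reported: ``retained_percent`` = AUC_i/AUC_1·100
    (the ratio itself) and ``loss_percent`` = (1 − AUC_i/AUC_1)·100, the
    headline column (how much of the first pull's work is gone). NaN with
    a flag when the first pull has zero area.
    """
    if not step_cycles:
        raise InvalidParameterError("strain step has no cycles")
    auc1 = step_cycles[0].auc_pull
    rows = []
    for c in step_cycles[1:]:
        if auc1 > 0:
            retained = 100.0 * c.auc_pull / auc1
            rows.append((c.index_in_step, retained, 100.0 - retained, ""))
        else:
            rows.append((c.index_in_step, float("nan"), float("nan"), "zero_first_pull_area"))
    return pd.DataFrame(
        rows, columns=["cycle", "retained_percent", "loss_percent", "flag"]
    )


def hysteresis_percent(cycle: Cycle) -> float:
    """Dissipated fraction of the pull work, 100·(AUC_pull − AUC_release)/AUC_pull.

    NaN when the pull area is zero.
    """
    ap = cycle.auc_pull
    if ap <= 0:
        return float("nan")
    return 100.0 * (ap - cycle.auc_release) / ap


def analyze_cyclic_trace(
    trace: RawTrace,
    ke: float,
    cross_section: FibreCrossSection,
    well: WellGeometry | None = None,
    drift_correct: bool = True,
    threshold: float = CHARACTERISTIC_THRESHOLD_PA,
) -> pd.DataFrame:
    """Full cyclic pipeline: drift-correct, split cycles, compute all metrics.

    Returns one row per cycle with columns ``step, cycle, reached_strain,
    characteristic_strain, retained_percent, loss_percent,
    hysteresis_percent`` (loss columns are NaN for each step's first cycle,
    whose pull is the reference).
    """
    if drift_correct:
        trace = correct_drift(trace)
    cycles = split_cycles(trace, ke, cross_section, well)
    rows = []
    step_id = 0
    step_start = 0
    for n, c in enumerate(cycles):
        if c.index_in_step == 1:
            step_id += 1
            step_start = n
        step_cycles = cycles[step_start: n + 1]
        if c.index_in_step > 1:
            lp = loss_percent(step_cycles).iloc[-1]
            retained, loss = lp["retained_percent"], lp["loss_percent"]
        else:
            retained = loss = float("nan")
        rows.append(
            {
                "step": step_id,
                "cycle": c.index_in_step,
                "reached_strain": c.reached_strain,
                "characteristic_strain": characteristic_strain(c, threshold),
                "retained_percent": retained,
                "loss_percent": loss,
                "hysteresis_percent": hysteresis_percent(c),
            }
        )
    return pd.DataFrame(rows)
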