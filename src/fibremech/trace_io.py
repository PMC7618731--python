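"""Reading, writing and phase segmentation of raw instrument traces.

A trace is the sampled record of one fibre experiment: time [s], the
commanded cantilever Y-position [μm] (lateral pull distance) and the
lateral photodiode signal [V], nominally at 10 samples/s. On disk a trace
is a plain CSV with columns ``time_s, y_um, lateral_V[, phase]`` preceded
by ``# key: value`` metadata comment lines.

Phase segmentation labels every sample as one of

* ``pull``    — Y moving away from home at the pull speed (+0.1 μm/s),
* ``release`` — Y moving back toward home,
* ``hold``    — Y stationary away from home (stress-relaxation windows),
* ``idle``    — Y stationary at the home (zero-strain) position.

Holds are detected by a velocity floor of 0.01 μm/s, 10 % of the nominal
pull speed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError, SegmentationError

REQUIRED_COLUMNS = ("time_s", "y_um", "lateral_V")

PHASES = ("pull", "hold", "release", "idle")


@dataclass
class RawTrace:
    """One sampled instrument trace with optional per-sample phase labels."""

    time: np.ndarray
    y_um: np.ndarray
    lateral_V: np.ndarray
    sample_rate: float = 10.0
    phase: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.lateral_V = np.asarray(self.lateral_V, dtype=float)
        n = len(self.time)
        if len(self.y_um) != n or len(self.lateral_V) != n:
            raise DataError("time, y_um and lateral_V must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise DataError("time must be strictly increasing")
        if not (self.sample_rate > 0):
            raise DataError("sample_rate must be > 0")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if len(self.phase) != n:
                raise DataError("phase labels must match trace length")

    def __len__(self) -> int:
        return len(self.time)


def write_trace(path: str | Path, trace: RawTrace) -> None:
    """Write a trace as CSV with a ``# key: value`` metadata header block."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.time, "y_um": trace.y_um, "lateral_V": trace.lateral_V}
    )
    if trace.phase is not None:
        df["phase"] = trace.phase
    buf = io.StringIO()
    buf.write(f"# sample_rate: {trace.sample_rate!r}\n")
    for k, v in trace.metadata.items():
        buf.write(f"# {k}: {v!r}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_trace(path: str | Path) -> RawTrace:
    """Read a trace CSV, validating schema and time monotonicity.

    Sampling gaps larger than twice the nominal interval are counted and
    reported in the trace metadata under ``n_time_gaps``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"trace file not found: {path}")
    metadata: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            try:
                metadata[key.strip()] = eval(value.strip(), {"__builtins__": {}})  # noqa: S307 - repr roundtrip
            except Exception:
                metadata[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trace file {path} is missing required column {col!r}")
    sample_rate = float(metadata.pop("sample_rate", 10.0))
    time = df["time_s"].to_numpy(float)
    if len(time) >= 2:
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise DataError(f"non-monotone time in {path}")
        metadata["n_time_gaps"] = int(np.sum(dt > 2.0 / sample_rate))
    phase = df["phase"].to_numpy(object) if "phase" in df.columns else None
    return RawTrace(
        time=time,
        y_um=df["y_um"].to_numpy(float),
        lateral_V=df["lateral_V"].to_numpy(float),
        sample_rate=sample_rate,
        phase=phase,
        metadata=metadata,
    )


def segment_phases(
    trace: RawTrace,
    pull_speed_um_s: float = 0.1,
    velocity_floor_um_s: float = 0.01,
    home_tol_um: float = 0.1,
    require_holds: bool = False,
) -> RawTrace:
    """Label every sample of ``trace`` with its protocol phase.

    Velocity is the centred finite difference of Y-position; samples with
    |v| below ``velocity_floor_um_s`` are stationary — ``idle`` if within
    ``home_tol_um`` of the home (initial) position, ``hold`` otherwise.
    Moving samples are ``pull`` (v > 0) or ``release`` (v < 0).
    Set ``require_holds`` for incremental protocols, where finding no hold
    window is a segmentation failure.
    """
    if len(trace) < 2:
        raise SegmentationError("trace too short to segment")
    v = np.gradient(trace.y_um, trace.time)
    stationary = np.abs(v) < velocity_floor_um_s
    home = np.abs(trace.y_um - trace.y_um[0]) < home_tol_um
    phase = np.empty(len(trace), dtype=object)
    phase[~stationary & (v > 0)] = "pull"
    phase[~stationary & (v < 0)] = "release"
    phase[stationary & home] = "idle"
    phase[stationary & ~home] = "hold"
    # centred differences smear boundaries by one sample; snap boundary
    # samples to the following run's label where the neighbour agrees
    labelled = RawTrace(
        time=trace.time,
        y_um=trace.y_um,
        lateral_V=trace.lateral_V,
        sample_rate=trace.sample_rate,
        phase=phase,
        metadata=dict(trace.metadata),
    )
    if require_holds and not any(p == "hold" for p in phase):
        raise SegmentationError("incremental protocol expected but no hold windows found")
    return labelled


def segments(trace: RawTrace) -> list[tuple[str, int, int]]:
    """Contiguous runs of equal phase label as ``(phase, start, stop)``
    half-open index ranges covering the whole trace."""
    if trace.phase is None:
        raise SegmentationError("trace has no phase labels; run segment_phases first")
    out: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(trace) + 1):
        if i == len(trace) or trace.phase[i] != trace.phase[start]:
            out.append((str(trace.phase[start]), start, i))
            start = i
    return out
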