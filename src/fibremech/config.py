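"""Run-configuration loading (YAML/JSON) for calibration and fibre geometry.

A run config has two blocks::

    calibration:
      w: 32.5e-6        # beam width [m]
      l: 350e-6         # beam length [m]
      h: 15e-6          # tip height [m]
      kn: 0.03          # thermal normal spring constant [N/m]
      E_si: 169e9       # optional, defaults to silicon
      G_si: 50.9e9      # optional; cancels out of k_e
      t: null           # beam thickness [m]; derived from kn when absent
      invols: 5.0e-8    # [m/V]; or instead:
      contact_curve: contact.csv   # two columns: distance_m, deflection_V
    fibre:
      height_nm: 180    # from the post-rupture contact-mode scan
      width_nm: 180     # width at half height
    well:
      half_width_um: 5
      convention: geometric
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .calibration import Cantilever, ContactCurve, calibrate, detect_contact_window
from .errors import SchemaError
from .mechanics import FibreCrossSection, WellGeometry


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def cantilever_from_config(cfg: dict, base_path: str | Path = ".") -> Cantilever:
    """Build a fully calibrated cantilever from the ``calibration`` block."""
    try:
        block = cfg["calibration"]
        c = Cantilever(
            width=float(block["w"]),
            length=float(block["l"]),
            tip_height=float(block["h"]),
            kn=float(block["kn"]),
            E_si=float(block.get("E_si", Cantilever.__dataclass_fields__["E_si"].default)),
            G_si=float(block.get("G_si", Cantilever.__dataclass_fields__["G_si"].default)),
            thickness=_opt_float(block.get("t")),
            invols=_opt_float(block.get("invols")),
        )
    except KeyError as e:
        raise SchemaError(f"calibration block is missing key {e}") from e
    curve = None
    if c.invols is None:
        rel = block.get("contact_curve")
        if rel is None:
            raise SchemaError("calibration block needs either 'invols' or 'contact_curve'")
        df = pd.read_csv(Path(base_path) / rel)
        for col in ("distance_m", "deflection_V"):
            if col not in df.columns:
                raise SchemaError(f"contact-curve file is missing column {col!r}")
        dist = df["distance_m"].to_numpy(float)
        defl = df["deflection_V"].to_numpy(float)
        window = detect_contact_window(dist, defl)
        curve = ContactCurve(distance=dist, deflection=defl, contact_window=window)
    return calibrate(c, curve)


def fibre_from_config(cfg: dict) -> FibreCrossSection:
    """Fibre cross-section from the ``fibre`` block (dimensions in nm)."""
    try:
        block = cfg["fibre"]
        return FibreCrossSection(
            height=float(block["height_nm"]) * 1e-9,
            width=float(block["width_nm"]) * 1e-9,
        )
    except KeyError as e:
        raise SchemaError(f"fibre block is missing key {e}") from e


def well_from_config(cfg: dict) -> WellGeometry:
    block = cfg.get("well", {})
    return WellGeometry(
        half_width_um=float(block.get("half_width_um", 5.0)),
        convention=block.get("convention", "geometric"),
    )


def _opt_float(value) -> float | None:
    return None if value is None else float(value)
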