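"""File formats and run provenance.

CSV dialect everywhere: comma-separated, UTF-8, mandatory header row,
dot decimal separator.  Result JSONs embed a provenance block (config
hash, seed, package version, timestamp) so a run can be reproduced from
its output alone.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .optics import CellModel, Spectrum, UniaxialMaterial
from .quantitation import AssaySeries

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_assay_csv",
    "write_assay_csv",
    "read_cell_json",
    "write_cell_json",
    "write_result_json",
    "write_png",
    "provenance",
]


def read_spectrum_csv(path) -> Spectrum:
    """Two-column spectrum: ``wavelength_nm,transmittance`` (+ optional
    ``normalized`` flag column)."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "transmittance"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    kind = "absolute"
    if "normalized" in df.columns and bool(df["normalized"].iloc[0]):
        kind = "normalized"
    return Spectrum(
        df["wavelength_nm"].to_numpy(float),
        df["transmittance"].to_numpy(float),
        kind=kind,
    )


def write_spectrum_csv(path, s: Spectrum) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": s.wavelengths_nm, "transmittance": s.values}
    )
    if s.kind == "normalized":
        df["normalized"] = 1
    df.to_csv(path, index=False)


def read_assay_csv(path, readout_name: str = "readout") -> AssaySeries:
    df = pd.read_csv(path)
    required = {"concentration_g_per_ml", "readout", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = df["concentration_g_per_ml"].le(0) | df["concentration_g_per_ml"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: invalid concentration at line {line}")
    return AssaySeries.from_frame(df, readout_name=readout_name)


def write_assay_csv(path, series: AssaySeries) -> None:
    series.to_frame().to_csv(path, index=False)


def _material_from_dict(d: dict) -> UniaxialMaterial:
    return UniaxialMaterial(
        name=d.get("name", "custom"),
        n_o_cauchy=tuple(d["n_o_cauchy"]),
        n_e_cauchy=tuple(d["n_e_cauchy"]),
        valid_range_nm=tuple(d.get("valid_range_nm", (380.0, 780.0))),
    )


def read_cell_json(path) -> CellModel:
    with open(path) as fh:
        d = json.load(fh)
    kwargs = dict(
        gap_um=d["gap_um"],
        tilt_deg=d["tilt_deg"],
        azimuth_deg=d.get("azimuth_deg", 45.0),
        metadata=d.get("metadata", {}),
    )
    if "material" in d:
        kwargs["material"] = _material_from_dict(d["material"])
    return CellModel(**kwargs)


def write_cell_json(path, cell: CellModel) -> None:
    d = {
        "gap_um": cell.gap_um,
        "tilt_deg": cell.tilt_deg,
        "azimuth_deg": cell.azimuth_deg,
        "material": {
            "name": cell.material.name,
            "n_o_cauchy": list(cell.material.n_o_cauchy),
            "n_e_cauchy": list(cell.material.n_e_cauchy),
            "valid_range_nm": list(cell.material.valid_range_nm),
        },
        "metadata": cell.metadata,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def provenance(config: dict, seed: int | None) -> dict:
    """Machine-readable provenance block for result files."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result_json(path, payload: dict, config: dict, seed: int | None) -> None:
    """Atomically write results plus provenance."""
    out = _jsonable({"provenance": provenance(config, seed), **payload})
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(out, fh, indent=2)
    os.replace(tmp, path)


def write_png(path, img: np.ndarray) -> None:
    from PIL import Image

    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path, format="PNG")


def read_png(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
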