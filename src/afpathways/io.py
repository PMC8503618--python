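"""Readers, writers and run logging.

The ingestion boundary is a documented open interchange schema, not a
mapping-system vendor format: an electrode x sample voltage matrix as
delimited text or an HDF5 dataset, plus a JSON metadata document

    {"fs_hz": 2034.5, "chamber": "LA",
     "contact_mask": [true, ...],          # one per electrode
     "qrs_times": [1234, ...],             # optional, sample indices
     "layout": {"spline_order": [...], "valve_spline": 0}}  # optional

Every result artifact embeds the fully resolved analysis configuration
so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .egm import Recording
from .grid import BasketLayout

__all__ = ["read_recording", "write_recording", "write_results", "load_config",
           "load_scene", "logger"]

logger = logging.getLogger("afpathways")


def _load_matrix(path: Path) -> np.ndarray:
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            if "voltages" not in f:
                raise ValueError("HDF5 file lacks a 'voltages' dataset")
            return np.asarray(f["voltages"])
    return np.loadtxt(path, delimiter=",")


def read_recording(path, metadata_path=None) -> Recording:
    """Read a recording matrix plus its JSON metadata.

    ``metadata_path`` defaults to ``<path>.json`` next to the matrix.
    Validation is strict: a missing or malformed field raises a
    ``ValueError`` naming it; non-finite voltages raise with the
    offending channel indices.
    """
    path = Path(path)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(
        path.suffix + ".json")
    if not meta_path.exists():
        raise ValueError(f"metadata file not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "fs_hz" not in meta:
        raise ValueError("metadata missing required field 'fs_hz'")
    fs = float(meta["fs_hz"])
    chamber = meta.get("chamber", "LA")
    if chamber not in ("LA", "RA"):
        raise ValueError(f"metadata field 'chamber' must be LA or RA, got {chamber!r}")
    volts = _load_matrix(path)
    if volts.ndim != 2:
        raise ValueError("voltage matrix must be 2D (electrodes x samples)")
    if not np.isfinite(volts).all():
        bad = np.nonzero(~np.isfinite(volts).all(axis=1))[0]
        raise ValueError(f"non-finite voltages on channels {bad.tolist()}")
    contact = meta.get("contact_mask")
    if contact is not None and len(contact) != volts.shape[0]:
        raise ValueError("metadata field 'contact_mask' length mismatch")
    layout = BasketLayout.from_dict(meta["layout"]) if meta.get("layout") else BasketLayout()
    qrs = np.asarray(meta["qrs_times"], dtype=int) if meta.get("qrs_times") else None
    return Recording(
        voltages=volts,
        fs=fs,
        chamber=chamber,
        layout=layout,
        contact_mask=np.asarray(contact, dtype=bool) if contact is not None else None,
        qrs_times=qrs,
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV + JSON metadata (round-trip exact)."""
    path = Path(path)
    np.savetxt(path, rec.voltages, delimiter=",", fmt="%.17g")
    meta = {
        "fs_hz": rec.fs,
        "chamber": rec.chamber,
        "contact_mask": rec.contact_mask.tolist(),
        "qrs_times": rec.qrs_times.tolist() if rec.qrs_times is not None else None,
        "layout": rec.layout.to_dict() if rec.layout is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def write_results(obj: dict, path, cfg: Optional[AnalysisConfig] = None) -> None:
    """Write a result JSON with the resolved config embedded."""
    out = dict(obj)
    out["config"] = (cfg or DEFAULT_CONFIG).to_dict()
    Path(path).write_text(json.dumps(out, indent=1, default=_jsonify))
    logger.info("wrote %s", path)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Load an AnalysisConfig from JSON/YAML, with keyword overrides."""
    d = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text) or {}
        else:
            d = json.loads(text)
    d.update(overrides)
    base = AnalysisConfig().to_dict()
    unknown = set(d) - set(base)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    base.update(d)
    cfg = AnalysisConfig.from_dict(base)
    for k, v in cfg.to_dict().items():
        logger.info("config %s = %r", k, v)
    return cfg


def load_scene(path):
    """Load a synthetic scene description (JSON or YAML)."""
    from .synth import SynthScene

    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return SynthScene.from_dict(d)
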