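"""Dataset containers and reconstruction bundles on disk.

A *dataset container* is a directory holding the LR intensity stack as a
float TIFF, the geometry and noise metadata as YAML, and a per-LED table
as CSV (plus, for simulated data, the ground-truth images so that later
evaluation is self-contained). A *reconstruction bundle* holds the
recovered amplitude/phase and pupil images as float TIFFs, the error
history as CSV, and a manifest with everything needed to reproduce the
run. Float stacks round-trip losslessly (float64 TIFF).
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from ._common import SolveResult
from .optics import GroundTruth, MeasurementSet, OpticalConfig, Pupil, led_illuminations, make_pupil

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_reconstruction",
    "read_reconstruction",
    "manifest_checksum",
]


def _config_dict(config: OpticalConfig) -> dict:
    return dataclasses.asdict(config)


def _led_table(ms: MeasurementSet) -> pd.DataFrame:
    rows = []
    for i, il in enumerate(ms.illuminations):
        rows.append(
            {
                "index": i,
                "row": il.led_index[0],
                "col": il.led_index[1],
                "illum_na": il.illum_na,
                "shift_y": il.pixel_shift[0],
                "shift_x": il.pixel_shift[1],
                "regime": il.regime,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(
    path,
    ms: MeasurementSet,
    truth: GroundTruth | None = None,
    true_pupil: Pupil | None = None,
) -> Path:
    """Write a dataset container directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "stack.tif", ms.intensities.astype(np.float64))
    meta = {
        "format": "fpmkit-dataset-v1",
        "optical_config": _config_dict(ms.config),
        "noise_record": _jsonable(ms.noise_record),
    }
    (path / "config.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    _led_table(ms).to_csv(path / "leds.csv", index=False)
    if truth is not None:
        tifffile.imwrite(path / "truth_amplitude.tif", truth.amplitude.astype(np.float64))
        tifffile.imwrite(path / "truth_phase.tif", truth.phase.astype(np.float64))
    if true_pupil is not None:
        tifffile.imwrite(
            path / "truth_pupil_phase.tif", np.angle(true_pupil.values).astype(np.float64)
        )
        tifffile.imwrite(
            path / "truth_pupil_amplitude.tif", np.abs(true_pupil.values).astype(np.float64)
        )
        (path / "truth_pupil.yaml").write_text(
            yaml.safe_dump({"zernike": [float(c) for c in true_pupil.aberration]})
        )
    return path


def read_dataset(path) -> tuple[MeasurementSet, GroundTruth | None, Pupil | None]:
    """Read a dataset container; the truth entries are None if absent."""
    path = Path(path)
    meta = yaml.safe_load((path / "config.yaml").read_text())
    if meta.get("format") != "fpmkit-dataset-v1":
        raise ValueError(f"{path} is not an fpmkit dataset container")
    config = OpticalConfig(**meta["optical_config"])
    stack = tifffile.imread(path / "stack.tif")
    illums = led_illuminations(config)
    ms = MeasurementSet(
        intensities=np.asarray(stack, dtype=float),
        illuminations=illums,
        config=config,
        noise_record=meta.get("noise_record", {"model": "none"}),
    )
    truth = None
    if (path / "truth_amplitude.tif").exists():
        truth = GroundTruth(
            amplitude=tifffile.imread(path / "truth_amplitude.tif"),
            phase=tifffile.imread(path / "truth_phase.tif"),
        )
    true_pupil = None
    if (path / "truth_pupil.yaml").exists():
        z = yaml.safe_load((path / "truth_pupil.yaml").read_text())["zernike"]
        true_pupil = make_pupil(config, tuple(z))
    return ms, truth, true_pupil


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _params_dict(params) -> dict:
    if params is None:
        return {}
    if dataclasses.is_dataclass(params):
        return _jsonable(dataclasses.asdict(params))
    return {"repr": repr(params)}


def write_reconstruction(path, result: SolveResult, config: OpticalConfig) -> Path:
    """Write a reconstruction bundle directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "amplitude.tif", result.amplitude.astype(np.float64))
    tifffile.imwrite(path / "phase.tif", result.phase.astype(np.float64))
    tifffile.imwrite(
        path / "pupil_amplitude.tif", np.abs(result.pupil.values).astype(np.float64)
    )
    tifffile.imwrite(
        path / "pupil_phase.tif", np.angle(result.pupil.values).astype(np.float64)
    )
    hist = {"iteration": list(range(len(result.history["E_p"])))}
    hist.update({k: v for k, v in result.history.items()})
    pd.DataFrame(hist).to_csv(path / "history.csv", index=False)
    manifest = {
        "format": "fpmkit-reconstruction-v1",
        "method": result.method,
        "n_iter": result.n_iter,
        "stop_reason": result.stop_reason,
        "params": _params_dict(result.params),
        "optical_config": _config_dict(config),
        "package_version": _package_version(),
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_reconstruction(path) -> dict:
    """Read a reconstruction bundle back into arrays + metadata."""
    path = Path(path)
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    if manifest.get("format") != "fpmkit-reconstruction-v1":
        raise ValueError(f"{path} is not an fpmkit reconstruction bundle")
    out = dict(manifest)
    amp = tifffile.imread(path / "amplitude.tif")
    phase = tifffile.imread(path / "phase.tif")
    out["object"] = amp * np.exp(1j * phase)
    out["pupil"] = tifffile.imread(path / "pupil_amplitude.tif") * np.exp(
        1j * tifffile.imread(path / "pupil_phase.tif")
    )
    out["history"] = pd.read_csv(path / "history.csv")
    return out


def manifest_checksum(path) -> str:
    """Stable checksum of a container's metadata + image bytes."""
    path = Path(path)
    h = hashlib.sha256()
    for f in sorted(path.iterdir()):
        if f.suffix in (".yaml", ".csv"):
            h.update(f.read_bytes())
        elif f.suffix == ".tif":
            h.update(np.ascontiguousarray(tifffile.imread(f)).tobytes())
    return h.hexdigest()


def _package_version() -> str:
    from . import __version__

    return __version__
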