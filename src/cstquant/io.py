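"""File I/O: TIFF channels and maps, trace CSVs, calibration and report JSON."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationFit
from .frap import FRAPTrace
from .images import ImageSet

CHANNEL_SUFFIXES = {"donor": "_donor.tif", "acceptor": "_acceptor.tif", "fret": "_fret.tif"}


def save_image_set(images: ImageSet, prefix: str | Path) -> dict[str, Path]:
    """Write one 16-bit grayscale TIFF per channel (suffixes _donor/_acceptor/_fret)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in images.channels().items():
        p = prefix.with_name(prefix.name + CHANNEL_SUFFIXES[name])
        tifffile.imwrite(p, np.clip(np.rint(arr), 0, 65535).astype(np.uint16))
        paths[name] = p
    return paths


def load_image_set(
    donor: str | Path, acceptor: str | Path, fret: str | Path
) -> ImageSet:
    """Load three channel TIFFs into an :class:`ImageSet`.

    16-bit input is the expected format; 8-bit input is accepted and
    promoted with a warning. Channel dimensions must match.
    """
    arrays = {}
    for name, path in (("donor", donor), ("acceptor", acceptor), ("fret", fret)):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{name} channel file not found: {path}")
        arr = tifffile.imread(path)
        if arr.dtype == np.uint8:
            warnings.warn(f"{path.name}: 8-bit input promoted to float", stacklevel=2)
        arrays[name] = np.asarray(arr, dtype=float)
    shapes = {n: a.shape for n, a in arrays.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"channel dimensions differ: {shapes}")
    return ImageSet(**arrays, metadata={"sources": {n: str(p) for n, p in
                                                    (("donor", donor), ("acceptor", acceptor), ("fret", fret))}})


def save_map(values: np.ndarray, path: str | Path) -> Path:
    """Write a scalar map as 32-bit float TIFF (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    return path


def load_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float32)


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def save_trace_csv(trace: FRAPTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(path, index=False)
    return path


def load_trace_csv(path: str | Path) -> FRAPTrace:
    return FRAPTrace.from_frame(pd.read_csv(path))


def save_calibration(fit: CalibrationFit, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(fit.__dict__, indent=2) + "\n")
    return path


def load_calibration(path: str | Path) -> CalibrationFit:
    return CalibrationFit(**json.loads(Path(path).read_text()))


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
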