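"""File I/O: TIFF stacks, JSON sidecars and curve CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError


def write_stack(path, stack: np.ndarray) -> None:
    """Write a 2D/3D intensity or label array as a (multi-page) TIFF."""
    arr = np.asarray(stack)
    if arr.ndim not in (2, 3):
        raise ValidationError("stack must be 2D or 3D")
    tifffile.imwrite(str(path), arr)


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return list(obj)
        return super().default(obj)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n"
    )


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
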