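"""File I/O shared by the pipeline stages: images, masks, tables, manifests."""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
from PIL import Image


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit RGB raster as TIFF or PNG depending on the suffix."""
    path = Path(path)
    arr = np.asarray(pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as single-channel PNG, 0/255."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def write_sidecar(path: str | Path, microns_per_pixel: float, marker_name: str,
                  **extra: Any) -> None:
    """JSON sidecar carrying image calibration and marker identity."""
    payload = {"microns_per_pixel": microns_per_pixel,
               "marker_name": marker_name, **extra}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_sidecar(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_manifest(path: str | Path, stage: str, params: dict[str, Any],
                   outputs: list[str]) -> None:
    """Append-style run manifest: one JSON document per run."""
    manifest = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": params,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                          encoding="utf-8")
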