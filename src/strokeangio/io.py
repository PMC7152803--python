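"""TIFF/CSV/JSON input and output.

Volumes are stored as multi-page TIFF with axes ``(z, y, x)``; time series
as multi-page TIFF with pages = frames; en-face maps and masks as single-page
TIFF.  Complex B-frame pairs are stored as two real-valued stacks (real and
imaginary parts) per repeat.  Ground truth and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .angiogram import AngiogramSeries, BFramePair
from .synthgen import GroundTruth


def write_series(path, series: AngiogramSeries) -> None:
    tifffile.imwrite(str(path), np.stack(series.frames).astype(np.float32))


def read_series(path, frame_interval_s: float = 10.0) -> AngiogramSeries:
    stack = tifffile.imread(str(path))
    frames = [np.asarray(f, float) for f in stack]
    return AngiogramSeries(frames, frame_times_s=frame_interval_s * np.arange(len(frames)))


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image).astype(np.float32))


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask).astype(np.uint8))


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_bframe_pair(directory, pair: BFramePair, stem: str = "bframe") -> None:
    """Two real TIFF stacks (real, imag) per repeat, as acquired data arrives."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, frame in (("a", pair.frame_a), ("b", pair.frame_b)):
        tifffile.imwrite(d / f"{stem}_{name}_real.tiff", frame.real.astype(np.float32))
        tifffile.imwrite(d / f"{stem}_{name}_imag.tiff", frame.imag.astype(np.float32))


def read_bframe_pair(directory, stem: str = "bframe", position_index: int = 0) -> BFramePair:
    d = Path(directory)

    def load(name):
        re = tifffile.imread(d / f"{stem}_{name}_real.tiff")
        im = tifffile.imread(d / f"{stem}_{name}_imag.tiff")
        return np.asarray(re, float) + 1j * np.asarray(im, float)

    return BFramePair(load("a"), load("b"), position_index=position_index)


def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "segment_theta": truth.segment_theta.tolist(),
        "segment_centerlines": [c.tolist() for c in truth.segment_centerlines],
        "stall_log": {str(k): v.tolist() for k, v in truth.stall_log.items()},
        "lesion_area_px": truth.lesion_area_px,
        "n_frames": truth.n_frames,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path, lesion_shape: tuple[int, int] | None = None) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    lesion = (np.zeros(lesion_shape, bool) if lesion_shape is not None
              else np.zeros((0, 0), bool))
    return GroundTruth(
        segment_centerlines=[np.array(c, int) for c in payload["segment_centerlines"]],
        segment_theta=np.array(payload["segment_theta"]),
        lesion_mask=lesion,
        lesion_area_px=int(payload["lesion_area_px"]),
        stall_log={int(k): np.array(v, int) for k, v in payload["stall_log"].items()},
        n_frames=payload.get("n_frames"),
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
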