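"""Image-stream operators for online behavior tracking.

The classic tracking chain — threshold the frame, keep the largest connected
component, reduce it to image moments — extracts an animal's position and
body orientation from video in real time.  The same moment machinery gives
the major-axis length used e.g. as a pupil-diameter proxy.  A region-of-
interest monitor turns the centroid trajectory into ENTER/EXIT events that
can gate stimulation, and a raw frame container sink provides bit-exact
video splitting without any codec.

Conventions: frames are 8-bit grayscale ``numpy`` arrays, origin top-left,
x = column and y = row (y increases downward).  Orientation is reported in
degrees in (-90, 90], measured from the +x axis toward +y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, BinaryIO, Iterable, Optional

import numpy as np
from scipy import ndimage

from .core import Observable
from .combinators import filter_, map_, sink

#: 8-connectivity structuring element for component labeling.
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Frame:
    """A timestamped 2-D intensity matrix with its ordinal in the stream."""

    pixels: np.ndarray
    time: int = 0
    index: int = 0


@dataclass(frozen=True)
class BlobMeasure:
    """Centroid, size and ellipse-model shape of one connected component."""

    centroid_x: float
    centroid_y: float
    area: int
    orientation: float  # degrees in (-90, 90], from +x toward +y (downward)
    major_axis: float   # pixels, 4*sqrt(larger eigenvalue of the covariance)


@dataclass(frozen=True)
class RoiEvent:
    """Edge-detected ROI crossing; level is the digital-output state after it."""

    kind: str  # "ENTER" or "EXIT"
    time: int
    level: int  # 1 iff inside after the event


def grayscale(pixels: np.ndarray) -> np.ndarray:
    """Luma conversion: round(0.299 R + 0.587 G + 0.114 B), clipped to [0, 255]."""
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected rows x cols x 3 RGB array, got {pixels.shape}")
    rgb = pixels.astype(np.float64)
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.round(luma), 0, 255).astype(np.uint8)


def threshold_range(pixels: np.ndarray, lo: int, hi: int,
                    invert: bool = False) -> np.ndarray:
    """Binary mask of pixels with lo <= value <= hi, xor ``invert``.

    ``invert=True`` selects everything outside the band — the usual way to
    segment a dark animal on a bright background.
    """
    mask = (pixels >= lo) & (pixels <= hi)
    return mask ^ invert


def largest_component(mask: np.ndarray) -> Optional[np.ndarray]:
    """Largest 8-connected component of a binary mask, or None if empty.

    Area ties resolve to the component whose first pixel comes earliest in
    row-major scan order (deterministic where sizes are equal).
    """
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return None
    counts = np.bincount(labeled.ravel())[1:]  # skip background
    best = int(np.argmax(counts)) + 1  # scipy labels in raster-scan order;
    # argmax keeps the first maximal label, i.e. the earliest first pixel
    return labeled == best


def blob_measure(component: np.ndarray) -> BlobMeasure:
    """Image-moment measures of one component mask.

    centroid = (M10/M00, M01/M00); orientation = 0.5*atan2(2*mu11', mu20'-mu02')
    with normalized central moments mu' = mu/M00; major_axis = 4*sqrt(l1)
    where l1 is the larger eigenvalue of [[mu20', mu11'], [mu11', mu02']].
    """
    ys, xs = np.nonzero(component)
    area = xs.size
    if area == 0:
        raise ValueError("empty component; filter with largest_component upstream")
    cx = xs.mean()
    cy = ys.mean()
    dx = xs - cx
    dy = ys - cy
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)
    orientation = np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02))
    if orientation <= -90.0:
        orientation += 180.0
    trace = mu20 + mu02
    det_root = np.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11 ** 2)
    lam1 = 0.5 * (trace + det_root)
    return BlobMeasure(float(cx), float(cy), int(area),
                       float(orientation), float(4.0 * np.sqrt(lam1)))


def track_largest(frame: Frame, lo: int, hi: int,
                  invert: bool = False) -> Optional[BlobMeasure]:
    """Convenience chain: threshold -> largest component -> moments."""
    component = largest_component(threshold_range(frame.pixels, lo, hi, invert))
    return None if component is None else blob_measure(component)


def roi_monitor(centroids: Observable, x0: float, y0: float,
                x1: float, y1: float) -> Observable:
    """ENTER/EXIT events as a centroid stream crosses a rectangle.

    Inside iff x0 <= cx < x1 and y0 <= cy < y1; initial state is outside, so
    the first event (if any) is ENTER, and events strictly alternate.
    Input elements may be :class:`BlobMeasure` or (x, y) pairs; None
    elements (no blob found) count as outside.
    """
    state = {"inside": False}

    def classify(measure):
        if measure is None:
            inside = False
        else:
            cx = getattr(measure, "centroid_x", None)
            cy = getattr(measure, "centroid_y", None)
            if cx is None:
                cx, cy = measure
            inside = (x0 <= cx < x1) and (y0 <= cy < y1)
        if inside == state["inside"]:
            return None
        state["inside"] = inside
        kind = "ENTER" if inside else "EXIT"
        return RoiEvent(kind, centroids.scheduler.clock, int(inside))

    return filter_(map_(centroids, classify), lambda ev: ev is not None)


# ---------------------------------------------------------------------------
# Raw frame container: JSON header line + concatenated row-major u8 frames.
# ---------------------------------------------------------------------------

class FrameFileWriter:
    """Incremental writer for the raw frame container.

    The file is a single JSON header line ``{"rows", "cols", "dtype": "u8",
    "count"}`` followed by the frames' pixel bytes, row-major.  The header's
    count is patched on close, so the format stays a one-pass stream sink.
    A frame whose dimensions differ from the first one is a stream error.
    """

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self._fh: Optional[BinaryIO] = None
        self._shape: Optional[tuple[int, int]] = None
        self.count = 0

    def write(self, frame: Frame) -> None:
        pixels = np.ascontiguousarray(frame.pixels, dtype=np.uint8)
        if self._fh is None:
            self._shape = pixels.shape
            self._fh = open(self.path, "wb")
            self._fh.write(self._header(0))
        if pixels.shape != self._shape:
            raise ValueError(f"frame shape {pixels.shape} != stream shape "
                             f"{self._shape}")
        self._fh.write(pixels.tobytes())
        self.count += 1

    def _header(self, count: int) -> bytes:
        # fixed-width count field so the close-time patch keeps every offset
        rows, cols = self._shape
        return (f'{{"rows": {rows}, "cols": {cols}, "dtype": "u8", '
                f'"count": {count:10d}}}\n').encode()

    def close(self) -> None:
        if self._fh is None:  # no frames: emit an empty 0x0 container
            self._shape = (0, 0)
            self._fh = open(self.path, "wb")
            self._fh.write(self._header(0))
        self._fh.seek(0)
        self._fh.write(self._header(self.count))
        self._fh.close()
        self._fh = None


def frame_writer(frames: Observable, path: str | Path) -> Observable:
    """Sink: write every frame to one raw container file; forward unchanged.

    The file is finalized (header count patched) on stream completion or
    error.  Combined with window_trigger + select_many, this yields one file
    per window — online video splitting with a bit-exact container.
    """
    writer = FrameFileWriter(path)

    def on_subscribe(guard):
        def effect(frame):
            writer.write(frame)

        def done():
            writer.close()
            guard.on_completed()

        def fail(info):
            writer.close()
            guard.on_error(info)

        inner = sink(frames, effect)
        return inner.subscribe(on_next=guard.on_next, on_completed=done,
                               on_error=fail).dispose

    return Observable(frames.scheduler, on_subscribe)


def read_frames(path: str | Path) -> list[np.ndarray]:
    """Invert :func:`frame_writer` exactly: header line, then raw u8 frames."""
    raw = Path(path).read_bytes()
    newline = raw.index(b"\n")
    header = json.loads(raw[:newline])
    rows, cols, count = header["rows"], header["cols"], header["count"]
    if header.get("dtype") != "u8":
        raise ValueError(f"unsupported dtype {header.get('dtype')!r}")
    body = raw[newline + 1:]
    expected = rows * cols * count
    if len(body) != expected:
        raise ValueError(f"container holds {len(body)} pixel bytes, header "
                         f"promises {expected}")
    data = np.frombuffer(body, dtype=np.uint8)
    return [data[i * rows * cols:(i + 1) * rows * cols].reshape(rows, cols)
            for i in range(count)]
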