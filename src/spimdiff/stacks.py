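"""Image-stack I/O, frame re-binning, ROI geometry and trace extraction.

An acquisition is a time-ordered stack of 2-D frames with a fixed frame
interval and a physical pixel size.  Intensity traces are obtained as the
mean pixel value over a region of interest (ROI) per frame; ROIs are either
pixel rectangles or annular bands at a known distance from the dye source,
which is how the distance axis of the diffusion analysis is defined.

Pixel coordinates are 0-based ``(x, y) = (column, row)`` with the origin at
the centre of the top-left pixel; distances are physical (um), computed
from pixel coordinates via the pixel size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "ROISpec",
    "IntensityTrace",
    "read_stack",
    "write_stack",
    "rebin",
    "distance_map",
    "build_roi_ladder",
    "extract_traces",
    "traces_to_csv",
    "traces_from_csv",
    "rois_to_json",
    "rois_from_json",
]


@dataclass
class ImageStack:
    """Time-ordered 2-D frames with physical calibration.

    ``frames`` has shape (T, H, W); ``origin_time`` is the observation-clock
    time of the first frame (s).
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of one frame."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Observation-clock time of each frame, s."""
        return self.origin_time + self.frame_interval * np.arange(self.n_frames)


@dataclass
class ROISpec:
    """A region of interest: a pixel rectangle or an annular distance band.

    Rectangles are given as ``(row0, row1, col0, col1)`` half-open bounds.
    Annuli are the pixels whose distance (um) from ``source`` falls in
    ``[d_lo, d_hi)``; ``source`` is a point ``(x, y)`` or a segment
    ``((x1, y1), (x2, y2))`` in pixel coordinates.
    """

    nominal_distance: float
    label: str = ""
    rect: tuple[int, int, int, int] | None = None
    source: tuple | None = None
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nominal_distance < 0:
            raise ValueError("nominal_distance must be >= 0")
        if (self.rect is None) == (self.band is None):
            raise ValueError("specify exactly one of rect= or (source=, band=)")
        if self.band is not None and self.source is None:
            raise ValueError("annular ROI needs a source")

    def mask(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Boolean pixel mask of this ROI on a frame of the given shape."""
        if self.rect is not None:
            r0, r1, c0, c1 = self.rect
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise ValueError(f"ROI {self.label!r}: rectangle outside frame bounds")
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            return m
        d = distance_map(shape, self.source, pixel_size)
        lo, hi = self.band
        m = (d >= lo) & (d < hi)
        if not m.any():
            raise ValueError(
                f"ROI {self.label!r}: empty annular band [{lo}, {hi}) um "
                f"at nominal distance {self.nominal_distance} um"
            )
        return m


@dataclass
class IntensityTrace:
    """Mean ROI intensity versus time at a known distance from the source."""

    times: np.ndarray
    values: np.ndarray
    distance: float
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")


def read_stack(
    path,
    frame_interval: float,
    pixel_size: float,
    origin_time: float = 0.0,
) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack, pages ordered by index."""
    with tifffile.TiffFile(str(path)) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"{path}: pages have mixed shapes {sorted(shapes)}")
        frames = tif.asarray()
    frames = np.asarray(frames, dtype=float)
    return ImageStack(frames, frame_interval, pixel_size, origin_time)


def write_stack(path, stack: ImageStack) -> None:
    """Write an ImageStack as a float32 multi-page TIFF (one page per frame)."""
    tifffile.imwrite(str(path), stack.frames.astype(np.float32), photometric="minisblack")


def rebin(stack: ImageStack, factor: int) -> ImageStack:
    """Sum-bin each frame in ``factor`` x ``factor`` blocks.

    Sum (not mean) binning follows camera hardware-binning semantics: total
    intensity over the retained region is preserved.  Trailing rows/columns
    not divisible by ``factor`` are dropped; the pixel size is multiplied
    by ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("rebin factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return ImageStack(
            stack.frames.copy(), stack.frame_interval, stack.pixel_size, stack.origin_time
        )
    T, H, W = stack.frames.shape
    h, w = H // factor, W // factor
    if h == 0 or w == 0:
        raise ValueError(f"frames of shape {(H, W)} are smaller than the bin factor")
    cropped = stack.frames[:, : h * factor, : w * factor]
    binned = cropped.reshape(T, h, factor, w, factor).sum(axis=(2, 4))
    return ImageStack(binned, stack.frame_interval, stack.pixel_size * factor, stack.origin_time)


def distance_map(shape: tuple[int, int], source, pixel_size: float) -> np.ndarray:
    """Per-pixel Euclidean distance (um) from a source point or segment.

    ``source`` is ``(x, y)`` or ``((x1, y1), (x2, y2))`` in pixel
    coordinates; it must intersect the frame bounds.
    """
    H, W = shape
    cols, rows = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    src = np.asarray(source, dtype=float)
    if src.shape == (2,):
        pts = src[None]
    elif src.shape == (2, 2):
        pts = src
    else:
        raise ValueError("source must be (x, y) or ((x1, y1), (x2, y2))")
    if not ((pts[:, 0] >= 0) & (pts[:, 0] <= W - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= H - 1)).all():
        raise ValueError(f"source {source} lies outside the frame bounds {(H, W)}")
    if src.shape == (2,):
        d = np.hypot(cols - src[0], rows - src[1])
    else:
        (x1, y1), (x2, y2) = src
        vx, vy = x2 - x1, y2 - y1
        L2 = vx * vx + vy * vy
        if L2 == 0:
            d = np.hypot(cols - x1, rows - y1)
        else:
            s = np.clip(((cols - x1) * vx + (rows - y1) * vy) / L2, 0.0, 1.0)
            d = np.hypot(cols - (x1 + s * vx), rows - (y1 + s * vy))
    return d * pixel_size


def build_roi_ladder(
    shape: tuple[int, int],
    source,
    pixel_size: float,
    start: float,
    stop: float,
    step: float,
    band_width: float,
) -> list[ROISpec]:
    """Annular-band ROIs at distances start, start+step, ..., stop (um).

    Each band covers distances ``[d - band_width/2, d + band_width/2)`` from
    the source; bands are pairwise disjoint when ``band_width <= step``.
    Raises if any band contains no pixels, naming the offending distance.
    """
    if not (0 <= start < stop):
        raise ValueError("require 0 <= start < stop")
    if step <= 0 or band_width <= 0:
        raise ValueError("step and band_width must be > 0")
    distances = np.arange(start, stop + 0.5 * step, step)
    dmap = distance_map(shape, source, pixel_size)
    rois = []
    for d in distances:
        lo, hi = d - band_width / 2.0, d + band_width / 2.0
        if not ((dmap >= lo) & (dmap < hi)).any():
            raise ValueError(f"annular band at {d} um contains no pixels")
        rois.append(
            ROISpec(
                nominal_distance=float(d),
                label=f"d{d:g}um",
                source=source,
                band=(float(lo), float(hi)),
            )
        )
    return rois


def extract_traces(
    stack: ImageStack,
    rois: list[ROISpec],
    background: ROISpec | None = None,
) -> list[IntensityTrace]:
    """Mean-intensity trace per ROI, optionally background-subtracted.

    The value at frame k is the mean over the ROI's pixels, minus the mean
    over the background ROI at the same frame when one is given.  Times are
    ``origin_time + k * frame_interval``.
    """
    T = stack.n_frames
    flat = stack.frames.reshape(T, -1)
    bg = None
    bg_mask = None
    if background is not None:
        bg_mask = background.mask(stack.shape, stack.pixel_size)
        bg = flat[:, bg_mask.ravel()].mean(axis=1)
    times = stack.times
    traces = []
    for roi in rois:
        m = roi.mask(stack.shape, stack.pixel_size)
        if bg_mask is not None and (m & bg_mask).any():
            warnings.warn(
                f"ROI {roi.label!r} overlaps the background ROI", stacklevel=2
            )
        vals = flat[:, m.ravel()].mean(axis=1)
        if bg is not None:
            vals = vals - bg
        traces.append(IntensityTrace(times, vals, roi.nominal_distance, roi.label))
    return traces


def traces_to_csv(path, traces: list[IntensityTrace]) -> None:
    """Write traces in long format: time_s, value, distance_um, roi_label."""
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.times,
                "value": tr.values,
                "distance_um": tr.distance,
                "roi_label": tr.roi_label,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path) -> list[IntensityTrace]:
    """Read traces written by :func:`traces_to_csv`."""
    df = pd.read_csv(path)
    traces = []
    for (label, dist), grp in df.groupby(["roi_label", "distance_um"], sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            IntensityTrace(
                grp["time_s"].to_numpy(), grp["value"].to_numpy(), float(dist), str(label)
            )
        )
    return traces


def rois_to_json(path, rois: list[ROISpec]) -> None:
    payload = [
        {
            "nominal_distance": r.nominal_distance,
            "label": r.label,
            "rect": list(r.rect) if r.rect is not None else None,
            "source": np.asarray(r.source).tolist() if r.source is not None else None,
            "band": list(r.band) if r.band is not None else None,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def rois_from_json(path) -> list[ROISpec]:
    payload = json.loads(Path(path).read_text())
    rois = []
    for item in payload:
        rois.append(
            ROISpec(
                nominal_distance=item["nominal_distance"],
                label=item.get("label", ""),
                rect=tuple(item["rect"]) if item.get("rect") else None,
                source=(
                    tuple(map(tuple, item["source"]))
                    if item.get("source") and isinstance(item["source"][0], list)
                    else tuple(item["source"]) if item.get("source") else None
                ),
                band=tuple(item["band"]) if item.get("band") else None,
            )
        )
    return rois
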