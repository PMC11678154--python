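"""Synthetic traces and SPIM-like image stacks for the diffusion assay.

Named presets encode the three experimental regimes the analysis is built
for: point injections of concentrated rhodamine into agarose gels (fast
diffusion, recording starts essentially at injection), dextran leaking from
the subintestinal-vein (SIV) plexus of control zebrafish embryos (D around
12 um^2/s, recording delayed by ~320 s of mounting time), and the same
assay in tumour-xenografted embryos (roughly tenfold slower diffusion and a
longer effective delay).  Traces realize the delayed point-source model
exactly, optionally with an early-time linear "pressure ramp" near the
source and a Gaussian read-noise + signal-proportional shot-noise camera
model; stacks render the same model over a pixel grid with a static
vessel-like second channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .model import DiffusionParams, SingularTimeError, concentration
from .stacks import ImageStack, IntensityTrace, distance_map, write_stack

__all__ = [
    "NoiseSpec",
    "PressureSpec",
    "Preset",
    "StackGeometry",
    "PRESET_NAMES",
    "make_preset",
    "simulate_traces",
    "render_stack",
    "write_simulation",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise: additive Gaussian read noise plus signal-proportional
    variance (a Gaussian stand-in for shot noise), per pixel and per frame."""

    read_sigma: float = 2.0
    shot_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_sigma < 0 or self.shot_scale < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def sigma(self, signal: np.ndarray) -> np.ndarray:
        return np.sqrt(self.read_sigma**2 + self.shot_scale * np.maximum(signal, 0.0))


@dataclass(frozen=True)
class PressureSpec:
    """Early-time linear concentration ramp near the injection site.

    The injection transiently pushes tracer through the medium, adding
    ``ramp_rate * min(t, ramp_duration)`` to pixels/ROIs within
    ``ramp_radius`` of the source.
    """

    ramp_rate: float = 50.0
    ramp_duration: float = 10.0
    ramp_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.ramp_rate < 0 or self.ramp_duration < 0 or self.ramp_radius < 0:
            raise ValueError("pressure-ramp parameters must be >= 0")

    def contribution(self, x: float, t: np.ndarray) -> np.ndarray:
        if x > self.ramp_radius:
            return np.zeros_like(t)
        return self.ramp_rate * np.minimum(t, self.ramp_duration)


@dataclass(frozen=True)
class Preset:
    """One named experimental condition.

    ``start_time`` is the time of the first recorded frame on the model's
    observation clock; presets with ``t0 = 0`` start one frame interval
    after injection, since the model diverges at diffusion time zero.
    """

    name: str
    D: float
    t0: float
    B: float
    roi_distances: tuple[float, ...]
    frame_interval: float
    n_frames: int
    noise: NoiseSpec = NoiseSpec()
    pressure_ramp: PressureSpec | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.roi_distances, dtype=float)
        if d.size == 0 or np.any(d < 0) or (d.size > 1 and not np.all(np.diff(d) > 0)):
            raise ValueError("roi_distances must be >= 0 and strictly increasing")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def params(self) -> DiffusionParams:
        return DiffusionParams(D=self.D, t0=self.t0, B=self.B)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.frame_interval * np.arange(self.n_frames)


def _agarose(name: str, D: float) -> Preset:
    return Preset(
        name=name,
        D=D,
        t0=0.0,
        B=20000.0,
        roi_distances=tuple(float(d) for d in range(30, 201, 10)),
        frame_interval=5.0,
        n_frames=720,
        pressure_ramp=PressureSpec(),
        start_time=5.0,
    )


def _embryo(name: str, D: float, t0: float) -> Preset:
    return Preset(
        name=name,
        D=D,
        t0=t0,
        B=20000.0,
        roi_distances=tuple(float(d) for d in range(10, 41, 5)),
        frame_interval=5.0,
        n_frames=720,
    )


_PRESETS: dict[str, Preset] = {
    "agarose_1pct": _agarose("agarose_1pct", 18.1),
    "agarose_2pct": _agarose("agarose_2pct", 8.9),
    "agarose_5pct": _agarose("agarose_5pct", 2.6),
    "control_embryo": _embryo("control_embryo", 12.0, 320.0),
    "xenograft_embryo": _embryo("xenograft_embryo", 1.0, 600.0),
    "xenograft_variant_a": _embryo("xenograft_variant_a", 1.9, 600.0),
    "xenograft_variant_b": _embryo("xenograft_variant_b", 0.82, 600.0),
}

PRESET_NAMES = tuple(_PRESETS)


def make_preset(name: str, **overrides) -> Preset:
    """Return a registered preset, optionally with fields overridden."""
    try:
        preset = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset


@dataclass(frozen=True)
class StackGeometry:
    """Pixel-grid geometry for rendered stacks.

    ``source`` is a point ``(x, y)`` or segment ``((x1, y1), (x2, y2))`` in
    pixel coordinates.  ``vessel_mask``, when given, is the static
    (EGFP-like) channel footprint; by default a band of pixels within
    ``vessel_halfwidth`` um of the source is used.
    """

    width: int = 128
    height: int = 128
    pixel_size: float = 1.375
    source: tuple = (0.0, 64.0)
    vessel_mask: np.ndarray | None = None
    vessel_halfwidth: float = 5.0
    vessel_intensity: float = 500.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.pixel_size <= 0:
            raise ValueError("invalid geometry")


def simulate_traces(
    preset: Preset,
    noise_free: bool = False,
    seed: int | None = None,
) -> list[IntensityTrace]:
    """Model-exact traces at the preset's ROI distances, optionally noisy.

    The value at frame k and ROI distance x is the delayed point-source
    concentration at observation time ``start_time + k * frame_interval``,
    plus the pressure-ramp contribution if configured, plus camera noise
    unless ``noise_free``.  Fixed seed implies bit-identical output.
    """
    t = preset.times
    rng = np.random.default_rng(preset.noise.seed if seed is None else seed)
    traces = []
    for x in preset.roi_distances:
        clean = concentration(preset.params, x, t)
        if preset.pressure_ramp is not None:
            clean = clean + preset.pressure_ramp.contribution(x, t - preset.start_time)
        vals = clean if noise_free else clean + rng.normal(0.0, preset.noise.sigma(clean))
        traces.append(IntensityTrace(t.copy(), vals, float(x), f"d{x:g}um"))
    return traces


def render_stack(
    preset: Preset,
    geom: StackGeometry = StackGeometry(),
    noise_free: bool = False,
    seed: int | None = None,
) -> tuple[ImageStack, ImageStack]:
    """Render (dye-channel time series, static vessel channel) stacks.

    The dye value of each pixel at frame k is the model concentration at
    the pixel's Euclidean distance from the source set, plus ramp and
    noise.  Raises the model's singular-time error if the first frame falls
    at diffusion time zero (``t0 = 0`` with ``start_time = 0``).
    """
    t = preset.times
    if t[0] + preset.t0 == 0:
        raise SingularTimeError(
            "first frame at diffusion time zero; use start_time > 0 or t0 > 0"
        )
    dmap = distance_map((geom.height, geom.width), geom.source, geom.pixel_size)
    frames = concentration(preset.params, dmap[None, :, :], t[:, None, None])
    if preset.pressure_ramp is not None:
        ramp = np.minimum(t - preset.start_time, preset.pressure_ramp.ramp_duration)
        frames = frames + (
            (dmap <= preset.pressure_ramp.ramp_radius)[None]
            * preset.pressure_ramp.ramp_rate
            * ramp[:, None, None]
        )
    if not noise_free:
        rng = np.random.default_rng(preset.noise.seed if seed is None else seed)
        frames = frames + rng.normal(0.0, preset.noise.sigma(frames))
    dye = ImageStack(frames, preset.frame_interval, geom.pixel_size, origin_time=float(t[0]))
    if geom.vessel_mask is not None:
        vmask = np.asarray(geom.vessel_mask, dtype=bool)
        if vmask.shape != (geom.height, geom.width):
            raise ValueError("vessel_mask shape does not match geometry")
    else:
        vmask = dmap <= geom.vessel_halfwidth
    vessel = ImageStack(
        vmask.astype(float) * geom.vessel_intensity,
        preset.frame_interval,
        geom.pixel_size,
    )
    return dye, vessel


def write_simulation(
    outdir,
    preset: Preset,
    geom: StackGeometry = StackGeometry(),
    noise_free: bool = False,
    seed: int | None = None,
) -> dict:
    """Render a stack pair and write TIFFs plus a ground-truth JSON sidecar.

    Returns the sidecar dictionary (also written to ``sidecar.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dye, vessel = render_stack(preset, geom, noise_free=noise_free, seed=seed)
    write_stack(outdir / "dye.tif", dye)
    write_stack(outdir / "vessel.tif", vessel)
    sidecar = {
        "preset": preset.name,
        "D_um2_per_s": preset.D,
        "t0_s": preset.t0,
        "B": preset.B,
        "roi_distances_um": list(preset.roi_distances),
        "frame_interval_s": preset.frame_interval,
        "n_frames": preset.n_frames,
        "start_time_s": preset.start_time,
        "pixel_size_um": geom.pixel_size,
        "source_px": np.asarray(geom.source).tolist(),
        "noise_free": bool(noise_free),
        "seed": preset.noise.seed if seed is None else seed,
    }
    (outdir / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
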