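"""Half-time (tau_1/2) wavefront analysis of intensity traces.

The time at which a trace drops to half its initial recorded value grows
linearly with the ROI's distance R0 from the source.  The inverse slope of
that line is a heuristic wave speed v of the spreading tracer, convertible
into an independent diffusion-coefficient estimate Dv through the f(D)
correction polynomial; and because the intercept of the trend is controlled
by the injection-to-observation delay (tau_1/2 -> 3 t0 as R0 -> 0), matching
the measured trend against model-simulated tau_1/2 curves over a small
(D, t0) grid yields an independent estimate of the delay t0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .model import DiffusionParams, FCorrection, half_time, solve_Dv, wave_speed
from .stacks import IntensityTrace

__all__ = [
    "NoCrossingError",
    "HalfTimeTrend",
    "measure_half_time",
    "build_trend",
    "simulate_trend",
    "estimate_t0",
    "DEFAULT_D_GRID",
    "DEFAULT_T0_GRID",
]

#: (D, t0) grids over which simulated tau_1/2 curves are matched to data.
DEFAULT_D_GRID = (4.0, 10.0)
DEFAULT_T0_GRID = (300.0, 450.0, 600.0, 1200.0, 1800.0)


class NoCrossingError(ValueError):
    """The trace never falls to half of its reference value."""


@dataclass
class HalfTimeTrend:
    """(R0, tau_1/2) points with their linear trend and derived estimates.

    ``v_hat`` is the inverse slope of the ordinary-least-squares line
    tau_1/2 = slope * R0 + intercept; ``v_points`` are the per-point
    heuristic speeds R0 / tau_1/2.  ``Dv_hat`` is the f(D)-corrected
    diffusion estimate; ``t0_hat`` and ``sse_table`` are filled by
    :func:`estimate_t0`.
    """

    R0: np.ndarray
    tau_half: np.ndarray
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    v_hat: float
    v_points: np.ndarray
    Dv_hat: float
    t0_hat: float | None = None
    sse_table: list[dict] = field(default_factory=list)


def measure_half_time(
    trace: IntensityTrace,
    initial: str = "first",
    window: int = 11,
) -> float:
    """Half-decay time of a trace, s, elapsed since the first recorded frame.

    The reference value is the trace value at the first frame (``"first"``,
    the default) or the maximum over the first ``window`` frames
    (``"early_max"``, for traces that still rise before decaying).  The
    crossing below half the reference is located by linear interpolation
    between the bracketing frames.
    """
    if initial not in ("first", "early_max"):
        raise ValueError(f"unknown initial-value convention {initial!r}")
    v = trace.values
    t = trace.times
    ref_idx = 0 if initial == "first" else int(np.argmax(v[:window]))
    ref = v[ref_idx]
    if not ref > 0:
        raise ValueError(f"trace {trace.roi_label!r}: reference value must be > 0")
    target = 0.5 * ref
    below = np.nonzero(v[ref_idx:] <= target)[0]
    if below.size == 0:
        raise NoCrossingError(
            f"trace {trace.roi_label!r} never falls to half its initial value"
        )
    k = ref_idx + below[0]
    if k == ref_idx:
        return float(t[k] - t[0])
    frac = (v[k - 1] - target) / (v[k - 1] - v[k])
    t_cross = t[k - 1] + frac * (t[k] - t[k - 1])
    return float(t_cross - t[0])


def build_trend(
    traces: list[IntensityTrace],
    fc: FCorrection = FCorrection(),
    reference_tau: float = 700.0,
    reading: str = "quotient",
    initial: str = "first",
    window: int = 11,
) -> HalfTimeTrend:
    """OLS tau_1/2-versus-R0 trend with wave-speed and Dv estimates.

    Traces without a half crossing are skipped with a warning (reported per
    ROI, not fatal to the batch); at least 3 valid points are required.
    ``Dv_hat`` is obtained by inverting the generalized-MSD relation at the
    reference point ``R0 = v_hat * reference_tau`` on the fitted line.
    """
    pts = []
    for tr in traces:
        try:
            tau = measure_half_time(tr, initial=initial, window=window)
        except (NoCrossingError, ValueError) as exc:
            warnings.warn(f"skipping ROI {tr.roi_label!r}: {exc}", stacklevel=2)
            continue
        if tau > 0:
            pts.append((tr.distance, tau))
    if len(pts) < 3:
        raise ValueError(f"need >= 3 valid half-time points, got {len(pts)}")
    pts.sort()
    R0 = np.array([p[0] for p in pts])
    tau = np.array([p[1] for p in pts])
    ols = linregress(R0, tau)
    slope, intercept = float(ols.slope), float(ols.intercept)
    if slope <= 0:
        warnings.warn(
            f"non-positive tau_1/2 trend slope ({slope:g} s/um): "
            "data inconsistent with outward diffusion",
            stacklevel=2,
        )
        v_hat = np.nan
        Dv_hat = np.nan
    else:
        v_hat = 1.0 / slope
        Dv_hat = solve_Dv(v_hat * reference_tau, reference_tau, fc, reading=reading)
    v_points = np.array([wave_speed(r, th) for r, th in zip(R0, tau)])
    return HalfTimeTrend(
        R0=R0,
        tau_half=tau,
        slope=slope,
        slope_se=float(ols.stderr),
        intercept=intercept,
        intercept_se=float(ols.intercept_stderr),
        v_hat=float(v_hat),
        v_points=v_points,
        Dv_hat=float(Dv_hat),
    )


def simulate_trend(D: float, t0: float, R0_grid) -> list[tuple[float, float]]:
    """Model tau_1/2 at each distance in ``R0_grid`` for given (D, t0).

    Uses the same half-time operator later compared against data, ensuring
    self-consistency of the matching procedure.
    """
    params = DiffusionParams(D=D, t0=t0)
    return [(float(r), half_time(params, float(r))) for r in R0_grid]


def estimate_t0(
    trend: HalfTimeTrend,
    D_grid=DEFAULT_D_GRID,
    t0_grid=DEFAULT_T0_GRID,
) -> float:
    """Delay estimate: the grid t0 whose simulated trend best matches the data.

    For every (D, t0) candidate the model tau_1/2 curve is evaluated at the
    measured distances and compared to the measured tau_1/2 by sum of
    squared errors, minimised jointly over both grids; ties break toward
    smaller t0.  Fills ``trend.t0_hat`` and ``trend.sse_table``.
    """
    D_grid = list(D_grid)
    t0_grid = sorted(t0_grid)
    if not D_grid or not t0_grid:
        raise ValueError("D_grid and t0_grid must be nonempty")
    table = []
    best = None
    for t0 in t0_grid:
        for D in D_grid:
            try:
                sim = np.array([tau for _, tau in simulate_trend(D, t0, trend.R0)])
            except ValueError as exc:
                warnings.warn(f"simulation failed for D={D}, t0={t0}: {exc}", stacklevel=2)
                continue
            sse = float(np.sum((sim - trend.tau_half) ** 2))
            table.append({"D": float(D), "t0": float(t0), "sse": sse})
            if best is None or sse < best[0]:
                best = (sse, float(t0), float(D))
    if best is None:
        raise RuntimeError("all trend simulations failed")
    trend.sse_table = table
    trend.t0_hat = best[1]
    return best[1]
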