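"""Savitzky-Golay smoothing and global shared-D least-squares fitting.

Each trace i, recorded at a known distance R0_i from the source, is
modelled as::

    y_i(t) = B_i / sqrt(pi * D * (t + t0)) * exp(-R0_i**2 / (4 * D * (t + t0)))

with one diffusion coefficient D shared across all traces, a free amplitude
B_i per trace (the local amount of tracer seen by that ROI) and, optionally,
a per-trace additive baseline.  The delay t0 is fixed at the known
experimental value by default and can be released as a shared fit
parameter.  A single diffusion component is fitted; the optimiser is
bounded trust-region least squares with multi-start over log-spaced initial
D values, and standard errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .stacks import IntensityTrace

__all__ = ["FitConfig", "GlobalFitResult", "smooth", "fit_global", "fit_report"]

T0_FREE = "free"
_T0_BOUNDS = (0.0, 3600.0)


@dataclass(frozen=True)
class FitConfig:
    """Smoothing and fitting configuration.

    ``t0_s`` is the fixed injection-to-observation delay in seconds, or the
    string ``"free"`` to fit it (bounds 0-3600 s).  ``baseline`` adds a
    per-trace additive offset to the model (off by default: the diffusion
    solution has none).
    """

    t0_s: float | str = 0.0
    sg_window: int = 11
    sg_order: int = 3
    D_bounds: tuple[float, float] = (0.01, 100.0)
    baseline: bool = False
    max_iter: int = 400
    tol: float = 1e-12
    n_starts: int = 5

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        lo, hi = self.D_bounds
        if not (0 < lo < hi):
            raise ValueError("D_bounds must satisfy 0 < lo < hi")
        if isinstance(self.t0_s, str):
            if self.t0_s != T0_FREE:
                raise ValueError(f"t0_s must be a number or '{T0_FREE}'")
        elif self.t0_s < 0:
            raise ValueError("fixed t0_s must be >= 0")

    @property
    def t0_free(self) -> bool:
        return self.t0_s == T0_FREE


@dataclass
class GlobalFitResult:
    """Output of the shared-D global fit."""

    D_hat: float
    D_se: float
    t0_used: float
    t0_se: float | None
    B_hat: np.ndarray
    baseline_hat: np.ndarray | None
    distances: np.ndarray
    rss: float
    r_squared: np.ndarray
    converged: bool
    n_iterations: int
    D_at_bound: bool


def smooth(trace: IntensityTrace, cfg: FitConfig) -> IntensityTrace:
    """Savitzky-Golay smoothing of a trace; times unchanged.

    Endpoints are handled by evaluating the local polynomial fit on the
    truncated window (``mode="interp"``), not by reflection padding, so
    traces that are polynomials of degree <= ``sg_order`` pass through
    unchanged.
    """
    if trace.values.size < cfg.sg_window:
        raise ValueError(
            f"trace of length {trace.values.size} is shorter than "
            f"sg_window={cfg.sg_window}"
        )
    vals = savgol_filter(trace.values, cfg.sg_window, cfg.sg_order, mode="interp")
    return IntensityTrace(trace.times.copy(), vals, trace.distance, trace.roi_label)


def _model_unit(D: float, t0: float, x: float, t: np.ndarray) -> np.ndarray:
    """Model trace with B = 1 (amplitude basis function)."""
    u = t + t0
    return 1.0 / np.sqrt(np.pi * D * u) * np.exp(-(x * x) / (4.0 * D * u))


def _amplitudes(
    D: float, t0: float, traces: list[IntensityTrace], baseline: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares B_i (and baselines) at fixed (D, t0), by projection."""
    B = np.empty(len(traces))
    c = np.zeros(len(traces))
    for i, tr in enumerate(traces):
        m = _model_unit(D, t0, tr.distance, tr.times)
        if baseline:
            A = np.column_stack([m, np.ones_like(m)])
            sol, *_ = np.linalg.lstsq(A, tr.values, rcond=None)
            B[i], c[i] = sol
        else:
            denom = float(m @ m)
            B[i] = float(m @ tr.values) / denom if denom > 0 else 1.0
        B[i] = max(B[i], 1e-12)
    return B, c


def fit_global(traces: list[IntensityTrace], cfg: FitConfig) -> GlobalFitResult:
    """Fit the delayed point-source model jointly to all traces.

    Minimises the unweighted sum of squared residuals over the shared D
    (and t0 when free), per-trace amplitudes and optional baselines.  ROI
    distances are taken from trace metadata and never fitted.
    """
    if len(traces) < 2:
        raise ValueError("global fit needs at least 2 traces")
    distances = np.array([tr.distance for tr in traces], dtype=float)
    if np.unique(distances).size < 2:
        raise ValueError("global fit needs traces at >= 2 distinct distances")
    for tr in traces:
        if not np.all(np.isfinite(tr.values)):
            raise ValueError(f"trace {tr.roi_label!r} has non-finite values")
    if not cfg.t0_free and cfg.t0_s == 0.0 and any(tr.times[0] == 0 for tr in traces):
        raise ValueError("t0 = 0 with a trace starting at t = 0 is singular")

    n = len(traces)
    y_all = np.concatenate([tr.values for tr in traces])
    free_t0 = cfg.t0_free

    def unpack(theta):
        D = theta[0]
        k = 1
        t0 = theta[k] if free_t0 else float(cfg.t0_s)
        if free_t0:
            k += 1
        B = theta[k : k + n]
        base = theta[k + n : k + 2 * n] if cfg.baseline else np.zeros(n)
        return D, t0, B, base

    def residuals(theta):
        D, t0, B, base = unpack(theta)
        res = []
        for i, tr in enumerate(traces):
            pred = B[i] * _model_unit(D, t0, tr.distance, tr.times) + base[i]
            res.append(pred - tr.values)
        return np.concatenate(res)

    lo = [cfg.D_bounds[0]] + ([_T0_BOUNDS[0]] if free_t0 else []) + [1e-12] * n
    hi = [cfg.D_bounds[1]] + ([_T0_BOUNDS[1]] if free_t0 else []) + [1e12] * n
    if cfg.baseline:
        lo += [-np.inf] * n
        hi += [np.inf] * n
    bounds = (np.array(lo), np.array(hi))

    D_starts = np.geomspace(cfg.D_bounds[0] * 1.5, cfg.D_bounds[1] / 1.5, cfg.n_starts)
    t0_start = 300.0 if free_t0 else float(cfg.t0_s)
    best = None
    n_iter = 0
    for D0 in D_starts:
        B0, c0 = _amplitudes(D0, max(t0_start, 1e-6), traces, cfg.baseline)
        theta0 = np.concatenate(
            [[D0], [t0_start] if free_t0 else [], B0, c0 if cfg.baseline else []]
        )
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        try:
            sol = least_squares(
                residuals,
                theta0,
                bounds=bounds,
                method="trf",
                xtol=cfg.tol,
                ftol=cfg.tol,
                gtol=cfg.tol,
                max_nfev=cfg.max_iter * theta0.size,
            )
        except Exception:
            continue
        n_iter += sol.nfev
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("global fit failed to converge from every start")

    D_hat, t0_hat, B_hat, base_hat = unpack(best.x)
    rss = float(2.0 * best.cost)
    dof = max(y_all.size - best.x.size, 1)
    # covariance from the Jacobian at the optimum (Gauss-Newton approximation)
    se = np.full(best.x.size, np.nan)
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.pinv(JTJ) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    at_bound = bool(
        np.isclose(D_hat, cfg.D_bounds[0], rtol=1e-6)
        or np.isclose(D_hat, cfg.D_bounds[1], rtol=1e-6)
    )
    if at_bound:
        warnings.warn(
            f"fitted D = {D_hat:g} um^2/s sits at a bound of {cfg.D_bounds}",
            stacklevel=2,
        )

    r2 = np.empty(n)
    for i, tr in enumerate(traces):
        pred = B_hat[i] * _model_unit(D_hat, t0_hat, tr.distance, tr.times) + base_hat[i]
        ss_res = float(np.sum((tr.values - pred) ** 2))
        ss_tot = float(np.sum((tr.values - tr.values.mean()) ** 2))
        r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    return GlobalFitResult(
        D_hat=float(D_hat),
        D_se=float(se[0]),
        t0_used=float(t0_hat),
        t0_se=float(se[1]) if free_t0 else None,
        B_hat=np.asarray(B_hat, dtype=float),
        baseline_hat=np.asarray(base_hat, dtype=float) if cfg.baseline else None,
        distances=distances,
        rss=rss,
        r_squared=r2,
        converged=bool(best.success),
        n_iterations=int(n_iter),
        D_at_bound=at_bound,
    )


def fit_report(
    result: GlobalFitResult,
    traces: list[IntensityTrace],
    json_path=None,
    plot_path=None,
) -> dict:
    """Serialise a fit as JSON and optionally plot data with fitted curves."""
    report = {
        "D_hat_um2_per_s": result.D_hat,
        "D_se_um2_per_s": result.D_se,
        "t0_used_s": result.t0_used,
        "t0_se_s": result.t0_se,
        "B_hat": result.B_hat.tolist(),
        "baseline_hat": (
            result.baseline_hat.tolist() if result.baseline_hat is not None else None
        ),
        "distances_um": result.distances.tolist(),
        "rss": result.rss,
        "r_squared": result.r_squared.tolist(),
        "converged": result.converged,
        "n_iterations": result.n_iterations,
        "D_at_bound": result.D_at_bound,
    }
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        base = result.baseline_hat if result.baseline_hat is not None else np.zeros(len(traces))
        for i, tr in enumerate(traces):
            (line,) = ax.plot(tr.times, tr.values, ".", ms=2, alpha=0.5)
            pred = (
                result.B_hat[i]
                * _model_unit(result.D_hat, result.t0_used, tr.distance, tr.times)
                + base[i]
            )
            ax.plot(
                tr.times, pred, "-", color=line.get_color(),
                label=f"{tr.distance:g} um",
            )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("intensity (a.u.)")
        ax.set_title(f"global fit: D = {result.D_hat:.3g} um$^2$/s")
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return report
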