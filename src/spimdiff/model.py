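"""Delayed point-source diffusion model and its analytic companions.

A bolus of fluorescent tracer (amount ``B``) released at the origin of a
semi-infinite medium spreads by Fickian diffusion.  Because recording starts
a delay ``t0`` after the release, the concentration observed at distance
``x`` and observation time ``t`` is the 1-D Gaussian point-source solution
evaluated at the shifted diffusion time ``t + t0``::

    C(x, t) = B / sqrt(pi * D * (t + t0)) * exp(-x**2 / (4 * D * (t + t0)))

All lengths are in micrometres, times in seconds and intensities in
arbitrary camera units throughout the package.

Besides the forward model this module provides the quantities derived from
it: the peak-passage time of the concentration wave, the half-decay time
tau_1/2 of an observed trace, the empirical correction polynomial f(D)
linking the tau_1/2 trend to the diffusion coefficient, and the wave-speed
estimators built on those.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DiffusionParams",
    "FCorrection",
    "SingularTimeError",
    "concentration",
    "peak_time",
    "half_time",
    "f_of_D",
    "wave_speed",
    "solve_Dv",
]


class SingularTimeError(ValueError):
    """The model was evaluated at diffusion time t + t0 = 0, where it diverges."""


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the delayed point-source solution.

    Attributes
    ----------
    D : float
        Diffusion coefficient, um^2/s.  Must be positive.
    t0 : float
        Delay between tracer release and the start of recording, s.
        ``t0 = 0`` is allowed (recording starts at release, as in the
        agarose calibration runs) but makes observation time ``t = 0``
        singular.
    B : float
        Amount of tracer on the half-line x >= 0, intensity * um.
    """

    D: float
    t0: float = 0.0
    B: float = 1.0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not self.B > 0:
            raise ValueError(f"B must be > 0, got {self.B}")


@dataclass(frozen=True)
class FCorrection:
    """Quadratic correction factor f(D) = c2*D^2 + c1*D + c0.

    Relates the half-time trend of an observed concentration wave to the
    underlying diffusion coefficient; approximately 4 over the supported
    range 1 <= D <= 20 um^2/s.
    """

    c2: float = 0.013
    c1: float = -0.51
    c0: float = 8.14


def concentration(params: DiffusionParams, x, t):
    """Observed concentration at distance ``x`` (um) and observation time ``t`` (s).

    Broadcasts over array-valued ``x`` and ``t``.

    Raises
    ------
    SingularTimeError
        If any requested time has ``t + t0 == 0``.
    ValueError
        For negative ``x`` or ``t``.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance x must be >= 0")
    if np.any(t < 0):
        raise ValueError("observation time t must be >= 0")
    u = t + params.t0
    if np.any(u == 0):
        raise SingularTimeError("concentration diverges at t + t0 = 0")
    out = params.B / np.sqrt(np.pi * params.D * u) * np.exp(-(x**2) / (4.0 * params.D * u))
    return out if out.ndim else float(out)


def peak_time(params: DiffusionParams, x: float, observed: bool = False) -> float:
    """Time at which the concentration at distance ``x`` peaks.

    On the injection clock the maximum of ``C`` over time sits at
    ``x**2 / (2 D)``.  With ``observed=True`` the time is returned on the
    recording clock, clamped at zero: ROIs whose peak passed during the
    delay ``t0`` show a monotonically decaying trace.
    """
    if x < 0:
        raise ValueError("distance x must be >= 0")
    tmax = x * x / (2.0 * params.D)
    if observed:
        return max(0.0, tmax - params.t0)
    return tmax


def half_time(params: DiffusionParams, x: float, rtol: float = 1e-10) -> float:
    """Half-decay time tau_1/2 of the observed trace at distance ``x``.

    The unique observation time ``t > 0`` at which the trace drops to half
    of its value at the first recorded instant (t = 0).  In the diffusion
    time ``u = t + t0`` this is the root beyond the peak of::

        0.5 * log(u / t0) + a / u - a / t0 = log 2,   a = x**2 / (4 D)

    Requires ``t0 > 0`` so the initial value is finite.  At ``x = 0`` the
    root is exactly ``3 * t0`` (the 1/sqrt(u) prefactor halves at u = 4 t0).
    """
    if params.t0 <= 0:
        raise ValueError("half_time requires t0 > 0 (finite initial value)")
    if x < 0:
        raise ValueError("distance x must be >= 0")
    a = x * x / (4.0 * params.D)
    t0 = params.t0

    def g(u: float) -> float:
        return 0.5 * np.log(u / t0) + a / u - a / t0 - np.log(2.0)

    # g < 0 up to max(t0, 2a) and strictly increasing beyond it, so the
    # root is bracketed by doubling from there.
    lo = max(t0, 2.0 * a)
    hi = 2.0 * lo
    for _ in range(200):
        if g(hi) > 0:
            break
        lo, hi = hi, 2.0 * hi
    else:  # pragma: no cover - unreachable for finite parameters
        raise RuntimeError(
            f"half_time bracket expansion failed for D={params.D}, t0={t0}, x={x}"
        )
    u_star = brentq(g, lo, hi, rtol=rtol)
    return float(u_star - t0)


def f_of_D(fc: FCorrection, D: float) -> float:
    """Evaluate the correction polynomial f at ``D`` (um^2/s).

    Warns outside the supported range 1 <= D <= 20 um^2/s, where the
    quadratic has not been validated.
    """
    if not 1.0 <= D <= 20.0:
        warnings.warn(
            f"f(D) evaluated outside its supported range 1 <= D <= 20 (D={D})",
            stacklevel=2,
        )
    return fc.c2 * D * D + fc.c1 * D + fc.c0


def wave_speed(R0: float, tau_half: float) -> float:
    """Heuristic speed v = R0 / tau_1/2 of the concentration wave, um/s."""
    if tau_half <= 0:
        raise ValueError("tau_half must be > 0")
    if R0 < 0:
        raise ValueError("R0 must be >= 0")
    return R0 / tau_half


def solve_Dv(
    R0: float,
    tau_half: float,
    fc: FCorrection = FCorrection(),
    reading: str = "quotient",
    bracket: tuple[float, float] = (0.01, 100.0),
) -> float:
    """Diffusion coefficient implied by a (R0, tau_1/2) pair, um^2/s.

    Inverts the generalized mean-squared-displacement relation.  Under the
    default ``"quotient"`` reading the relation is
    ``R0**2 = 4 * D * tau_half / f(D)``; the alternative ``"product"``
    reading multiplies by f(D) instead.  Solved by Brent root-finding on
    ``bracket``; a root outside the bracket is an error, not an
    extrapolation.
    """
    if R0 < 0:
        raise ValueError("R0 must be >= 0")
    if tau_half <= 0:
        raise ValueError("tau_half must be > 0")
    if reading not in ("quotient", "product"):
        raise ValueError(f"unknown reading {reading!r}")
    if R0 == 0:
        return 0.0

    def h(D: float) -> float:
        f = fc.c2 * D * D + fc.c1 * D + fc.c0
        msd = 4.0 * D * tau_half / f if reading == "quotient" else 4.0 * D * tau_half * f
        return msd - R0 * R0

    # h can have two roots in the bracket (f is quadratic); take the smallest,
    # which lies on the physically supported low-D branch.
    grid = np.geomspace(bracket[0], bracket[1], 400)
    vals = np.array([h(D) for D in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if vals[0] == 0:
        return float(grid[0])
    if sign_change.size == 0:
        raise ValueError(
            f"no diffusion coefficient in {list(bracket)} um^2/s reproduces "
            f"R0={R0} um at tau_half={tau_half} s ({reading} reading)"
        )
    i = sign_change[0]
    return float(brentq(h, grid[i], grid[i + 1], rtol=1e-12))
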