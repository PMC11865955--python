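"""Wave-intensity analysis, wall shear stress and summary haemodynamics.

Wave intensity analysis (WIA) splits the sampled pressure and mean-velocity
signals at a location into forward (incident, +) and backward (reflected, -)
travelling components using the water-hammer relations

    dp+- = (dp +- rho c du) / 2,     du+- = (du +- dp/(rho c)) / 2,

with c the local pulse-wave velocity.  The split is exact by construction
(dp+ + dp- = dp, du+ + du- = du) and the cumulated components reconstruct the
original signals.  The time-normalized wave intensity WI+- = (dp+-/dt)(du+-/dt)
classifies waves: compressive waves carry dp+- > 0, expansive dp+- < 0.  The
reflection coefficient IR is the amplitude ratio of the reflected to the
incident compressive pressure excursion.

Wall shear stress uses the Stokes boundary-layer profile: tau_w = mu ubar /
delta at the wall, with ubar = q/A and delta the boundary-layer thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import MMHG, BloodParams
from .solver import Solution, pulse_wave_velocity

__all__ = [
    "WIASeries",
    "WSSSeries",
    "SummaryMetrics",
    "wia",
    "reflection_coefficient",
    "wss",
    "summarize",
    "wia_at",
    "wss_at",
]


@dataclass(frozen=True)
class WIASeries:
    """Forward/backward decomposition of (p, u) over one cycle.

    Increment arrays have length n-1 for n samples; cumulated components have
    length n and start from half the initial signal values, so that
    p_plus + p_minus = p and u_plus + u_minus = u exactly.
    """

    dp_plus: np.ndarray
    dp_minus: np.ndarray
    du_plus: np.ndarray
    du_minus: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray
    u_plus: np.ndarray
    u_minus: np.ndarray
    wi_plus: np.ndarray
    wi_minus: np.ndarray
    c_pwv: float
    dt: float

    @property
    def IR(self) -> float:
        return reflection_coefficient(self)


@dataclass(frozen=True)
class WSSSeries:
    """Wall shear stress tau_w(t) (g cm^-1 s^-2) at one location."""

    tau_w: np.ndarray
    delta_cm: float


@dataclass(frozen=True)
class SummaryMetrics:
    """Cycle summary at one location: pressures in mmHg, flows in ml/s."""

    p_systolic: float
    p_diastolic: float
    pulse_pressure: float
    pulse_flow: float
    area_deformation: float


def wia(p, ubar, rho: float, c_pwv: float, dt: float = 1.0) -> WIASeries:
    """Decompose pressure (CGS) and mean velocity into incident/reflected parts.

    ``p`` and ``ubar`` are sampled on a uniform grid over one cycle; ``dt``
    only scales the reported wave intensities.
    """
    p = np.asarray(p, dtype=float)
    u = np.asarray(ubar, dtype=float)
    if c_pwv <= 0:
        raise ValueError("pulse-wave velocity must be positive")
    dp = np.diff(p)
    du = np.diff(u)
    zc = rho * c_pwv
    dp_p = 0.5 * (dp + zc * du)
    dp_m = 0.5 * (dp - zc * du)
    du_p = 0.5 * (du + dp / zc)
    du_m = 0.5 * (du - dp / zc)
    p_plus = 0.5 * p[0] + np.concatenate([[0.0], np.cumsum(dp_p)])
    p_minus = 0.5 * p[0] + np.concatenate([[0.0], np.cumsum(dp_m)])
    u_plus = 0.5 * u[0] + np.concatenate([[0.0], np.cumsum(du_p)])
    u_minus = 0.5 * u[0] + np.concatenate([[0.0], np.cumsum(du_m)])
    return WIASeries(
        dp_plus=dp_p, dp_minus=dp_m, du_plus=du_p, du_minus=du_m,
        p_plus=p_plus, p_minus=p_minus, u_plus=u_plus, u_minus=u_minus,
        wi_plus=(dp_p / dt) * (du_p / dt), wi_minus=(dp_m / dt) * (du_m / dt),
        c_pwv=c_pwv, dt=dt)


def _compressive_amplitude(dcomp: np.ndarray) -> float:
    """Largest contiguous rise of a cumulated component over compressive runs.

    Compressive portions are the intervals where the pressure increment of
    the component is positive; the amplitude is the largest total rise over
    one such contiguous run.
    """
    best = run = 0.0
    for d in dcomp:
        if d > 0:
            run += d
            best = max(best, run)
        else:
            run = 0.0
    return best


def reflection_coefficient(series: WIASeries) -> float:
    """IR = amplitude of reflected / incident compressive pressure waves.

    Returns NaN (flagged missing) when no incident compressive wave exists.
    """
    inc = _compressive_amplitude(series.dp_plus)
    ref = _compressive_amplitude(series.dp_minus)
    if inc == 0.0:
        return math.nan
    return ref / inc


def wss(q, A, mu: float, delta: float) -> WSSSeries:
    """Wall shear stress tau_w = mu (q/A) / delta; sign follows the flow."""
    q = np.asarray(q, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("areas must be positive")
    return WSSSeries(tau_w=mu * (q / A) / delta, delta_cm=delta)


def summarize(sol: Solution, vid: int, frac: float = 0.5) -> SummaryMetrics:
    """Pulse metrics of the converged cycle at a location inside a vessel."""
    p = sol.pressure(vid, frac)
    q = sol.flow(vid, frac)
    A = sol.area(vid, frac)
    return SummaryMetrics(
        p_systolic=float(p.max()),
        p_diastolic=float(p.min()),
        pulse_pressure=float(p.max() - p.min()),
        pulse_flow=float(q.max() - q.min()),
        area_deformation=float((A.max() - A.min()) / A.min()),
    )


def _local_pwv(sol: Solution, params, vid: int, frac: float) -> float:
    v = sol.network.vessels[vid]
    r0 = float(v.radius_at(frac * v.length_cm))
    law = params.large_law(v.group_large)
    return float(pulse_wave_velocity(r0, law(r0), params.blood.rho))


def wia_at(sol: Solution, params, vid: int, frac: float = 0.5,
           c_pwv: float | None = None) -> WIASeries:
    """WIA of a solved cycle at a vessel location.

    The default wave speed is the local linearized pulse-wave velocity
    sqrt(2Eh/(3 rho r0)) evaluated at the analysis location; pass ``c_pwv``
    to override (e.g. a PU-loop estimate).
    """
    p = sol.pressure(vid, frac) * MMHG
    u = sol.flow(vid, frac) / sol.area(vid, frac)
    c = _local_pwv(sol, params, vid, frac) if c_pwv is None else c_pwv
    return wia(p, u, params.blood.rho, c, dt=sol.T / sol.n_t)


def wss_at(sol: Solution, blood: BloodParams, vid: int, frac: float = 0.5) -> WSSSeries:
    """Wall shear stress series of a solved cycle at a vessel location."""
    return wss(sol.flow(vid, frac), sol.area(vid, frac), blood.mu, blood.delta)
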