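"""Intraventricular flow metrics on gridded velocity fields.

Two dimensionless diagnostics of diastolic filling:

* mean vorticity  omega_bar(t) = (T / V) * integral_V |curl v| dV, with T the
  heartbeat period and V the masked (chamber) volume — evaluated with
  mask-aware second-order finite differences and midpoint quadrature;
* vortex formation time  VFT = integral over the E-wave period of
  v_MV(t) / d dt, with v_MV = Q_MV / A_eff the mean transmitral velocity and
  d = sqrt(4 A_eff / pi) the effective orifice diameter. The optimal range is
  3 <= VFT <= 4, up to 5 acceptable, above that the forming vortex ring
  breaks down.

The velocity fields may come from any solver export or from the analytic
fixtures in :mod:`lvmech.synthetic_cohort`; Q_MV is typically dV/dt of the
volume curve during filling (mass conservation with a binary valve model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_kinematics import VolumeCurve
from .synthetic_cohort import GriddedVelocityField

__all__ = [
    "TransmitralFlow",
    "FlowMetrics",
    "vorticity_field",
    "mean_vorticity",
    "vortex_formation_time",
    "classify_vft",
    "transmitral_flow_from_volume_curve",
]


@dataclass
class TransmitralFlow:
    """Transmitral flow rate over the E-wave window.

    Q_mv in mL/s on ``times`` (s); ``a_eff`` the effective mitral orifice
    area in mm^2; ``t_e`` the E-wave period in s, starting at ``times[0]``.
    """

    times: np.ndarray
    q_mv: np.ndarray
    a_eff: float
    t_e: float

    def __post_init__(self):
        if self.a_eff <= 0:
            raise ValueError("effective orifice area must be positive")
        if self.t_e <= 0:
            raise ValueError("E-wave period must be positive")

    @property
    def diameter(self) -> float:
        """Effective orifice diameter d = sqrt(4 A_eff / pi), mm."""
        return float(np.sqrt(4.0 * self.a_eff / np.pi))


@dataclass
class FlowMetrics:
    omega_bar: np.ndarray
    omega_bar_diastolic_peak: float
    vft: float
    vft_label: str


def _masked_derivative(f: np.ndarray, mask: np.ndarray, axis: int, h: float) -> np.ndarray:
    """d f / d axis using only in-mask nodes: centered 2nd order where both
    neighbors are masked-in, one-sided 2nd order (3-point) at mask boundaries,
    one-sided 1st order as a last resort, 0 where isolated."""
    fp = np.roll(f, -1, axis)  # f[i+1]
    fm = np.roll(f, 1, axis)  # f[i-1]
    fpp = np.roll(f, -2, axis)
    fmm = np.roll(f, 2, axis)
    mp = np.roll(mask, -1, axis)
    mm = np.roll(mask, 1, axis)
    mpp = np.roll(mask, -2, axis)
    mmm = np.roll(mask, 2, axis)
    # roll wraps around; forbid wrapped neighbors at the array edge
    edge_lo = np.zeros_like(mask)
    edge_hi = np.zeros_like(mask)
    sl = [slice(None)] * mask.ndim
    sl[axis] = 0
    edge_lo[tuple(sl)] = True
    sl[axis] = -1
    edge_hi[tuple(sl)] = True
    mm = mm & ~edge_lo
    mp = mp & ~edge_hi
    sl[axis] = 1
    e2lo = edge_lo.copy()
    e2lo[tuple(sl)] = True
    sl[axis] = -2
    e2hi = edge_hi.copy()
    e2hi[tuple(sl)] = True
    mmm = mmm & ~e2lo
    mpp = mpp & ~e2hi

    out = np.zeros_like(f)
    centered = mp & mm
    fwd2 = ~centered & mp & mpp
    bwd2 = ~centered & mm & mmm
    fwd1 = ~centered & ~fwd2 & ~bwd2 & mp
    bwd1 = ~centered & ~fwd2 & ~bwd2 & ~fwd1 & mm
    out[centered] = (fp[centered] - fm[centered]) / (2 * h)
    out[fwd2] = (-3 * f[fwd2] + 4 * fp[fwd2] - fpp[fwd2]) / (2 * h)
    out[bwd2] = (3 * f[bwd2] - 4 * fm[bwd2] + fmm[bwd2]) / (2 * h)
    out[fwd1] = (fp[fwd1] - f[fwd1]) / h
    out[bwd1] = (f[bwd1] - fm[bwd1]) / h
    return out


def vorticity_field(field: GriddedVelocityField, frame: int | None = None) -> np.ndarray:
    """Pointwise vorticity modulus |curl v| on the masked region.

    Derivatives use only in-mask nodes (centered in the interior, one-sided at
    the mask boundary, both second order). Values outside the mask are 0.
    """
    v = field.velocity
    if v.ndim == 5:
        if frame is None:
            raise ValueError("time-series field: specify a frame")
        v = v[frame]
    mask = field.mask
    idx = np.nonzero(mask)
    for ax in range(3):
        if idx[ax].max() - idx[ax].min() < 1:
            raise ValueError("mask interior needs at least 2 nodes per direction")
    h = field.spacing
    d = {}
    for comp in range(3):
        for ax in range(3):
            d[(comp, ax)] = _masked_derivative(v[..., comp], mask, ax, h)
    wx = d[(2, 1)] - d[(1, 2)]
    wy = d[(0, 2)] - d[(2, 0)]
    wz = d[(1, 0)] - d[(0, 1)]
    out = np.sqrt(wx**2 + wy**2 + wz**2)
    out[~mask] = 0.0
    return out


def mean_vorticity(
    field: GriddedVelocityField, period: float, diastolic_frames: np.ndarray | None = None
):
    """Dimensionless mean vorticity omega_bar(t) = (T/V) int_V |curl v| dV.

    The integral and the mask volume use the same midpoint quadrature, so
    omega_bar is the in-mask average of the vorticity modulus times T.
    Returns (omega_bar array over frames, diastolic peak); for a single
    snapshot the array has one entry and equals the peak.
    """
    v = field.velocity
    n_t = v.shape[0] if v.ndim == 5 else 1
    omega = np.empty(n_t)
    for i in range(n_t):
        w = vorticity_field(field, i if v.ndim == 5 else None)
        omega[i] = period * w[field.mask].mean()
    if diastolic_frames is None:
        peak = float(omega.max())
    else:
        peak = float(omega[np.asarray(diastolic_frames, int)].max())
    return omega, peak


def vortex_formation_time(flow: TransmitralFlow) -> float:
    """VFT = integral over T_E of (Q_MV / A_eff) / d dt (trapezoidal).

    Negative transmitral flow samples inside the window (valve leakage or
    detection slop) are clipped to zero; an all-negative window raises.
    """
    t = np.asarray(flow.times, float)
    q = np.asarray(flow.q_mv, float)
    sel = (t >= t[0]) & (t <= t[0] + flow.t_e)
    if not np.any(q[sel] > 0):
        raise ValueError("transmitral flow is non-positive over the E-wave period")
    v_mv = np.clip(q[sel], 0.0, None) * 1000.0 / flow.a_eff  # mm/s
    return float(np.trapezoid(v_mv / flow.diameter, t[sel]))


def classify_vft(vft: float) -> str:
    """Formation-time bands: <3 suboptimal, [3,4] optimal, (4,5] acceptable,
    >5 high (vortex-ring breakdown)."""
    if vft < 0:
        raise ValueError("VFT must be non-negative")
    if vft < 3.0:
        return "suboptimal"
    if vft <= 4.0:
        return "optimal"
    if vft <= 5.0:
        return "acceptable"
    return "high"


def transmitral_flow_from_volume_curve(vc: VolumeCurve, mv_area: float) -> TransmitralFlow:
    """Transmitral flow from mass conservation: Q_MV = dV/dt during filling,
    over the detected E-wave window of the volume curve."""
    t_on, t_end = vc.t_e_window
    t = vc.times
    if t_end < t_on:
        sel = (t >= t_on) | (t <= t_end)
        tt = np.where(t < t_on, t + vc.period, t)
        order = np.argsort(tt[sel])
        times = tt[sel][order]
        q = vc.dvdt[sel][order]
    else:
        sel = (t >= t_on) & (t <= t_end)
        times = t[sel]
        q = vc.dvdt[sel]
    return TransmitralFlow(times=times, q_mv=q, a_eff=mv_area, t_e=float(vc.t_e))
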