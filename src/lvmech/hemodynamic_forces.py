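"""Hemodynamic force from boundary data.

The net force the blood exerts on the chamber is evaluated from wall and
orifice velocities alone:

    F(t) = rho * [ d/dt ( oint_S x (v.n) dS )  +  oint_S v (v.n) dS ]

where v is the fluid velocity on the moving endocardial surface (no-slip:
wall velocity on the tissue, wall velocity plus a mass-conserving plug flow on
the open orifice). The time derivative of the first moment is taken by
periodic (spectral) differencing across frames, which is robust at the
11-32 frames/cycle of exercise echo. F is reported dimensionless as
f = F / (rho g V(t)) in percent.

Valves follow the binary model: the aortic orifice is open exactly when the
chamber ejects (dV/dt < 0) and the mitral orifice when it fills, each carrying
a uniform normal plug velocity of magnitude |dV/dt| / orifice area.

Six longitudinal-force scalars summarize f_z(t): whole-cycle / systolic /
diastolic RMS amplitudes (LVLF, LVsysLF, LVdiaLF) and the signed-lobe means
(LVsysIm over the systolic positive lobe, LVs over the following negative
suction interval, LVdiaIm over the next diastolic positive lobe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_kinematics import MeshSequence, VolumeCurve, mesh_volume

__all__ = [
    "HDFSeries",
    "HDFParameters",
    "RHO_BLOOD",
    "G_STANDARD",
    "boundary_velocity",
    "orifice_plug_velocity",
    "surface_first_moment",
    "hdf_time_series",
    "hdf_parameters",
]

RHO_BLOOD = 1060.0  # kg/m^3
G_STANDARD = 9.81  # m/s^2


@dataclass
class HDFSeries:
    """Dimensionless hemodynamic force over one cycle.

    ``force_n`` is F(t) in Newtons, shape (n_frames, 3); ``f_percent`` is
    100 * F / (rho g V(t)); ``i_ed``/``i_es`` delimit systole [ED, ES)."""

    times: np.ndarray
    force_n: np.ndarray
    f_percent: np.ndarray
    volume_ml: np.ndarray
    period: float
    i_ed: int
    i_es: int
    rho: float = RHO_BLOOD
    g: float = G_STANDARD

    @property
    def f_long(self) -> np.ndarray:
        """Longitudinal (apex->base, +z) dimensionless force, %."""
        return self.f_percent[:, 2]


@dataclass
class HDFParameters:
    """The six longitudinal-force scalars, %.

    Lobe-based parameters are None (with the matching flag) when the lobe is
    absent from the waveform; LVs is reported as a magnitude.
    """

    lvlf: float
    lvsyslf: float
    lvdialf: float
    lvsysim: float | None
    lvs: float | None
    lvdiaim: float | None
    missing_lobes: tuple = ()


def _spectral_derivative(y: np.ndarray, period: float) -> np.ndarray:
    """d/dt of a periodic uniformly sampled series (FFT differentiation)."""
    n = y.shape[0]
    k = np.fft.fftfreq(n, d=period / n) * 2j * np.pi
    if n % 2 == 0:
        k[n // 2] = 0.0  # Nyquist mode has no well-defined derivative
    return np.real(np.fft.ifft(k.reshape((-1,) + (1,) * (y.ndim - 1)) * np.fft.fft(y, axis=0), axis=0))


def _require_uniform(times: np.ndarray, period: float):
    n = len(times)
    expect = times[0] + np.arange(n) * period / n
    if not np.allclose(times, expect, atol=1e-9 * period):
        raise ValueError("frames must be uniformly spaced over the cycle; resample first")


def boundary_velocity(seq: MeshSequence) -> np.ndarray:
    """Material (wall) velocity of every vertex, mm/s, shape (n_frames, n_vertices, 3).

    Computed by periodic spectral differencing of vertex trajectories on the
    uniform frame grid (no-slip: this is also the fluid velocity at the wall).
    """
    if seq.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    _require_uniform(seq.times, seq.period)
    return _spectral_derivative(seq.vertices, seq.period)


def orifice_plug_velocity(vc: VolumeCurve, mv_area: float, av_area: float):
    """Mass-conservation plug velocities (mm/s) on the two orifices vs time.

    Returns (times, v_av, v_mv) on the dense volume-curve grid, signed along
    the outward normal: ejection (dV/dt < 0) opens the aortic orifice with
    outward speed |dV/dt|/av_area; filling opens the mitral orifice with
    inward (negative) speed -dV/dt/mv_area. The closed valve carries zero.
    dV/dt is in mL/s = 1000 mm^3/s.
    """
    if mv_area <= 0 or av_area <= 0:
        raise ValueError("orifice areas must be positive")
    q = vc.dvdt * 1000.0  # mm^3/s
    v_av = np.where(q < 0, -q / av_area, 0.0)
    v_mv = np.where(q > 0, -q / mv_area, 0.0)
    return vc.times.copy(), v_av, v_mv


def _triangle_geometry(points, triangles):
    p = points[triangles]
    centroid = p.mean(axis=1)
    n_area = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # n * A
    return centroid, n_area


def surface_first_moment(points: np.ndarray, triangles: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """oint x (vec . n) dS for a uniform vector field, exactly (the integrand
    is linear per flat triangle). Equals vec * V_enclosed for a closed surface
    — the oracle identity for the force kernel. Units follow the inputs."""
    centroid, n_area = _triangle_geometry(points, triangles)
    flux = n_area @ np.asarray(vec, float)
    return (centroid * flux[:, None]).sum(axis=0)


def hdf_time_series(
    seq: MeshSequence,
    vc: VolumeCurve | None = None,
    *,
    av_triangles: np.ndarray | None = None,
    mv_triangles: np.ndarray | None = None,
    rho: float = RHO_BLOOD,
    g: float = G_STANDARD,
    harmonics: int | None = None,
) -> HDFSeries:
    """Evaluate the dimensionless hemodynamic force on a registered sequence.

    Orifice triangle ids default to the ``av_triangles``/``mv_triangles``
    metadata written by the synthetic generator; without them the surface is
    treated as all-wall (valid for rigid-motion oracles where dV/dt = 0).
    ``harmonics`` optionally truncates the Fourier content of the first-moment
    series before differencing (off by default).
    """
    _require_uniform(seq.times, seq.period)
    n = seq.n_frames
    tris = seq.triangles
    if av_triangles is None:
        av_triangles = np.asarray(seq.metadata.get("av_triangles", []), int)
    if mv_triangles is None:
        mv_triangles = np.asarray(seq.metadata.get("mv_triangles", []), int)

    vols = np.array([mesh_volume(seq.frame(i), tris) for i in range(n)])
    i_ed, i_es = int(np.argmax(vols)), int(np.argmin(vols))
    dvdt = _spectral_derivative(vols, seq.period)  # mL/s
    vel = boundary_velocity(seq)  # mm/s

    m1 = np.empty((n, 3))  # oint x (v.n) dS, mm^4/s
    m2 = np.empty((n, 3))  # oint v (v.n) dS, mm^5/s^2
    for i in range(n):
        pts = seq.frame(i)
        centroid, n_area = _triangle_geometry(pts, tris)
        v_tri = vel[i][tris].mean(axis=1)  # mm/s per triangle

        if len(av_triangles) or len(mv_triangles):
            nhat_a = np.linalg.norm(n_area, axis=1)
            q = dvdt[i] * 1000.0  # mm^3/s
            if q < 0 and len(av_triangles):  # ejection: aortic plug outward
                patch = av_triangles
            elif q > 0 and len(mv_triangles):  # filling: mitral plug inward
                patch = mv_triangles
            else:
                patch = None
            if patch is not None:
                area = nhat_a[patch].sum()
                if area <= 0:
                    raise ValueError("zero orifice area with nonzero flux")
                nhat = n_area[patch] / np.maximum(nhat_a[patch], 1e-300)[:, None]
                v_tri[patch] = v_tri[patch] + (-q / area) * nhat

        flux = np.einsum("ij,ij->i", v_tri, n_area)  # mm^3/s per triangle
        m1[i] = (centroid * flux[:, None]).sum(axis=0)
        m2[i] = (v_tri * flux[:, None]).sum(axis=0)

    if harmonics is not None:
        m1_hat = np.fft.fft(m1, axis=0)
        keep = np.zeros(n, bool)
        idx = np.fft.fftfreq(n, d=1.0 / n)
        keep[np.abs(idx) <= harmonics] = True
        m1 = np.real(np.fft.ifft(np.where(keep[:, None], m1_hat, 0.0), axis=0))

    dm1 = _spectral_derivative(m1, seq.period)  # mm^4/s^2
    # SI: x in m (1e-3), v in m/s (1e-3), dS in m^2 (1e-6) -> both terms 1e-12
    force = rho * (dm1 + m2) * 1e-12  # N
    v_m3 = vols * 1e-6
    f_percent = 100.0 * force / (rho * g * v_m3[:, None])
    return HDFSeries(
        times=seq.times.copy(), force_n=force, f_percent=f_percent,
        volume_ml=vols, period=seq.period, i_ed=i_ed, i_es=i_es, rho=rho, g=g,
    )


# ---------------------------------------------------------------------------
# longitudinal-force parameters


def _rms(t, f, idx):
    if len(idx) == 0:
        return 0.0
    return float(np.sqrt(np.mean(f[idx] ** 2)))


def _crossing(t, f, i, j):
    """Linear-interpolated zero-crossing time between samples i and j."""
    if f[j] == f[i]:
        return t[i]
    return t[i] + (t[j] - t[i]) * (-f[i]) / (f[j] - f[i])


def _lobe_mean(t, f, i0, i1, sign):
    """Time-average of f over the contiguous lobe spanned by samples [i0, i1]
    (inclusive), extended to the interpolated zero crossings at both ends."""
    ts, te = t[i0], t[i1]
    area = np.trapezoid(f[i0 : i1 + 1], t[i0 : i1 + 1]) if i1 > i0 else 0.0
    if i0 > 0 and np.sign(f[i0 - 1]) != sign and f[i0] != 0.0:
        tc = _crossing(t, f, i0 - 1, i0)
        area += 0.5 * f[i0] * (ts - tc)
        ts = tc
    if i1 < len(f) - 1 and np.sign(f[i1 + 1]) != sign and f[i1] != 0.0:
        tc = _crossing(t, f, i1, i1 + 1)
        area += 0.5 * f[i1] * (tc - te)
        te = tc
    if te <= ts:
        return None
    return float(area / (te - ts))


def _runs(mask):
    """Contiguous runs of True as (start, stop-inclusive) pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def hdf_parameters(hdf: HDFSeries, vc: VolumeCurve | None = None) -> HDFParameters:
    """Extract the six longitudinal-force scalars from a cycle.

    Systole is [ED, ES) on the frame grid (from the series' own volume
    extrema). Lobes are located on the longitudinal trace: the systolic
    positive lobe containing the systolic maximum, the negative suction
    interval starting at the first zero-crossing after it, and the diastolic
    positive lobe immediately following. Missing lobes are flagged, not
    reported as zero.
    """
    f = hdf.f_long
    n = len(f)
    # rotate so the cycle starts at ED
    shift = hdf.i_ed
    f = np.roll(f, -shift)
    t = np.arange(n) * hdf.period / n
    n_sys = (hdf.i_es - hdf.i_ed) % n

    lvlf = _rms(t, f, np.arange(n))
    lvsyslf = _rms(t, f, np.arange(n_sys))
    lvdialf = _rms(t, f, np.arange(n_sys, n))

    missing = []
    lvsysim = lvs = lvdiaim = None

    # close the cycle periodically so lobes ending at t = T interpolate their
    # final zero crossing correctly; runs starting at the appended sample are
    # ignored
    fe = np.append(f, f[0])
    te = np.append(t, hdf.period)

    pos_runs = [r for r in _runs(fe > 0) if r[0] < n_sys]
    if pos_runs and np.any(f[:n_sys] > 0):
        i_max = int(np.argmax(np.where(np.arange(n) < n_sys, f, -np.inf)))
        run = next((r for r in pos_runs if r[0] <= i_max <= r[1]), None)
        if run is not None:
            lvsysim = _lobe_mean(te, fe, run[0], run[1], 1.0)
            # suction: contiguous negative interval right after the lobe
            neg_runs = [r for r in _runs(fe < 0) if r[1] >= r[0] > run[1] and r[0] <= n]
            if neg_runs:
                s = neg_runs[0]
                m = _lobe_mean(te, fe, s[0], s[1], -1.0)
                lvs = abs(m) if m is not None else None
                pos_after = [r for r in _runs(fe > 0) if s[1] < r[0] <= n]
                if pos_after:
                    d = pos_after[0]
                    lvdiaim = _lobe_mean(te, fe, d[0], d[1], 1.0)
    for name, val in (("lvsysim", lvsysim), ("lvs", lvs), ("lvdiaim", lvdiaim)):
        if val is None:
            missing.append(name)
    return HDFParameters(
        lvlf=lvlf, lvsyslf=lvsyslf, lvdialf=lvdialf,
        lvsysim=lvsysim, lvs=lvs, lvdiaim=lvdiaim,
        missing_lobes=tuple(missing),
    )
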