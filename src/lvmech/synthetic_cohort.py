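"""Synthetic ventricle cohort with known ground truth.

Real exercise-echocardiography geometries are not publicly deposited, so every
downstream stage (volume curves, strain eigen-analysis, hemodynamic forces,
flow metrics, cohort statistics) is exercised on generated data with analytic
ground truth.

The ventricle is a half prolate spheroid (apex at -z, base plane at z = 0)
closed by a fan cap across the mitral annulus; the aortic orifice is a marked
circular sub-region of the cap. Deformation is an axisymmetric material map
combining longitudinal shortening, circumferential shortening and torsion,
driven by a piecewise-smooth volume waveform with a half-cosine systolic
ejection and E/A filling waves (Hann bumps in dV/dt) separated by a diastasis
that shrinks as heart rate rises. Because the scaling map is linear (and
torsion volume-preserving per z-plane), the mesh volume tracks the target
waveform exactly up to triangulation error, which cancels in volume ratios.

Also provided: analytic velocity-field fixtures (solid-body rotation, Hill's
spherical vortex) and a rigid-translation sequence, used as oracles for the
vorticity and hemodynamic-force integrals.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .mesh_kinematics import (
    Landmarks,
    MeshSequence,
    VolumeCurve,
    mesh_volume,
    volume_curve_from_samples,
)

__all__ = [
    "PhaseLabel",
    "VentricleSpec",
    "VolumeWaveform",
    "PHASE_DEFAULTS",
    "target_heart_rates",
    "generate_ventricle_sequence",
    "generate_cohort",
    "GridSpec",
    "GriddedVelocityField",
    "solid_body_rotation_field",
    "hill_vortex_field",
    "rigid_translation_sequence",
]


class PhaseLabel(str, Enum):
    """The five exercise-protocol acquisition phases plus the control group."""

    CONTROL = "Control"
    REST = "Rest"
    MID = "Mid"
    PEAK = "Peak"
    RECOVERY5 = "Recovery5"
    RECOVERY10 = "Recovery10"


def target_heart_rates(age: float, baseline_hr: float) -> tuple[float, float]:
    """Mid- and peak-exercise target heart rates (beats/min).

    peak = (220 - age) * 0.85; mid = (peak - baseline)/2 + baseline.
    """
    if not 0 < age < 120:
        raise ValueError(f"age must be in (0, 120) years, got {age}")
    if baseline_hr < 0:
        raise ValueError("baseline heart rate must be non-negative")
    peak = (220.0 - age) * 0.85
    if peak <= 0:
        raise ValueError("degenerate age: non-positive target heart rate")
    mid = (peak - baseline_hr) / 2.0 + baseline_hr
    return mid, peak


@dataclass(frozen=True)
class VentricleSpec:
    """Parameters of one synthetic ventricle cycle.

    EDV/ESV in mL, HR in beats/min, ``e_a_ratio`` the E:A peak dV/dt ratio,
    ``systolic_fraction`` the fraction of the cycle spent ejecting,
    ``twist_deg`` the apex-base torsion at end systole, ``long_circ_split``
    in [0, 1] partitioning volumetric shortening between the longitudinal
    (1 = all longitudinal) and circumferential directions,
    ``activation_lead`` a transient extra longitudinal weighting at
    contraction onset (produces the early cross-direction stretch seen in
    secondary-strain time courses; 0 disables it).
    """

    edv: float = 90.0
    esv: float = 36.0
    hr: float = 76.0
    e_a_ratio: float = 1.6
    systolic_fraction: float = 0.375
    twist_deg: float = 12.0
    long_circ_split: float = 0.27
    activation_lead: float = 1.5
    n_frames: int = 32
    seed: int = 0
    long_axis_ratio: float = 2.0  # long-axis length / base radius
    n_long: int = 24  # mesh rings apex -> base
    n_circ: int = 48  # vertices per ring
    e_wave_fraction: float = 0.45  # of diastole
    a_wave_fraction: float = 0.30  # of diastole

    def __post_init__(self):
        if not self.edv > self.esv > 0:
            raise ValueError(f"need EDV > ESV > 0, got EDV={self.edv}, ESV={self.esv}")
        if self.hr <= 0:
            raise ValueError("heart rate must be positive")
        if self.e_a_ratio <= 0:
            raise ValueError("E/A ratio must be positive")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic fraction must be in (0, 1)")
        if not 0 <= self.long_circ_split <= 1:
            raise ValueError("long_circ_split must be in [0, 1]")
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if self.e_wave_fraction + self.a_wave_fraction >= 1.0:
            raise ValueError(
                "E and A wave fractions leave no diastasis: "
                f"{self.e_wave_fraction} + {self.a_wave_fraction} >= 1"
            )

    @property
    def period(self) -> float:
        return 60.0 / self.hr


class VolumeWaveform:
    """Closed-form V(t) over one cycle for a :class:`VentricleSpec`.

    Systole [0, t_s]: half-cosine ejection EDV -> ESV. Diastole: dV/dt is the
    sum of an E-wave and an A-wave Hann bump whose peak ratio equals the
    specified E/A; the E wave starts at t_s, the A wave ends at T, and the
    flat diastasis between them shrinks with the diastolic duration (i.e. as
    heart rate rises).
    """

    def __init__(self, spec: VentricleSpec):
        self.spec = spec
        T = spec.period
        self.T = T
        self.t_s = spec.systolic_fraction * T
        td = T - self.t_s
        self.w_e = spec.e_wave_fraction * td
        self.w_a = spec.a_wave_fraction * td
        self.t_e0 = self.t_s
        self.t_a0 = T - self.w_a
        sv = spec.edv - spec.esv
        # Hann bump peak p over width w has area p*w/2; areas must sum to SV
        self.p_a = 2.0 * sv / (spec.e_a_ratio * self.w_e + self.w_a)
        self.p_e = spec.e_a_ratio * self.p_a
        resid = self.volume(T - 1e-12) - spec.edv
        if abs(resid) > 1e-6 * spec.edv:
            raise ValueError(
                f"waveform failed to return to EDV (residual {resid:.3g} mL) "
                f"for spec {spec}"
            )

    @staticmethod
    def _bump(x):
        x = np.asarray(x, float)
        return np.where((x >= 0) & (x <= 1), np.sin(np.pi * np.clip(x, 0, 1)) ** 2, 0.0)

    @staticmethod
    def _bump_integral(x):
        # integral of sin^2(pi u) du from 0 to x, clipped to [0, 1]
        x = np.clip(np.asarray(x, float), 0.0, 1.0)
        return x / 2.0 - np.sin(2 * np.pi * x) / (4 * np.pi)

    def dvdt(self, t):
        """dV/dt in mL/s (array-safe), periodic in T."""
        t = np.asarray(t, float) % self.T
        s = self.spec
        sv = s.edv - s.esv
        sys_part = np.where(
            t < self.t_s,
            -(sv * np.pi / (2 * self.t_s)) * np.sin(np.pi * np.clip(t, 0, self.t_s) / self.t_s),
            0.0,
        )
        dia = self.p_e * self._bump((t - self.t_e0) / self.w_e) + self.p_a * self._bump(
            (t - self.t_a0) / self.w_a
        )
        return sys_part + np.where(t >= self.t_s, dia, 0.0)

    def volume(self, t):
        """V(t) in mL (array-safe), periodic in T."""
        t = np.asarray(t, float) % self.T
        s = self.spec
        sv = s.edv - s.esv
        v_sys = s.edv - sv * (1 - np.cos(np.pi * np.clip(t, 0, self.t_s) / self.t_s)) / 2
        fill = self.p_e * self.w_e * self._bump_integral(
            (t - self.t_e0) / self.w_e
        ) + self.p_a * self.w_a * self._bump_integral((t - self.t_a0) / self.w_a)
        return np.where(t < self.t_s, v_sys, s.esv + fill)

    def ground_truth_curve(self, n_dense: int = 1024) -> VolumeCurve:
        t = np.linspace(0.0, self.T, n_dense, endpoint=False)
        return volume_curve_from_samples(t, self.volume(t), self.T, n_dense=n_dense)


# ---------------------------------------------------------------------------
# mesh construction


def _spheroid_template(spec: VentricleSpec):
    """Reference (end-diastolic) half-spheroid mesh sized so the enclosed
    analytic volume equals EDV. Returns vertices, triangles, orifice triangle
    ids and landmark coordinates."""
    edv_mm3 = spec.edv * 1000.0
    # (2/3) pi R^2 L = EDV with L = ratio * R
    R = (3.0 * edv_mm3 / (2.0 * np.pi * spec.long_axis_ratio)) ** (1.0 / 3.0)
    L = spec.long_axis_ratio * R

    nl, nc = spec.n_long, spec.n_circ
    psi = np.linspace(0.0, np.pi / 2.0, nl + 1)[1:]  # rings, apex excluded
    theta = 2 * np.pi * np.arange(nc) / nc
    rings = np.empty((nl, nc, 3))
    rings[..., 0] = (R * np.sin(psi))[:, None] * np.cos(theta)[None, :]
    rings[..., 1] = (R * np.sin(psi))[:, None] * np.sin(theta)[None, :]
    rings[..., 2] = (-L * np.cos(psi))[:, None]

    apex = np.array([[0.0, 0.0, -L]])
    cap_center = np.array([[0.0, 0.0, 0.0]])
    vertices = np.concatenate([apex, rings.reshape(-1, 3), cap_center], axis=0)
    i_apex = 0
    i_cap = len(vertices) - 1

    def ring(i, j):  # ring index i (0-based), circumferential j
        return 1 + i * nc + (j % nc)

    tris = []
    for j in range(nc):  # apex fan
        tris.append([i_apex, ring(0, j), ring(0, j + 1)])
    for i in range(nl - 1):  # wall strips, winding consistent with the fans
        for j in range(nc):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            tris.append([b, a, c])
            tris.append([b, c, d])
    cap_start = len(tris)
    for j in range(nc):  # annulus fan cap
        tris.append([i_cap, ring(nl - 1, j + 1), ring(nl - 1, j)])
    triangles = np.asarray(tris, np.int64)

    if mesh_volume(vertices, triangles, allow_inverted=True) < 0:
        triangles = triangles[:, ::-1]
        cap_start = cap_start  # flip preserves ordering

    # aortic orifice: cap triangles whose centroid lies in a circle of radius
    # 0.35 R centered at (0.45 R, 0) on the base plane
    cap_ids = np.arange(cap_start, len(triangles))
    cap_centroids = vertices[triangles[cap_ids]].mean(axis=1)
    ao_center = np.array([0.45 * R, 0.0, 0.0])
    in_ao = np.linalg.norm(cap_centroids[:, :2] - ao_center[:2], axis=1) <= 0.35 * R
    av_tris = cap_ids[in_ao]
    mv_tris = np.concatenate([np.arange(cap_start), cap_ids[~in_ao]])

    landmarks0 = {
        "annulus_center": np.array([0.0, 0.0, 0.0]),
        "aortic_center": ao_center,
        "apex": np.array([0.0, 0.0, -L]),
    }
    return vertices, triangles, av_tris, mv_tris, landmarks0, L


def _deform(points0, L, wave: VolumeWaveform, t):
    """Axisymmetric material map at time t applied to reference points."""
    s = wave.spec
    g = float(wave.volume(t)) / s.edv  # volume ratio, lambda_L * lambda_C^2
    c = (s.edv - float(wave.volume(t))) / (s.edv - s.esv)  # contraction phase
    split = s.long_circ_split + s.activation_lead * max(0.0, 1.0 - c) * (
        1.0 if c > 1e-12 else 0.0
    )
    lam_l = g**split
    lam_c = g ** ((1.0 - split) / 2.0)

    p = points0.copy()
    depth = -points0[:, 2] / L  # 0 at base, 1 at apex (material coordinate)
    p[:, 0] = lam_c * points0[:, 0]
    p[:, 1] = lam_c * points0[:, 1]
    p[:, 2] = lam_l * points0[:, 2]
    alpha = np.deg2rad(s.twist_deg) * c * depth
    ca, sa = np.cos(alpha), np.sin(alpha)
    x, y = p[:, 0].copy(), p[:, 1].copy()
    p[:, 0] = ca * x - sa * y
    p[:, 1] = sa * x + ca * y
    return p


def generate_ventricle_sequence(
    spec: VentricleSpec,
) -> tuple[MeshSequence, Landmarks, VolumeCurve]:
    """Generate one cycle: mesh sequence, per-frame landmarks and the dense
    ground-truth volume curve. Deterministic for identical specs."""
    wave = VolumeWaveform(spec)
    verts0, triangles, av_tris, mv_tris, lm0, L = _spheroid_template(spec)
    times = np.linspace(0.0, spec.period, spec.n_frames, endpoint=False)

    frames = np.empty((spec.n_frames, len(verts0), 3))
    lm_pts = np.stack([lm0["annulus_center"], lm0["aortic_center"], lm0["apex"]])
    lm_frames = np.empty((spec.n_frames, 3, 3))
    for i, t in enumerate(times):
        frames[i] = _deform(verts0, L, wave, t)
        lm_frames[i] = _deform(lm_pts, L, wave, t)

    seq = MeshSequence(
        frames,
        triangles,
        times,
        spec.period,
        metadata={
            "spec": _spec_to_dict(spec),
            "av_triangles": av_tris.tolist(),
            "mv_triangles": mv_tris.tolist(),
        },
    )
    landmarks = Landmarks(lm_frames[:, 0], lm_frames[:, 1], lm_frames[:, 2])
    return seq, landmarks, wave.ground_truth_curve()


def _spec_to_dict(spec: VentricleSpec) -> dict:
    return {
        k: getattr(spec, k)
        for k in (
            "edv", "esv", "hr", "e_a_ratio", "systolic_fraction", "twist_deg",
            "long_circ_split", "activation_lead", "n_frames", "seed",
            "long_axis_ratio", "n_long", "n_circ",
            "e_wave_fraction", "a_wave_fraction",
        )
    }


# ---------------------------------------------------------------------------
# cohort sampling

# Per-phase study conditions: HR, EDV, ESV and EF as published mean +/- SD
# for the exercise protocol cohort; frame counts per cycle as acquired per
# phase; E/A at the single value reported per phase (no spread published; a
# 15% relative SD is used for inter-subject variability). Systolic fraction
# rises with heart rate (diastole shortens preferentially). By default ESV is
# derived from correlated (EDV, EF) draws — EDV and ESV covary strongly
# within subjects, and independent draws would misstate the EF spread; the
# independent esv entry is used only when explicitly overridden.
PHASE_DEFAULTS: dict[PhaseLabel, dict] = {
    PhaseLabel.CONTROL: dict(hr=(77, 9), edv=(89, 21), esv=(35, 13), ef=(61, 4),
                             n_frames=(32, 5), e_a_ratio=1.6, systolic_fraction=0.375),
    PhaseLabel.REST: dict(hr=(76, 11), edv=(90, 24), esv=(36, 10), ef=(59, 4),
                          n_frames=(26, 7), e_a_ratio=1.6, systolic_fraction=0.375),
    PhaseLabel.MID: dict(hr=(141, 19), edv=(81, 31), esv=(27, 8), ef=(65, 6),
                         n_frames=(12, 1), e_a_ratio=6.3, systolic_fraction=0.45),
    PhaseLabel.PEAK: dict(hr=(174, 10), edv=(66, 19), esv=(21, 6.4), ef=(68, 4),
                          n_frames=(11, 1), e_a_ratio=1.5, systolic_fraction=0.50),
    PhaseLabel.RECOVERY5: dict(hr=(102, 11), edv=(79, 17), esv=(32, 6), ef=(59, 2),
                               n_frames=(17, 2), e_a_ratio=1.1, systolic_fraction=0.40),
    PhaseLabel.RECOVERY10: dict(hr=(100, 12), edv=(86, 19), esv=(37, 8), ef=(57, 2),
                                n_frames=(19, 4), e_a_ratio=1.2, systolic_fraction=0.40),
}

_EA_REL_SD = 0.15
_MAX_REDRAWS = 100


def _truncnorm(rng, mean, sd, lo=-np.inf, hi=np.inf):
    """One draw from N(mean, sd) truncated to [max(lo, mean-3sd), min(hi, mean+3sd)]."""
    if sd < 0:
        raise ValueError("SD must be >= 0")
    if sd == 0:
        return float(mean)
    lo = max(lo, mean - 3 * sd)
    hi = min(hi, mean + 3 * sd)
    for _ in range(_MAX_REDRAWS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError(f"truncated-normal draw failed for mean={mean}, sd={sd}")


def sample_spec(rng, phase: PhaseLabel, params: dict | None = None, *,
                seed: int = 0) -> VentricleSpec:
    """Draw one subject's :class:`VentricleSpec` for a phase from truncated
    normals (+/- 3 SD, physiologic floors); redraw on ESV >= 0.9 EDV."""
    p = dict(PHASE_DEFAULTS[phase])
    if params:
        p.update(params)
    esv_independent = params is not None and "esv" in params
    for _ in range(_MAX_REDRAWS):
        hr = _truncnorm(rng, *p["hr"], lo=30.0)
        edv = _truncnorm(rng, *p["edv"], lo=20.0)
        if esv_independent:
            esv = _truncnorm(rng, *p["esv"], lo=5.0)
        else:
            ef = _truncnorm(rng, *p["ef"], lo=15.0, hi=90.0)
            esv = edv * (1.0 - ef / 100.0)
        if 5.0 < esv < 0.9 * edv:
            break
    else:
        raise RuntimeError(f"could not draw ESV < 0.9 EDV for phase {phase}")
    ea = _truncnorm(rng, p["e_a_ratio"], _EA_REL_SD * p["e_a_ratio"], lo=0.3)
    nf = max(10, int(round(_truncnorm(rng, *p["n_frames"], lo=10))))
    return VentricleSpec(
        edv=edv, esv=esv, hr=hr, e_a_ratio=ea,
        systolic_fraction=p["systolic_fraction"],
        twist_deg=_truncnorm(rng, 12.0, 3.0, lo=0.0),
        long_circ_split=_truncnorm(rng, 0.27, 0.05, lo=0.0, hi=1.0),
        n_frames=nf, seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    phase_params: dict | None = None,
    seed: int = 0,
    phases: tuple[PhaseLabel, ...] = (
        PhaseLabel.REST, PhaseLabel.MID, PhaseLabel.PEAK,
        PhaseLabel.RECOVERY5, PhaseLabel.RECOVERY10,
    ),
) -> list[tuple[str, PhaseLabel, VentricleSpec]]:
    """Draw per-subject, per-phase specs (reproducible by seed).

    ``phase_params`` optionally overrides :data:`PHASE_DEFAULTS` entries per
    phase. Returns (subject id, phase, spec) records; meshes are generated
    lazily with :func:`generate_ventricle_sequence`.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_subjects):
        sid = f"S{k:03d}"
        for phase in phases:
            overrides = (phase_params or {}).get(phase, None)
            spec = sample_spec(rng, phase, overrides, seed=seed)
            records.append((sid, phase, spec))
    return records


# ---------------------------------------------------------------------------
# analytic velocity-field fixtures


@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian grid: ``n`` nodes per axis spanning [-extent, extent]
    in each direction (node-centered, endpoints excluded by half a cell so no
    node sits exactly on symmetry planes)."""

    n: int = 48
    extent: float = 1.2

    def coords(self):
        h = 2 * self.extent / self.n
        x = -self.extent + (np.arange(self.n) + 0.5) * h
        return np.meshgrid(x, x, x, indexing="ij"), h


@dataclass
class GriddedVelocityField:
    """Cartesian-sampled velocity with a ventricle (or fixture) mask.

    ``velocity`` has shape (nx, ny, nz, 3) for a single snapshot or
    (nt, nx, ny, nz, 3) for a time series; ``mask`` is boolean (nx, ny, nz);
    ``spacing`` is the isotropic grid spacing.
    """

    velocity: np.ndarray
    mask: np.ndarray
    spacing: float
    times: np.ndarray | None = None

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not self.mask.any():
            raise ValueError("empty mask")


def solid_body_rotation_field(
    omega: float, grid: GridSpec = GridSpec(), mask_radius: float = 1.0
) -> GriddedVelocityField:
    """v = Omega x-hat-z cross x everywhere; spherical mask. The vorticity
    modulus is exactly 2*Omega inside — the standard curl oracle."""
    if mask_radius > grid.extent:
        raise ValueError("mask exceeds grid bounds")
    (X, Y, Z), h = grid.coords()
    v = np.stack([-omega * Y, omega * X, np.zeros_like(X)], axis=-1)
    mask = X**2 + Y**2 + Z**2 <= mask_radius**2
    return GriddedVelocityField(v, mask, h)


def hill_vortex_field(
    U: float, a: float, grid: GridSpec = GridSpec()
) -> GriddedVelocityField:
    """Hill's spherical vortex of radius ``a`` and strength ``U`` (frame of
    the vortex: uniform stream -U at infinity, recirculating interior).

    Interior vorticity is azimuthal with modulus (15 U / 2 a^2) * sigma, so the
    volume-mean modulus over the sphere is (45 pi / 32) * U / a.
    """
    if U <= 0 or a <= 0:
        raise ValueError("U and a must be positive")
    if a > grid.extent:
        raise ValueError("vortex radius exceeds grid bounds")
    (X, Y, Z), h = grid.coords()
    sigma2 = X**2 + Y**2
    r2 = sigma2 + Z**2
    r = np.sqrt(r2)
    inside = r2 <= a**2

    # Stokes streamfunction psi_in = (3U/4) sigma^2 (1 - r^2/a^2)
    uz_in = 1.5 * U * (1.0 - (2.0 * sigma2 + Z**2) / a**2)
    us_in = 1.5 * U * Z / a**2  # u_sigma / sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - a**3 / r**3
        uz_out = -U * f - 1.5 * U * a**3 * sigma2 / r**5
        us_out = 1.5 * U * a**3 * Z / r**5  # u_sigma / sigma
    uz = np.where(inside, uz_in, uz_out)
    us_over_sigma = np.where(inside, us_in, us_out)
    v = np.stack([us_over_sigma * X, us_over_sigma * Y, uz], axis=-1)
    return GriddedVelocityField(v, inside, h)


def rigid_translation_sequence(
    accel_profile,
    base_points: np.ndarray,
    triangles: np.ndarray,
    period: float,
    n_frames: int = 32,
) -> MeshSequence:
    """Translate a closed mesh rigidly with the given periodic acceleration
    profile ``a(t) -> (3,)`` (mm/s^2). Displacement is obtained by spectral
    double integration of the sampled profile (mean acceleration removed, so
    the motion is periodic); the enclosed volume is constant over time.

    The net force on such a surface is rho * V * a(t), which makes this the
    sign-and-scale oracle for the hemodynamic-force boundary integral.
    """
    times = np.linspace(0.0, period, n_frames, endpoint=False)
    acc = np.array([np.asarray(accel_profile(t), float) for t in times])
    if acc.shape != (n_frames, 3):
        raise ValueError("accel_profile must return a 3-vector")
    acc = acc - acc.mean(axis=0)  # periodicity requires zero-mean acceleration
    k = np.fft.fftfreq(n_frames, d=period / n_frames) * 2j * np.pi
    k[0] = 1.0  # DC handled separately (zero)
    acc_hat = np.fft.fft(acc, axis=0)
    disp_hat = acc_hat / k[:, None] ** 2
    disp_hat[0] = 0.0
    disp = np.real(np.fft.ifft(disp_hat, axis=0))
    vertices = base_points[None, :, :] + disp[:, None, :]
    return MeshSequence(vertices, triangles, times, period)
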