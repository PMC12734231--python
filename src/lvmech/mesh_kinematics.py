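"""Endocardial mesh-sequence kinematics.

A cardiac cycle is represented as a closed triangulated surface with fixed
connectivity and per-frame vertex positions (one material point per vertex).
This module provides the containers (:class:`MeshSequence`, :class:`Landmarks`,
:class:`VolumeCurve`), divergence-theorem volumes, volume-curve analysis with
E/A-wave detection on dV/dt, rigid registration to the anatomical frame
(apex at -z, base at +z, aortic outlet toward +x), periodic cycle resampling
and cohort averaging, plus PLY + JSON sidecar I/O.

Units: coordinates in mm, volumes in mL, time in s. Conversions happen only
at I/O boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

__all__ = [
    "MeshSequence",
    "Landmarks",
    "VolumeCurve",
    "QCWarning",
    "mesh_volume",
    "surface_area_centroid",
    "volume_curve",
    "volume_curve_from_samples",
    "register",
    "resample_cycle",
    "average_cohort",
    "write_mesh_sequence",
    "read_mesh_sequence",
]

MIN_FRAMES = 10  # below this, wall-motion analysis is considered unreliable


class QCWarning(UserWarning):
    """Quality-control warning (e.g. fewer frames than the reliability floor)."""


@dataclass
class MeshSequence:
    """One cardiac cycle of a closed triangulated endocardial surface.

    Attributes
    ----------
    vertices : (n_frames, n_vertices, 3) float array, mm
    triangles : (n_triangles, 3) int array, outward-oriented, fixed over time
    times : (n_frames,) float array, s; times[0] == 0 and times[-1] < period
    period : heartbeat period T in s
    """

    vertices: np.ndarray
    triangles: np.ndarray
    times: np.ndarray
    period: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError("vertices must have shape (n_frames, n_vertices, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must have shape (n_triangles, 3)")
        if len(self.times) != self.n_frames:
            raise ValueError("times length must match the number of frames")
        if self.n_frames and (self.times[0] != 0.0 or self.times[-1] >= self.period):
            raise ValueError("times must start at 0 and end before the period T")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.vertices[i]

    def validate_watertight(self) -> None:
        """Raise if the surface is not closed and consistently oriented.

        Every undirected edge must be shared by exactly two triangles and every
        directed edge must appear exactly once (consistent winding).
        """
        tri = self.triangles
        edges = np.concatenate(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
        )
        directed = edges[:, 0] * (tri.max() + 1) + edges[:, 1]
        if len(np.unique(directed)) != len(directed):
            raise ValueError("inconsistent orientation: duplicated directed edge")
        undirected = np.sort(edges, axis=1)
        _, counts = np.unique(undirected, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("surface is not watertight: edge not shared by 2 faces")


@dataclass
class Landmarks:
    """Per-frame anatomical landmarks: mitral-annulus center, aortic-orifice
    center and apex, each of shape (n_frames, 3), mm."""

    annulus_center: np.ndarray
    aortic_center: np.ndarray
    apex: np.ndarray

    def __post_init__(self):
        self.annulus_center = np.atleast_2d(np.asarray(self.annulus_center, float))
        self.aortic_center = np.atleast_2d(np.asarray(self.aortic_center, float))
        self.apex = np.atleast_2d(np.asarray(self.apex, float))
        for a in (self.annulus_center, self.aortic_center, self.apex):
            if not np.all(np.isfinite(a)):
                raise ValueError("landmarks must be finite")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Landmarks":
        return Landmarks(
            self.annulus_center @ R.T + t,
            self.aortic_center @ R.T + t,
            self.apex @ R.T + t,
        )


@dataclass
class VolumeCurve:
    """Volume curve of one cycle with filling-wave indices.

    ``times``/``volume``/``dvdt`` are a dense periodic resampling of the frame
    volumes (used for extremum and peak detection); the raw per-frame samples
    are kept in ``frame_times``/``frame_volumes``.

    E and A peaks are the two largest positive local maxima of dV/dt in
    diastole, ordered by time; ``e_a_ratio`` is their ratio on dV/dt (mL/s).
    ``t_e`` is the E-wave period from its onset (last non-positive point of
    dV/dt before the E peak) to the E-A local minimum. When the two filling
    waves merge into a single lobe, ``a_peak`` and ``e_a_ratio`` are NaN and
    ``merged_filling_waves`` is set.
    """

    times: np.ndarray
    volume: np.ndarray
    dvdt: np.ndarray
    period: float
    frame_times: np.ndarray
    frame_volumes: np.ndarray
    i_ed: int
    i_es: int
    edv: float
    esv: float
    e_peak: float
    a_peak: float
    e_a_ratio: float
    t_e: float
    t_e_window: tuple
    merged_filling_waves: bool = False

    @property
    def stroke_volume(self) -> float:
        return self.edv - self.esv

    @property
    def ejection_fraction(self) -> float:
        """EF = (EDV - ESV)/EDV, dimensionless (multiply by 100 for %)."""
        return (self.edv - self.esv) / self.edv

    @property
    def t_ed(self) -> float:
        return float(self.times[self.i_ed])

    @property
    def t_es(self) -> float:
        return float(self.times[self.i_es])

    def frame_index_ed(self) -> int:
        return int(np.argmax(self.frame_volumes))

    def frame_index_es(self) -> int:
        return int(np.argmin(self.frame_volumes))


# ---------------------------------------------------------------------------
# volumes


def _signed_volume_mm3(points: np.ndarray, triangles: np.ndarray) -> float:
    p = points[triangles]
    return float(np.einsum("ij,ij->", np.cross(p[:, 0], p[:, 1]), p[:, 2]) / 6.0)


def mesh_volume(points: np.ndarray, triangles: np.ndarray, *, allow_inverted: bool = False) -> float:
    """Divergence-theorem volume of a closed triangulated surface, in mL.

    Positive for outward orientation; an inward-oriented (negative) surface
    raises unless ``allow_inverted`` is set, in which case the signed value is
    returned.
    """
    v_ml = _signed_volume_mm3(np.asarray(points, float), np.asarray(triangles)) / 1000.0
    if v_ml <= 0 and not allow_inverted:
        raise ValueError(
            f"non-positive enclosed volume ({v_ml:.3f} mL): surface is inward-"
            "oriented or not closed"
        )
    return v_ml


def surface_area_centroid(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of the surface (the 'geometric center'), mm."""
    p = np.asarray(points, float)[triangles]
    centroids = p.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    return (centroids * areas[:, None]).sum(axis=0) / areas.sum()


# ---------------------------------------------------------------------------
# volume curve and E/A analysis


def _periodic_spline(times: np.ndarray, values: np.ndarray, period: float) -> CubicSpline:
    t_ext = np.append(times, times[0] + period)
    v_ext = np.concatenate([values, values[:1]], axis=0)
    return CubicSpline(t_ext, v_ext, axis=0, bc_type="periodic")


def volume_curve_from_samples(
    times: np.ndarray,
    volumes: np.ndarray,
    period: float,
    *,
    n_dense: int = 1024,
) -> VolumeCurve:
    """Build a :class:`VolumeCurve` from sampled V(t) over one cycle.

    The samples are interpolated with a periodic cubic spline, resampled on a
    dense uniform grid and differentiated analytically (spline derivative);
    ED/ES and the E/A filling peaks are detected on the dense curve.
    """
    times = np.asarray(times, float)
    volumes = np.asarray(volumes, float)
    if len(times) < 4:
        raise ValueError("need at least 4 volume samples")
    spline = _periodic_spline(times, volumes, period)
    td = np.linspace(0.0, period, n_dense, endpoint=False)
    v = spline(td)
    dv = spline(td, 1)

    i_ed = int(np.argmax(v))
    i_es = int(np.argmin(v))
    if i_ed == i_es:
        raise ValueError("degenerate volume curve: ED and ES coincide")
    edv, esv = float(v[i_ed]), float(v[i_es])

    # diastole: from ES to ED going forward in (periodic) time
    n_dia = (i_ed - i_es) % n_dense
    dia_idx = (i_es + np.arange(1, n_dia)) % n_dense
    dv_dia = dv[dia_idx]
    if not np.any(dv_dia > 0):
        raise ValueError("no positive dV/dt lobe found in diastole")

    floor = 0.005 * dv_dia.max()
    peaks, props = find_peaks(dv_dia, height=floor, prominence=floor)
    merged = False
    if len(peaks) == 0:  # monotone filling up to the ED sample
        peaks = np.array([int(np.argmax(dv_dia))])
        props = {"peak_heights": dv_dia[peaks]}
    if len(peaks) >= 2:
        order = np.argsort(props["peak_heights"])[::-1][:2]
        two = np.sort(peaks[order])  # ordered by time
        i_e_local, i_a_local = int(two[0]), int(two[1])
        e_peak = float(dv_dia[i_e_local])
        a_peak = float(dv_dia[i_a_local])
        e_a = e_peak / a_peak
    else:
        merged = True
        i_e_local = int(peaks[0])
        i_a_local = None
        e_peak = float(dv_dia[i_e_local])
        a_peak = float("nan")
        e_a = float("nan")

    # E-wave window: onset = last non-positive dV/dt point before the E peak;
    # end = E-A local minimum (or next non-positive point when A is absent).
    pre = np.nonzero(dv_dia[: i_e_local + 1] <= floor * 0.1)[0]
    i_on = int(pre[-1]) if len(pre) else 0
    if i_a_local is not None:
        i_end = i_e_local + int(np.argmin(dv_dia[i_e_local : i_a_local + 1]))
    else:
        post = np.nonzero(dv_dia[i_e_local:] <= floor * 0.1)[0]
        i_end = i_e_local + (int(post[0]) if len(post) else len(dv_dia) - 1 - i_e_local)
    dt = period / n_dense
    t_on = ((i_es + 1 + i_on) % n_dense) * dt
    t_end = ((i_es + 1 + i_end) % n_dense) * dt
    t_e = (t_end - t_on) % period

    return VolumeCurve(
        times=td,
        volume=v,
        dvdt=dv,
        period=period,
        frame_times=times,
        frame_volumes=volumes,
        i_ed=i_ed,
        i_es=i_es,
        edv=edv,
        esv=esv,
        e_peak=e_peak,
        a_peak=a_peak,
        e_a_ratio=e_a,
        t_e=float(t_e),
        t_e_window=(float(t_on), float(t_end)),
        merged_filling_waves=merged,
    )


def volume_curve(seq: MeshSequence, *, n_dense: int = 1024) -> VolumeCurve:
    """Volume curve of a mesh sequence (divergence-theorem frame volumes)."""
    if seq.n_frames < MIN_FRAMES:
        warnings.warn(
            f"sequence has {seq.n_frames} frames (< {MIN_FRAMES}); volume-curve "
            "analysis may be unreliable",
            QCWarning,
        )
    vols = np.array([mesh_volume(seq.frame(i), seq.triangles) for i in range(seq.n_frames)])
    return volume_curve_from_samples(seq.times, vols, seq.period, n_dense=n_dense)


# ---------------------------------------------------------------------------
# registration


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.isclose(c, -1.0):
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def register(seq: MeshSequence, landmarks: Landmarks, *, return_transform: bool = False):
    """Rigidly align a sequence to the anatomical reference frame.

    At the end-diastolic frame (max volume): the area-weighted surface centroid
    is translated to the origin; the long axis (annulus center -> apex) is
    aligned with -z so the apex points down and the base up; the roll about z
    is fixed so the aortic-orifice center projects onto the +x half-plane.
    The same rigid transform is applied to every frame and landmark.
    """
    vols = [mesh_volume(seq.frame(i), seq.triangles) for i in range(seq.n_frames)]
    i_ed = int(np.argmax(vols))
    axis = landmarks.apex[i_ed] - landmarks.annulus_center[i_ed]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate long axis: apex coincides with annulus center")
    center = surface_area_centroid(seq.frame(i_ed), seq.triangles)

    R1 = _rotation_between(axis / norm, np.array([0.0, 0.0, -1.0]))
    ao = R1 @ (landmarks.aortic_center[i_ed] - center)
    phi = np.arctan2(ao[1], ao[0])
    c, s = np.cos(-phi), np.sin(-phi)
    R2 = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    R = R2 @ R1
    t = -R @ center

    new_vertices = seq.vertices @ R.T + t
    out = MeshSequence(new_vertices, seq.triangles, seq.times, seq.period, dict(seq.metadata))
    new_lm = landmarks.transformed(R, t)
    if return_transform:
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = t
        return out, new_lm, T
    return out, new_lm


# ---------------------------------------------------------------------------
# resampling and cohort averaging


def resample_cycle(seq: MeshSequence, n_out: int, landmarks: Landmarks | None = None):
    """Periodic cubic-spline resampling of vertex trajectories to ``n_out``
    uniformly spaced phase points; the common clock is the phase fraction t/T."""
    if n_out < MIN_FRAMES:
        raise ValueError(f"n_out must be >= {MIN_FRAMES}, got {n_out}")
    t_new = np.linspace(0.0, seq.period, n_out, endpoint=False)
    spline = _periodic_spline(seq.times, seq.vertices, seq.period)
    out = MeshSequence(spline(t_new), seq.triangles, t_new, seq.period, dict(seq.metadata))
    if landmarks is None:
        return out
    lm = Landmarks(
        _periodic_spline(seq.times, landmarks.annulus_center, seq.period)(t_new),
        _periodic_spline(seq.times, landmarks.aortic_center, seq.period)(t_new),
        _periodic_spline(seq.times, landmarks.apex, seq.period)(t_new),
    )
    return out, lm


def average_cohort(sequences: list[MeshSequence]) -> MeshSequence:
    """Vertex-wise mean of registered sequences sharing topology and frame
    count (resample with :func:`resample_cycle` first if counts differ).

    The result is expressed on the phase-fraction clock with the mean period.
    """
    if not sequences:
        raise ValueError("empty cohort")
    ref = sequences[0]
    for s in sequences[1:]:
        if s.n_frames != ref.n_frames:
            raise ValueError("frame counts differ; resample_cycle the inputs first")
        if s.vertices.shape != ref.vertices.shape or not np.array_equal(
            s.triangles, ref.triangles
        ):
            raise ValueError("topology mismatch across cohort")
    mean_T = float(np.mean([s.period for s in sequences]))
    times = np.linspace(0.0, mean_T, ref.n_frames, endpoint=False)
    mean_vertices = np.mean([s.vertices for s in sequences], axis=0)
    return MeshSequence(mean_vertices, ref.triangles.copy(), times, mean_T)


# ---------------------------------------------------------------------------
# I/O: one ASCII PLY per frame + JSON sidecar


def _write_ply_double(path: Path, points: np.ndarray, triangles: np.ndarray) -> None:
    # ASCII PLY with double-precision vertices (stock exporters down-cast to
    # float32, breaking lossless round-trips); readable by any PLY reader
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(points)}",
        "property double x", "property double y", "property double z",
        f"element face {len(triangles)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in points]
    lines += [f"3 {a} {b} {c}" for a, b, c in triangles]
    path.write_text("\n".join(lines) + "\n")


def write_mesh_sequence(
    path,
    seq: MeshSequence,
    landmarks: Landmarks,
    *,
    extras: dict | None = None,
) -> Path:
    """Write one ASCII PLY file per frame plus a ``sequence.json`` sidecar
    carrying period, frame times, per-frame landmark coordinates and any extra
    metadata (phase label, generator spec, orifice triangle ids, seed...)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i in range(seq.n_frames):
        _write_ply_double(path / f"frame_{i:04d}.ply", seq.frame(i), seq.triangles)
    sidecar = {
        "format": "lvmech-mesh-sequence-v1",
        "period_s": seq.period,
        "times_s": seq.times.tolist(),
        "n_frames": seq.n_frames,
        "landmarks": {
            "annulus_center": landmarks.annulus_center.tolist(),
            "aortic_center": landmarks.aortic_center.tolist(),
            "apex": landmarks.apex.tolist(),
        },
        "metadata": extras or {},
    }
    (path / "sequence.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_mesh_sequence(path) -> tuple[MeshSequence, Landmarks]:
    """Read a sequence written by :func:`write_mesh_sequence`.

    Validates fixed topology across frames and watertightness, and attaches a
    ``qc_low_frame_count`` flag in ``seq.metadata`` (with a :class:`QCWarning`)
    when the cycle has fewer than 10 frames.
    """
    path = Path(path)
    sidecar_file = path / "sequence.json"
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    times = np.asarray(sidecar["times_s"], float)
    n_frames = int(sidecar["n_frames"])
    frames, triangles = [], None
    for i in range(n_frames):
        mesh = trimesh.load(path / f"frame_{i:04d}.ply", process=False)
        if triangles is None:
            triangles = np.asarray(mesh.faces, np.int64)
        elif not np.array_equal(np.asarray(mesh.faces, np.int64), triangles):
            raise ValueError(f"topology mismatch at frame {i}")
        frames.append(np.asarray(mesh.vertices, float))
    lm = sidecar["landmarks"]
    if not all(k in lm for k in ("annulus_center", "aortic_center", "apex")):
        raise ValueError("sidecar is missing landmarks")
    seq = MeshSequence(
        np.stack(frames), triangles, times, float(sidecar["period_s"]),
        dict(sidecar.get("metadata", {})),
    )
    seq.validate_watertight()
    if seq.n_frames < MIN_FRAMES:
        warnings.warn(
            f"{path.name}: {seq.n_frames} frames per cycle (< {MIN_FRAMES})",
            QCWarning,
        )
        seq.metadata["qc_low_frame_count"] = True
    landmarks = Landmarks(lm["annulus_center"], lm["aortic_center"], lm["apex"])
    return seq, landmarks
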