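"""Surface Lagrangian strain eigen-analysis.

Each triangle of the end-diastolic (maximum-volume) reference surface carries
an in-plane deformation gradient F mapping its reference edge vectors to the
current ones, expressed in an orthonormal tangent frame. The rotation-removed
right stretch U = sqrt(F^T F) defines the Lagrangian strain S = U - I. Its
eigenvalues, ordered lambda_p <= lambda_s, are the principal and secondary
strains (negative = shortening); the eigenvector of lambda_p, lifted back to
3D in the reference triangle plane, is the local strain-line direction.

Global quantities are reference-area-weighted surface means: GPS/GSS of the
two eigenvalues, GLS/GCS of the normal strain along the local longitudinal
(projection of the apex-base axis onto the triangle plane) and circumferential
(its in-plane orthogonal) directions. All are reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_kinematics import MeshSequence, mesh_volume

__all__ = [
    "SurfaceStrainField",
    "GlobalStrainSeries",
    "triangle_deformation_gradient",
    "principal_strain_field",
    "directional_strain",
    "global_strain_series",
]

_LONGITUDINAL = np.array([0.0, 0.0, 1.0])  # registered apex->base axis
_DEGENERATE_AREA = 1e-12
_MAX_MASKED_AREA_FRACTION = 0.01


@dataclass
class SurfaceStrainField:
    """Per-triangle strain state at one frame.

    ``tensor`` holds the symmetric 2x2 strain in the local tangent frame
    (components [S11, S22, S12]); eigenvalues satisfy lambda_p <= lambda_s;
    ``principal_dir``/``secondary_dir`` are 3D unit vectors tangent to the
    reference surface; ``ref_area`` is the reference triangle area in mm^2;
    masked (degenerate) triangles are excluded from global averages.
    """

    tensor: np.ndarray
    lambda_p: np.ndarray
    lambda_s: np.ndarray
    principal_dir: np.ndarray
    secondary_dir: np.ndarray
    ref_area: np.ndarray
    basis_t1: np.ndarray
    basis_t2: np.ndarray
    masked: np.ndarray

    @property
    def gps(self) -> float:
        """Reference-area-weighted mean principal strain, %."""
        return 100.0 * _area_mean(self.lambda_p, self.ref_area, self.masked)

    @property
    def gss(self) -> float:
        """Reference-area-weighted mean secondary strain, %."""
        return 100.0 * _area_mean(self.lambda_s, self.ref_area, self.masked)

    def to_dataframe(self):
        """Per-triangle table (triangle id, eigenvalues, strain-line direction)
        for CSV export / color-map rendering."""
        import pandas as pd

        return pd.DataFrame({
            "triangle": np.arange(len(self.lambda_p)),
            "lambda_p": self.lambda_p,
            "lambda_s": self.lambda_s,
            "dir_x": self.principal_dir[:, 0],
            "dir_y": self.principal_dir[:, 1],
            "dir_z": self.principal_dir[:, 2],
            "ref_area_mm2": self.ref_area,
            "masked": self.masked,
        })


@dataclass
class GlobalStrainSeries:
    """Time courses of the four global strains in % (0 at the ED reference)."""

    times: np.ndarray
    gps: np.ndarray
    gss: np.ndarray
    gls: np.ndarray
    gcs: np.ndarray
    i_ed: int
    i_es: int


def _area_mean(values, areas, masked):
    keep = ~masked
    if not keep.any():
        raise ValueError("all triangles are masked")
    return float(np.sum(values[keep] * areas[keep]) / np.sum(areas[keep]))


def _tangent_frames(ref_points: np.ndarray, triangles: np.ndarray):
    """Orthonormal tangent frame per reference triangle.

    t1 is the unit projection of the global longitudinal axis onto the
    triangle plane (falling back to the longest edge where the plane is
    nearly perpendicular to it); t2 = n x t1 (circumferential sense).
    """
    p = ref_points[triangles]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    n = np.cross(e1, e2)
    area = 0.5 * np.linalg.norm(n, axis=1)
    good = area > _DEGENERATE_AREA
    nhat = np.zeros_like(n)
    nhat[good] = n[good] / (2.0 * area[good])[:, None]

    proj = _LONGITUDINAL[None, :] - (nhat @ _LONGITUDINAL)[:, None] * nhat
    pnorm = np.linalg.norm(proj, axis=1)
    # fallback: longest edge when the plane is nearly horizontal
    e3 = p[:, 2] - p[:, 1]
    edges = np.stack([e1, e2, e3], axis=1)
    longest = edges[np.arange(len(p)), np.argmax(np.linalg.norm(edges, axis=2), axis=1)]
    use_fallback = pnorm < 1e-6
    t1 = np.where(use_fallback[:, None], longest, proj)
    t1 = t1 - (np.einsum("ij,ij->i", t1, nhat))[:, None] * nhat
    t1 /= np.maximum(np.linalg.norm(t1, axis=1), 1e-300)[:, None]
    t2 = np.cross(nhat, t1)
    return t1, t2, nhat, area, good


def _edges_2d(points, triangles, t1, t2):
    p = points[triangles]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    A = np.empty(triangles.shape[:1] + (2, 2))
    A[:, 0, 0] = np.einsum("ij,ij->i", e1, t1)
    A[:, 0, 1] = np.einsum("ij,ij->i", e2, t1)
    A[:, 1, 0] = np.einsum("ij,ij->i", e1, t2)
    A[:, 1, 1] = np.einsum("ij,ij->i", e2, t2)
    return A


def triangle_deformation_gradient(ref_triangle: np.ndarray, cur_triangle: np.ndarray) -> np.ndarray:
    """In-plane 2x2 deformation gradient of a single triangle.

    Maps reference edge vectors (in the reference tangent frame) to current
    edge vectors (in the current tangent frame). Rigid rotations of the
    current triangle do not affect U = sqrt(F^T F).
    """
    ref = np.asarray(ref_triangle, float)[None, :, :]
    cur = np.asarray(cur_triangle, float)[None, :, :]
    tris = np.array([[0, 1, 2]])
    t1r, t2r, _, area_r, good_r = _tangent_frames(ref.reshape(3, 3), tris)
    t1c, t2c, _, area_c, good_c = _tangent_frames(cur.reshape(3, 3), tris)
    if not (good_r[0] and good_c[0]):
        raise ValueError("degenerate triangle (zero area)")
    A = _edges_2d(ref.reshape(3, 3), tris, t1r, t2r)[0]
    B = _edges_2d(cur.reshape(3, 3), tris, t1c, t2c)[0]
    return B @ np.linalg.inv(A)


def _eig2_sym(c11, c22, c12):
    """Eigendecomposition of symmetric 2x2 matrices (vectorized).

    Returns (lo, hi, (vx, vy) of the *lo* eigenvector)."""
    tr = c11 + c22
    disc = np.sqrt(np.maximum((c11 - c22) ** 2 + 4 * c12**2, 0.0))
    lo = 0.5 * (tr - disc)
    hi = 0.5 * (tr + disc)
    # (C - lo I) v = 0 admits v = (lo - c22, c12) or (c12, lo - c11);
    # pick whichever has the larger norm for numerical safety
    ax, ay = lo - c22, c12
    bx, by = c12, lo - c11
    use_b = bx**2 + by**2 > ax**2 + ay**2
    vx = np.where(use_b, bx, ax)
    vy = np.where(use_b, by, ay)
    deg = disc <= 1e-9 * np.maximum(np.abs(tr), 1e-12)
    vx = np.where(deg, 1.0, vx)
    vy = np.where(deg, 0.0, vy)
    norm = np.sqrt(vx**2 + vy**2)
    norm = np.where(norm < 1e-300, 1.0, norm)
    return lo, hi, vx / norm, vy / norm, deg


def principal_strain_field(
    seq: MeshSequence, frame: int, ref_frame: int | None = None
) -> SurfaceStrainField:
    """Per-triangle Lagrangian strain of ``frame`` w.r.t. the ED reference.

    ``ref_frame`` defaults to the maximum-volume frame. Degenerate triangles
    are masked; more than 1% masked reference area raises.
    """
    if ref_frame is None:
        vols = [mesh_volume(seq.frame(i), seq.triangles) for i in range(seq.n_frames)]
        ref_frame = int(np.argmax(vols))
    ref = seq.frame(ref_frame)
    cur = seq.frame(frame)
    tris = seq.triangles

    t1r, t2r, nr, area_r, good_r = _tangent_frames(ref, tris)
    t1c, t2c, nc, area_c, good_c = _tangent_frames(cur, tris)
    masked = ~(good_r & good_c)
    if np.sum(area_r[masked]) > _MAX_MASKED_AREA_FRACTION * np.sum(area_r):
        raise ValueError("more than 1% of reference area is degenerate")

    A = _edges_2d(ref, tris, t1r, t2r)
    B = _edges_2d(cur, tris, t1c, t2c)
    detA = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    detA = np.where(masked, 1.0, detA)
    Ainv = np.empty_like(A)
    Ainv[:, 0, 0] = A[:, 1, 1] / detA
    Ainv[:, 0, 1] = -A[:, 0, 1] / detA
    Ainv[:, 1, 0] = -A[:, 1, 0] / detA
    Ainv[:, 1, 1] = A[:, 0, 0] / detA
    F = np.einsum("nij,njk->nik", B, Ainv)

    C = np.einsum("nji,njk->nik", F, F)  # F^T F (right Cauchy-Green)
    lo, hi, vx, vy, deg = _eig2_sym(C[:, 0, 0], C[:, 1, 1], C[:, 0, 1])
    lam_p = np.sqrt(np.maximum(lo, 0.0)) - 1.0
    lam_s = np.sqrt(np.maximum(hi, 0.0)) - 1.0

    # strain tensor S = U - I in the local frame, via U = (C + sqrt(det C) I)/tr(U)
    # (2x2 identity: U = (C + sqrt(detC) I) / sqrt(trC + 2 sqrt(detC)))
    detC = np.maximum(C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] ** 2, 0.0)
    sdet = np.sqrt(detC)
    denom = np.sqrt(np.maximum(C[:, 0, 0] + C[:, 1, 1] + 2 * sdet, 1e-300))
    S11 = (C[:, 0, 0] + sdet) / denom - 1.0
    S22 = (C[:, 1, 1] + sdet) / denom - 1.0
    S12 = C[:, 0, 1] / denom
    tensor = np.stack([S11, S22, S12], axis=1)

    # lift eigenvectors into 3D on the reference tangent plane
    p_dir = vx[:, None] * t1r + vy[:, None] * t2r
    s_dir = -vy[:, None] * t1r + vx[:, None] * t2r

    # tie-break near-equal eigenvalues: report the longitudinal-most direction
    # as principal so strain-lines stay well defined on isotropic patches
    if np.any(deg):
        long_t = _LONGITUDINAL[None, :]
        p_al = np.abs(np.einsum("ij,ij->i", p_dir, np.broadcast_to(long_t, p_dir.shape)))
        s_al = np.abs(np.einsum("ij,ij->i", s_dir, np.broadcast_to(long_t, s_dir.shape)))
        swap = deg & (s_al > p_al)
        p_dir[swap], s_dir[swap] = s_dir[swap], p_dir[swap].copy()

    return SurfaceStrainField(
        tensor=tensor,
        lambda_p=lam_p,
        lambda_s=lam_s,
        principal_dir=p_dir,
        secondary_dir=s_dir,
        ref_area=area_r,
        basis_t1=t1r,
        basis_t2=t2r,
        masked=masked,
    )


def directional_strain(
    field: SurfaceStrainField, direction: np.ndarray, *, tol: float = 1e-6
) -> np.ndarray:
    """Normal strain e . S e along a tangent ``direction``.

    ``direction`` may be a single 3-vector (projected per triangle) or an
    (n_triangles, 3) array of per-triangle tangent directions; a direction
    further than ``tol`` (after normalization) from any triangle plane raises.
    """
    d = np.asarray(direction, float)
    if d.ndim == 1:
        d = np.broadcast_to(d, field.basis_t1.shape)
    c1 = np.einsum("ij,ij->i", d, field.basis_t1)
    c2 = np.einsum("ij,ij->i", d, field.basis_t2)
    norm_in = np.sqrt(c1**2 + c2**2)
    norm_d = np.linalg.norm(d, axis=1)
    off_plane = norm_d - norm_in
    keep = ~field.masked
    if np.any(off_plane[keep] > np.maximum(tol, 1e-9) * np.maximum(norm_d[keep], 1e-300)):
        raise ValueError("direction is not tangent to the surface within tolerance")
    norm_in = np.where(norm_in < 1e-300, 1.0, norm_in)
    e1, e2 = c1 / norm_in, c2 / norm_in
    S11, S22, S12 = field.tensor[:, 0], field.tensor[:, 1], field.tensor[:, 2]
    return e1 * (S11 * e1 + S12 * e2) + e2 * (S12 * e1 + S22 * e2)


def global_strain_series(seq: MeshSequence, ref_frame: int | None = None) -> GlobalStrainSeries:
    """GPS/GSS/GLS/GCS time courses in %, zero at the ED reference frame.

    GLS/GCS probe the strain tensor along each triangle's local longitudinal
    and circumferential axes (the reference tangent frame itself), with
    reference-area weighting.
    """
    vols = np.array([mesh_volume(seq.frame(i), seq.triangles) for i in range(seq.n_frames)])
    if ref_frame is None:
        ref_frame = int(np.argmax(vols))
    i_es = int(np.argmin(vols))

    gps = np.empty(seq.n_frames)
    gss = np.empty(seq.n_frames)
    gls = np.empty(seq.n_frames)
    gcs = np.empty(seq.n_frames)
    for i in range(seq.n_frames):
        f = principal_strain_field(seq, i, ref_frame=ref_frame)
        gps[i] = f.gps
        gss[i] = f.gss
        gls[i] = 100.0 * _area_mean(
            directional_strain(f, f.basis_t1), f.ref_area, f.masked
        )
        gcs[i] = 100.0 * _area_mean(
            directional_strain(f, f.basis_t2), f.ref_area, f.masked
        )
    return GlobalStrainSeries(
        times=seq.times.copy(), gps=gps, gss=gss, gls=gls, gcs=gcs,
        i_ed=int(ref_frame), i_es=i_es,
    )
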