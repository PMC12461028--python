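"""Spherical-harmonic shape expansion of segmented objects.

A segmented object is reduced to its marching-cubes surface point cloud and
the radius function about its centroid is expanded in real orthonormal
spherical harmonics:

    r(theta, phi) = sum_{l=0}^{lmax} sum_{m=-l}^{l} c_{l,m} Y_{l,m}(theta, phi)

with the volume-equivalent radius r0 = c_{0,0} / sqrt(4 pi).  The expansion
is fit by damped linear least squares on the (irregular) surface vertices,
guarded against overfitting by requiring (lmax+1)^2 <= n_points.  Alignment
rotates each shape so that its most-compressed principal axis of the
degree-2 (quadrupole) deformation lies along z, the frame in which the
deformation parameter D = |c_{2,0}| / c_{0,0} is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from skimage.measure import marching_cubes

from . import _sh
from .imgseg import LabelMap3D

__all__ = [
    "SurfaceCloud",
    "SHExpansion",
    "extract_surface",
    "fit_sh",
    "power_spectrum",
    "equivalent_radius",
    "node_antinode_distance",
    "align_shape",
    "rotate_expansion",
    "quadrupole_tensor",
    "deformation_parameter",
    "expansions_to_frame",
]

MIN_SURFACE_POINTS = 8
#: largest spherical cap (half-angle, radians) allowed to be empty of points
MAX_EMPTY_CAP = np.deg2rad(60.0)


@dataclass
class SurfaceCloud:
    """Surface vertices of one object, Cartesian (x, y, z) in micrometers."""

    points: np.ndarray
    center: np.ndarray
    label_id: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) < MIN_SURFACE_POINTS:
            raise ValueError("degenerate object: fewer than 8 surface points")
        if np.any(np.linalg.norm(self.points - self.center, axis=1) == 0):
            raise ValueError("surface point coincides with the center")

    def spherical(self, center: np.ndarray | None = None):
        """(r, theta, phi) of every point about ``center`` (default: own)."""
        c = self.center if center is None else np.asarray(center, dtype=float)
        d = self.points - c
        r = np.linalg.norm(d, axis=1)
        theta = np.arccos(np.clip(d[:, 2] / r, -1.0, 1.0))
        phi = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * np.pi)
        return r, theta, phi

    def coverage_gap(self) -> float:
        """Largest empty-cap half-angle over a probe set of directions."""
        _, theta, phi = self.spherical()
        n = np.column_stack([
            np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta),
        ])
        probes = _fibonacci_sphere(128)
        cosmax = (probes @ n.T).max(axis=1)
        return float(np.arccos(np.clip(cosmax, -1.0, 1.0)).max())


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


@dataclass
class SHExpansion:
    """Real orthonormal SH coefficient table for one object.

    ``coeffs`` is flat in (l, m) order (index l^2 + l + m), in micrometers.
    ``aligned`` is set by :func:`align_shape`; the deformation parameter is
    only defined in that frame.
    """

    lmax: int
    coeffs: np.ndarray
    center: np.ndarray
    residual_rms: float = 0.0
    n_points: int = 0
    normalization: str = "real_orthonormal"
    aligned: bool = False
    label_id: int = 0
    flags: list[str] = dc_field(default_factory=list)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if len(self.coeffs) != _sh.n_modes(self.lmax):
            raise ValueError("coefficient table length does not match lmax")
        if self.coeffs[0] <= 0:
            raise ValueError("c_{0,0} must be positive")

    def coeff(self, l: int, m: int) -> float:
        return float(self.coeffs[_sh.mode_index(l, m)])

    def radius(self, theta, phi):
        return _sh.evaluate(self.coeffs, theta, phi)


def extract_surface(labels: LabelMap3D, label_id: int) -> SurfaceCloud:
    """Marching-cubes surface of one label, in physical micrometers.

    The cloud center is the (intensity-free) voxel centroid of the label.
    """
    mask = labels.labels == label_id
    if not mask.any():
        raise ValueError(f"label {label_id} not present in the label map")
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    crop = mask[tuple(slice(a, b) for a, b in zip(lo, hi))]
    padded = np.pad(crop.astype(float), 1)
    try:
        verts_zyx, _, _, _ = marching_cubes(
            padded, level=0.5, spacing=tuple(labels.voxel_size)
        )
    except (ValueError, RuntimeError) as exc:
        raise ValueError(f"degenerate object {label_id}: {exc}") from exc
    offset = (lo - 1) * labels.voxel_size
    verts_zyx = verts_zyx + offset
    points = verts_zyx[:, ::-1]  # (z, y, x) -> (x, y, z)
    centroid = (idx.mean(axis=0) * labels.voxel_size)[::-1]
    if len(points) < MIN_SURFACE_POINTS:
        raise ValueError(f"degenerate object {label_id}: fewer than 8 surface points")
    return SurfaceCloud(points=points, center=centroid, label_id=label_id)


def max_degree(n_points: int) -> int:
    """Largest degree admitted by the anti-overfit guard for n points."""
    return int(np.floor(np.sqrt(n_points))) - 1


def _lstsq_coeffs(r, theta, phi, lmax: int, damping: float = 1e-8) -> np.ndarray:
    A = _sh.design_matrix(lmax, theta, phi)
    ata = A.T @ A + damping * np.eye(A.shape[1])
    return np.linalg.solve(ata, A.T @ r)


@lru_cache(maxsize=1)
def _dipole_matrix() -> np.ndarray:
    """B with n_hat . e_i = sum_j B[i, j] Y_{1, m_j},  m_j in (-1, 0, 1)."""
    th, ph, w = _sh.gauss_sphere_grid(8, 16)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    n = np.stack([
        np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH),
    ])
    B = np.empty((3, 3))
    for j, m in enumerate((-1, 0, 1)):
        Y = _sh.real_sh(1, m, TH, PH)
        B[:, j] = np.sum(n * Y * w, axis=(1, 2))
    return B


def fit_sh(
    surface: SurfaceCloud,
    lmax: int,
    recenter: bool = True,
    check_coverage: bool = True,
) -> SHExpansion:
    """Damped least-squares SH fit of the radius function.

    Enforces the Nyquist-like guard (lmax+1)^2 <= n_points.  With
    ``recenter`` (default), one recentring step moves the expansion center
    by the displacement encoded in the degree-1 dipole and refits, which
    suppresses spurious l = 1 power from a center offset.
    """
    n = len(surface.points)
    if lmax < 0:
        raise ValueError("lmax must be non-negative")
    if _sh.n_modes(lmax) > n:
        raise ValueError(
            f"overfit guard: (lmax+1)^2 = {_sh.n_modes(lmax)} exceeds "
            f"{n} surface points; maximum admissible degree is {max_degree(n)}"
        )
    flags = []
    if check_coverage and surface.coverage_gap() > MAX_EMPTY_CAP:
        flags.append("poor_angular_coverage")

    center = surface.center.copy()
    r, theta, phi = surface.spherical(center)
    coeffs = _lstsq_coeffs(r, theta, phi, lmax)

    if recenter and lmax >= 1:
        c1 = coeffs[_sh.mode_index(1, -1):_sh.mode_index(1, 1) + 1]
        shift = np.linalg.solve(_dipole_matrix().T, c1)
        if np.linalg.norm(shift) > 1e-12:
            center = center + shift
            r, theta, phi = surface.spherical(center)
            coeffs = _lstsq_coeffs(r, theta, phi, lmax)
            flags.append("recentred")

    A = _sh.design_matrix(lmax, theta, phi)
    residual_rms = float(np.sqrt(np.mean((A @ coeffs - r) ** 2)))
    return SHExpansion(
        lmax=lmax, coeffs=coeffs, center=center,
        residual_rms=residual_rms, n_points=n,
        label_id=surface.label_id, flags=flags,
    )


def power_spectrum(exp: SHExpansion) -> np.ndarray:
    """Per-degree power P_l = sum_m c_{l,m}^2 (um^2), length lmax + 1."""
    return np.array([
        np.sum(exp.coeffs[l * l:(l + 1) ** 2] ** 2) for l in range(exp.lmax + 1)
    ])


def equivalent_radius(exp: SHExpansion) -> float:
    """Undeformed sphere radius r0 = c_{0,0} / sqrt(4 pi), by volume conservation."""
    return float(exp.coeffs[0] / np.sqrt(4.0 * np.pi))


def node_antinode_distance(r0: float, l: int) -> float:
    """Lateral resolution of degree l: d_NA = pi r0 / l."""
    if l < 1:
        raise ValueError("degree l = 0 has no angular nodes")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    return np.pi * r0 / l


@lru_cache(maxsize=1)
def _quadrupole_forms() -> np.ndarray:
    """Traceless symmetric M_m with n^T M_m n = Y_{2,m}(n), m = -2..2."""
    dirs = _fibonacci_sphere(400)
    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    phi = np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2 * np.pi)
    nx, ny, nz = dirs.T
    design = np.column_stack([
        nx**2, ny**2, nz**2, 2 * nx * ny, 2 * nx * nz, 2 * ny * nz,
    ])
    forms = np.empty((5, 3, 3))
    for j, m in enumerate(range(-2, 3)):
        Y = _sh.real_sh(2, m, theta, phi)
        p, *_ = np.linalg.lstsq(design, Y, rcond=None)
        forms[j] = [[p[0], p[3], p[4]], [p[3], p[1], p[5]], [p[4], p[5], p[2]]]
    return forms


def quadrupole_tensor(exp: SHExpansion) -> np.ndarray:
    """Symmetric traceless tensor Q with degree-2 radius part = n^T Q n."""
    if exp.lmax < 2:
        raise ValueError("degree-2 coefficients required (lmax >= 2)")
    c2 = exp.coeffs[_sh.mode_index(2, -2):_sh.mode_index(2, 2) + 1]
    return np.tensordot(c2, _quadrupole_forms(), axes=1)


def rotate_expansion(exp: SHExpansion, rotation: np.ndarray) -> SHExpansion:
    """Coefficients of the actively rotated body, by exact quadrature.

    The rotated radius function is f'(n) = f(R^T n); projecting it back on
    the SH basis with a Gauss-Legendre x uniform-azimuth rule of sufficient
    resolution is exact for band-limited f, so this equals an analytic
    Wigner-D rotation to machine precision.
    """
    R = np.asarray(rotation, dtype=float)
    lmax = exp.lmax
    th, ph, w = _sh.gauss_sphere_grid(lmax + 2, 2 * lmax + 4)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    n = np.stack([
        np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH),
    ], axis=-1)
    nr = n @ R  # rows of n times R: (R^T n)
    th_r = np.arccos(np.clip(nr[..., 2], -1.0, 1.0))
    ph_r = np.mod(np.arctan2(nr[..., 1], nr[..., 0]), 2 * np.pi)
    f = _sh.evaluate(exp.coeffs, th_r, ph_r)
    coeffs = np.array([
        np.sum(f * _sh.real_sh(l, m, TH, PH) * w) for l, m in _sh.mode_list(lmax)
    ])
    return SHExpansion(
        lmax=lmax, coeffs=coeffs, center=exp.center.copy(),
        residual_rms=exp.residual_rms, n_points=exp.n_points,
        normalization=exp.normalization, aligned=exp.aligned,
        label_id=exp.label_id, flags=list(exp.flags),
    )


def _c20_after(exp: SHExpansion, rotation: np.ndarray) -> float:
    """c_{2,0} of the rotated body (projection of degree-2 part only)."""
    th, ph, w = _sh.gauss_sphere_grid(exp.lmax + 2, 2 * exp.lmax + 4)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    n = np.stack([
        np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH),
    ], axis=-1)
    nr = n @ np.asarray(rotation)
    th_r = np.arccos(np.clip(nr[..., 2], -1.0, 1.0))
    ph_r = np.mod(np.arctan2(nr[..., 1], nr[..., 0]), 2 * np.pi)
    f = _sh.evaluate(exp.coeffs, th_r, ph_r)
    return float(np.sum(f * _sh.real_sh(2, 0, TH, PH) * w))


def _rotation_mapping_to_z(v: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Proper rotation R with R v = z_hat, using ``other`` for the x row."""
    v = v / np.linalg.norm(v)
    a = other - (other @ v) * v
    a /= np.linalg.norm(a)
    # deterministic in-plane sign so the rotation (hence alignment) is unique
    if a[np.argmax(np.abs(a))] < 0:
        a = -a
    b = np.cross(v, a)
    return np.array([a, b, v])


#: degree-2 power below which a shape counts as spherical for alignment
P2_SPHERICAL_TOL = 1e-10


def align_shape(
    exp: SHExpansion, tol: float = P2_SPHERICAL_TOL, verify: bool = True
):
    """Rotate the expansion into the frame minimizing c_{2,0}.

    The five degree-2 coefficients define a symmetric traceless quadrupole
    tensor; its eigenvector of most negative radial perturbation (smallest
    eigenvalue) is mapped to the z axis, which minimizes c_{2,0} over all
    rotations.  Near-spherical shapes (P_2 < tol) get the identity rotation
    and a ``degenerate_quadrupole`` flag.

    Returns ``(aligned_expansion, rotation_matrix)``.
    """
    if exp.lmax < 2:
        raise ValueError("alignment requires lmax >= 2")
    P2 = power_spectrum(exp)[2]
    if P2 < tol:
        out = SHExpansion(
            lmax=exp.lmax, coeffs=exp.coeffs.copy(), center=exp.center.copy(),
            residual_rms=exp.residual_rms, n_points=exp.n_points,
            normalization=exp.normalization, aligned=True,
            label_id=exp.label_id, flags=list(exp.flags) + ["degenerate_quadrupole"],
        )
        return out, np.eye(3)
    Q = quadrupole_tensor(exp)
    evals, evecs = np.linalg.eigh(Q)  # ascending
    v = evecs[:, 0]
    if v[2] < 0 or (v[2] == 0 and (v[0] < 0 or (v[0] == 0 and v[1] < 0))):
        v = -v
    R = _rotation_mapping_to_z(v, evecs[:, 2])
    out = rotate_expansion(exp, R)
    out.aligned = True
    if verify:
        c20 = out.coeff(2, 0)
        scale = max(1.0, abs(exp.coeffs[0]))
        for axis in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
            for delta in (-0.05, 0.05):
                Rp = Rotation.from_rotvec(delta * axis).as_matrix() @ R
                if _c20_after(exp, Rp) < c20 - 1e-8 * scale:
                    raise RuntimeError(
                        "alignment post-condition violated: a nearby rotation "
                        "lowers c_{2,0}"
                    )
    return out, R


def deformation_parameter(aligned: SHExpansion) -> float:
    """D = |c_{2,0}| / c_{0,0} in the c_{2,0}-minimizing frame."""
    if not aligned.aligned:
        raise ValueError(
            "deformation parameter is defined in the aligned frame; "
            "call align_shape first"
        )
    return abs(aligned.coeff(2, 0)) / aligned.coeff(0, 0)


def expansions_to_frame(exps: list[SHExpansion]) -> pd.DataFrame:
    """Long-form coefficient table: label_id, l, m, c_um."""
    rows = []
    for e in exps:
        for l, m in _sh.mode_list(e.lmax):
            rows.append({
                "label_id": e.label_id, "l": l, "m": m,
                "c_um": e.coeffs[_sh.mode_index(l, m)],
            })
    return pd.DataFrame(rows, columns=["label_id", "l", "m", "c_um"])
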