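"""Synthetic voxel phantoms with known spherical-harmonic shapes.

Every rendered object is a star-convex body whose radius function
r(theta, phi) = sum c_{l,m} Y_{l,m} is known exactly, so downstream
segmentation, surface extraction and coefficient fitting can be validated
against ground truth without any microscopy data.  Rendering uses a
one-voxel partial-volume ramp at the boundary (linear in the signed radial
distance) to avoid stair-step bias, then applies Gaussian or Poisson noise
from a stored seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import tifffile

from . import _sh
from .imgseg import Image3D

__all__ = [
    "GroundTruthShape",
    "NoiseModel",
    "FixtureField",
    "sphere_coeffs",
    "render_sh_shape",
    "render_field",
    "write_field",
    "read_truth",
]

_DENSE_GRID = _sh.gauss_sphere_grid(32, 64)


def sphere_coeffs(radius: float, lmax: int = 0) -> np.ndarray:
    """Coefficient table of a perfect sphere: c_{0,0} = sqrt(4 pi) R."""
    c = np.zeros(_sh.n_modes(lmax))
    c[0] = np.sqrt(4.0 * np.pi) * radius
    return c


@dataclass
class GroundTruthShape:
    """One star-convex object: SH coefficients (um), center (x, y, z um)."""

    coeffs: np.ndarray
    center: np.ndarray
    intensity: float = 1.0
    label_id: int = 1

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        _sh.lmax_of(self.coeffs)  # validates length
        if self.coeffs[0] <= 0:
            raise ValueError("c_{0,0} must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.label_id <= 0:
            raise ValueError("label_id must be a positive integer")
        if self.min_radius() <= 0:
            raise ValueError("invalid shape: radius function is not strictly positive")

    def radius(self, theta, phi):
        """r(theta, phi) in micrometers."""
        return _sh.evaluate(self.coeffs, theta, phi)

    def min_radius(self) -> float:
        th, ph, _ = _DENSE_GRID
        return float(self.radius(th[:, None], ph[None, :]).min())

    def max_radius(self) -> float:
        th, ph, _ = _DENSE_GRID
        return float(self.radius(th[:, None], ph[None, :]).max())

    def volume(self, n_theta: int = 64, n_phi: int = 128) -> float:
        """Exact volume by angular quadrature of (1/3) closed-integral r^3 dOmega."""
        th, ph, w = _sh.gauss_sphere_grid(n_theta, n_phi)
        r = self.radius(th[:, None], ph[None, :])
        return float(np.sum(w * r**3) / 3.0)


@dataclass
class NoiseModel:
    """none | gaussian (sigma relative to peak) | poisson (photons at peak)."""

    kind: str = "none"
    sigma_rel: float = 0.05
    peak_photons: float = 200.0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.kind!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return values
        peak = values.max()
        if peak <= 0:
            return values
        if self.kind == "gaussian":
            out = values + rng.normal(0.0, self.sigma_rel * peak, size=values.shape)
            return np.clip(out, 0.0, None)
        scale = self.peak_photons / peak
        return rng.poisson(values * scale).astype(float) / scale


@dataclass
class FixtureField:
    image: Image3D
    truth: list[GroundTruthShape]
    seed: int
    noise_model: NoiseModel = dc_field(default_factory=NoiseModel)


def _voxel_centers_um(grid_shape, voxel_size):
    """Physical (x, y, z) coordinate arrays of voxel centers.

    The voxel at index (iz, iy, ix) sits at physical position
    index * voxel_size, matching the coordinate convention of
    skimage.measure.marching_cubes with ``spacing=voxel_size``.
    """
    nz, ny, nx = grid_shape
    vz, vy, vx = voxel_size
    return np.arange(nz) * vz, np.arange(ny) * vy, np.arange(nx) * vx


def _render_into(canvas: np.ndarray, truth: GroundTruthShape, voxel_size: np.ndarray):
    """Add one shape's partial-volume occupancy to the canvas."""
    rmax = truth.max_radius()
    ramp = float(np.mean(voxel_size))  # anti-alias shell thickness
    nz, ny, nx = canvas.shape
    # bounding box in voxel indices (center is x, y, z; axes are z, y, x)
    czyx = truth.center[::-1]
    lo = np.floor((czyx - rmax - 2 * ramp) / voxel_size).astype(int)
    hi = np.ceil((czyx + rmax + 2 * ramp) / voxel_size).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > np.array([nz, ny, nx])):
        raise ValueError(
            f"shape with label_id={truth.label_id} exceeds the image grid"
        )
    zc = np.arange(lo[0], hi[0]) * voxel_size[0] - czyx[0]
    yc = np.arange(lo[1], hi[1]) * voxel_size[1] - czyx[1]
    xc = np.arange(lo[2], hi[2]) * voxel_size[2] - czyx[2]
    dz, dy, dx = np.meshgrid(zc, yc, xc, indexing="ij")
    d = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(d > 0, dz / np.where(d > 0, d, 1.0), 1.0), -1, 1))
    phi = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    r_dir = truth.radius(theta, phi)
    occ = np.clip((r_dir - d) / ramp + 0.5, 0.0, 1.0)
    canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += truth.intensity * occ


def render_sh_shape(
    truth: GroundTruthShape,
    voxel_size,
    grid_shape,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> Image3D:
    """Voxelize one shape onto a dark background.

    A voxel is fully foreground when its center lies more than half a voxel
    inside r(theta, phi) along its own direction from the object center;
    the transition is a linear one-voxel partial-volume ramp.  Noise (if
    any) is applied last with the given seed.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if np.any(voxel_size <= 0):
        raise ValueError("voxel_size must be positive")
    canvas = np.zeros(tuple(grid_shape), dtype=float)
    _render_into(canvas, truth, voxel_size)
    noise_model = noise_model or NoiseModel()
    canvas = noise_model.apply(canvas, np.random.default_rng(seed))
    return Image3D(canvas, voxel_size)


def _random_deformation(
    rng: np.random.Generator, r0: float, amplitude: float, l_range
) -> np.ndarray:
    """Coefficients with max angular deviation = amplitude * r0."""
    l_lo, l_hi = l_range
    lmax = l_hi
    coeffs = np.zeros(_sh.n_modes(lmax))
    coeffs[0] = np.sqrt(4.0 * np.pi) * r0
    if amplitude <= 0:
        return coeffs
    dev = np.zeros_like(coeffs)
    for l in range(l_lo, l_hi + 1):
        for m in range(-l, l + 1):
            dev[_sh.mode_index(l, m)] = rng.normal()
    th, ph, _ = _DENSE_GRID
    peak = np.abs(_sh.evaluate(dev, th[:, None], ph[None, :])).max()
    coeffs += dev * (amplitude * r0 / peak)
    return coeffs


def render_field(
    n_objects: int,
    radius_range=(4.0, 6.0),
    deformation_amplitude: float = 0.1,
    l_range=(2, 4),
    grid_shape=(64, 64, 64),
    voxel_size=0.5,
    seed: int = 0,
    noise_model: NoiseModel | None = None,
    max_tries: int = 200,
) -> FixtureField:
    """Render a field of non-overlapping deformed blobs with full ground truth.

    Placement, radii, intensities and deformation coefficients are all drawn
    from ``seed``; rendering is bit-reproducible.  Packing failure after
    bounded retries raises ``cannot place objects``.
    """
    rng = np.random.default_rng(seed)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    grid_shape = tuple(int(s) for s in grid_shape)
    noise_model = noise_model or NoiseModel()
    extent_zyx = (np.array(grid_shape) - 1) * voxel_size  # physical size
    margin_vox = 2.0 * np.mean(voxel_size)

    truths: list[GroundTruthShape] = []
    centers: list[np.ndarray] = []
    maxima: list[float] = []
    for i in range(n_objects):
        r0 = rng.uniform(*radius_range)
        coeffs = _random_deformation(rng, r0, deformation_amplitude, l_range)
        shape = GroundTruthShape(
            coeffs=coeffs,
            center=np.zeros(3),
            intensity=rng.uniform(0.8, 1.2),
            label_id=i + 1,
        )
        rmax = shape.max_radius()
        placed = False
        for _ in range(max_tries):
            lo = rmax + margin_vox
            hi_zyx = extent_zyx - (rmax + margin_vox)
            if np.any(hi_zyx <= lo):
                break
            c_xyz = np.array([
                rng.uniform(lo, hi_zyx[2]),
                rng.uniform(lo, hi_zyx[1]),
                rng.uniform(lo, hi_zyx[0]),
            ])
            ok = all(
                np.linalg.norm(c_xyz - c2) > rmax + m2 + margin_vox
                for c2, m2 in zip(centers, maxima)
            )
            if ok:
                shape.center = c_xyz
                placed = True
                break
        if not placed:
            raise ValueError("cannot place objects: packing failed after retries")
        truths.append(shape)
        centers.append(shape.center)
        maxima.append(rmax)

    canvas = np.zeros(grid_shape, dtype=float)
    for shape in truths:
        _render_into(canvas, shape, voxel_size)
    canvas = noise_model.apply(canvas, np.random.default_rng(seed))
    return FixtureField(Image3D(canvas, voxel_size), truths, seed, noise_model)


def write_field(field: FixtureField, tiff_path, truth_path) -> None:
    """Write the image as multi-page TIFF and the truth table as JSON."""
    tifffile.imwrite(
        str(tiff_path),
        field.image.values.astype(np.float32),
        resolution=(1.0 / field.image.voxel_size[2], 1.0 / field.image.voxel_size[1]),
    )
    records = []
    for t in field.truth:
        lmax = _sh.lmax_of(t.coeffs)
        records.append({
            "label_id": t.label_id,
            "center_um": list(map(float, t.center)),
            "intensity": t.intensity,
            "coeffs": [
                {"l": l, "m": m, "c": float(t.coeffs[_sh.mode_index(l, m)])}
                for l, m in _sh.mode_list(lmax)
            ],
        })
    payload = {
        "voxel_size_um": list(map(float, field.image.voxel_size)),
        "seed": field.seed,
        "noise_model": {
            "kind": field.noise_model.kind,
            "sigma_rel": field.noise_model.sigma_rel,
            "peak_photons": field.noise_model.peak_photons,
        },
        "objects": records,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(truth_path) -> list[GroundTruthShape]:
    """Load a truth table written by :func:`write_field`."""
    with open(truth_path) as fh:
        payload = json.load(fh)
    shapes = []
    for rec in payload["objects"]:
        lmax = max(c["l"] for c in rec["coeffs"])
        coeffs = np.zeros(_sh.n_modes(lmax))
        for c in rec["coeffs"]:
            coeffs[_sh.mode_index(c["l"], c["m"])] = c["c"]
        shapes.append(GroundTruthShape(
            coeffs=coeffs,
            center=np.array(rec["center_um"]),
            intensity=rec["intensity"],
            label_id=rec["label_id"],
        ))
    return shapes
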