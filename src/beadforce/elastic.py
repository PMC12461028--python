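"""Analytic linear elastostatics of a solid sphere under radial surface displacement.

The sensor bead is an isotropic, linearly elastic solid sphere (shear
modulus G, Poisson ratio nu).  Its surface displacement is assumed purely
radial and expanded in real spherical harmonics; for each mode (l, m) the
interior displacement solving the Navier-Lame equilibrium equation

    1/(1 - 2 nu) grad(div u) + laplace(u) = 0

is a combination of the two regular spheroidal solid-harmonic families

    u1 = grad(r^l Y_lm),
    u2 = r^2 grad(r^l Y_lm) + beta_l x r^l Y_lm,
    beta_l = -(6 l + 2 - nu (8 l + 4)) / (l + 5 - 4 nu),

whose weights follow from a per-degree 2x2 solve of the boundary
conditions u_r(r0) = Y_lm, u_tangential(r0) = 0 (l = 0 is the single
hydrostatic family u = A r e_r).  Strain and isotropic Hooke's law
(T = lambda tr(eps) I + 2 G eps, lambda = 2 G nu / (1 - 2 nu)) then give
closed-form surface traction scales per degree: the radial traction per
unit (um) coefficient amplitude is

    t_rr[l] = G tau_rr(l, nu) / r0,

so the full radial traction map is T_rr(theta, phi) =
sum c_lm t_rr[l] Y_lm(theta, phi).  Everything is linear in the
coefficients and in G; coefficients are in um, G in Pa, tractions in Pa,
integrated forces in N.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import _sh
from .shape import SHExpansion, equivalent_radius, quadrupole_tensor, power_spectrum

__all__ = [
    "MaterialParams",
    "ModeBasis",
    "StressMap",
    "ForceResult",
    "build_mode_basis",
    "stress_map",
    "total_force",
    "compression_axis",
    "navier_residual",
]

#: 1 Pa * um^2 in newtons
PA_UM2_TO_N = 1e-12

DEFAULT_BASIS_LMAX = 15


@dataclass
class MaterialParams:
    """Shear modulus G (Pa) and Poisson ratio nu of the sensor material."""

    G: float
    nu: float

    def __post_init__(self):
        if self.G <= 0:
            raise ValueError("shear modulus G must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(
                "Poisson ratio must lie in (-1, 0.5); nu = 0.5 is "
                "incompressible and singular here"
            )

    @property
    def lame_lambda(self) -> float:
        return 2.0 * self.G * self.nu / (1.0 - 2.0 * self.nu)


def _beta(l: np.ndarray, nu: float) -> np.ndarray:
    return -(6.0 * l + 2.0 - nu * (8.0 * l + 4.0)) / (l + 5.0 - 4.0 * nu)


def _dimensionless_traction_tables(lmax: int, nu: float):
    """Per-degree tau_rr, tau_rt with traction scale = G * tau / r0.

    Closed forms from the 2x2 boundary solve: with beta = beta_l,
    U'(r0) r0 = 2 l / beta + l + 1 and div(u)(r0) r0 = U'(r0) r0 + 2, so

        tau_rr = lam_hat (2 l / beta + l + 3) + 2 (2 l / beta + l + 1)
        tau_rt = 1 + 2 / beta          (zero for l = 0)

    where lam_hat = lambda / G = 2 nu / (1 - 2 nu).
    """
    lam_hat = 2.0 * nu / (1.0 - 2.0 * nu)
    ls = np.arange(lmax + 1, dtype=float)
    beta = _beta(ls, nu)
    if np.any(np.abs(beta) < 1e-12):
        bad = int(ls[np.argmin(np.abs(beta))])
        raise ValueError(f"singular mode system at l={bad}, nu={nu}")
    uprime = 2.0 * ls / beta + ls + 1.0
    tau_rr = lam_hat * (uprime + 2.0) + 2.0 * uprime
    tau_rt = 1.0 + 2.0 / beta
    # hydrostatic degree: u = (r / r0) e_r, tau_rr = 3 lam_hat + 2, no shear
    tau_rr[0] = 3.0 * lam_hat + 2.0
    tau_rt[0] = 0.0
    beta[0] = np.nan
    return beta, tau_rr, tau_rt


def _cache_path(lmax: int, nu: float) -> Path:
    root = os.environ.get("XDG_CACHE_HOME", os.path.expanduser("~/.cache"))
    return Path(root) / "beadforce" / f"modes_l{lmax}_nu{nu:.6f}.json"


@dataclass
class ModeBasis:
    """Per-degree interior solution weights and surface traction scales.

    Traction scales are per micrometer of coefficient amplitude:
    the mode (l, m) at amplitude c contributes
    c * rr_scale[l] * Y_lm e_r + c * rt_scale[l] * grad_s Y_lm
    to the surface traction (Pa).
    """

    lmax: int
    material: MaterialParams
    r0: float
    beta: np.ndarray = dc_field(repr=False, default=None)
    tau_rr: np.ndarray = dc_field(repr=False, default=None)
    tau_rt: np.ndarray = dc_field(repr=False, default=None)

    @property
    def rr_scale(self) -> np.ndarray:
        """Radial traction per unit coefficient, Pa / um, indexed by degree."""
        return self.material.G * self.tau_rr / self.r0

    @property
    def rt_scale(self) -> np.ndarray:
        """Tangential traction per unit coefficient, Pa / um, by degree."""
        return self.material.G * self.tau_rt / self.r0

    def slice(self, lmax: int) -> "ModeBasis":
        """A lower-degree view of the same precomputed basis."""
        if lmax > self.lmax:
            raise ValueError("cannot slice to a larger lmax")
        return ModeBasis(
            lmax=lmax, material=self.material, r0=self.r0,
            beta=self.beta[:lmax + 1].copy(),
            tau_rr=self.tau_rr[:lmax + 1].copy(),
            tau_rt=self.tau_rt[:lmax + 1].copy(),
        )

    def radial_profiles(
        self, l: int, rho,
        a_scale: float = 1.0, b_scale: float = 1.0, beta_scale: float = 1.0,
    ):
        """U(rho), V(rho) of mode degree l at relative radius rho = r / r0.

        The interior displacement per unit coefficient is
        u = U Y e_r + V grad_s Y (dimensionless, coefficient carries um).
        ``a_scale``/``b_scale`` rescale the two family weights (still an
        exact interior solution, wrong boundary values); ``beta_scale``
        perturbs the second family's internal coupling, which breaks the
        bulk equation itself — both are diagnostics probes.
        """
        rho = np.asarray(rho, dtype=float)
        if l == 0:
            return a_scale * rho, np.zeros_like(rho)
        b = self.beta[l]
        bf = b * beta_scale  # coupling inside family 2: r^2 grad(phi) + bf x phi
        U = (b_scale * (l + bf) * rho ** (l + 1) - a_scale * l * rho ** (l - 1)) / b
        V = (b_scale * rho ** (l + 1) - a_scale * rho ** (l - 1)) / b
        return U, V

    def displacement(
        self, l: int, m: int, points: np.ndarray,
        a_scale: float = 1.0, b_scale: float = 1.0, beta_scale: float = 1.0,
    ) -> np.ndarray:
        """Interior displacement field of mode (l, m) at Cartesian points.

        Points are relative to the sphere center, in um; returns the
        dimensionless displacement per unit (um) coefficient amplitude.
        """
        p = np.asarray(points, dtype=float)
        r = np.linalg.norm(p, axis=-1)
        if np.any(r == 0) and l != 0:
            raise ValueError("displacement undefined at the exact center for l > 0")
        rho = r / self.r0
        safe_r = np.where(r > 0, r, 1.0)
        theta = np.arccos(np.clip(p[..., 2] / safe_r, -1, 1))
        phi = np.mod(np.arctan2(p[..., 1], p[..., 0]), 2 * np.pi)
        Y, dth, dph = _sh.real_sh_grad(l, m, theta, phi)
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        e_r = np.stack([st * cp, st * sp, ct], axis=-1)
        e_th = np.stack([ct * cp, ct * sp, -st], axis=-1)
        e_ph = np.stack([-sp, cp, np.zeros_like(sp)], axis=-1)
        U, V = self.radial_profiles(l, rho, a_scale, b_scale, beta_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            dph_over_sin = np.where(st > 1e-12, dph / np.where(st > 0, st, 1.0), 0.0)
        return (
            U[..., None] * Y[..., None] * e_r
            + V[..., None] * (dth[..., None] * e_th + dph_over_sin[..., None] * e_ph)
        )


def build_mode_basis(
    lmax: int, material: MaterialParams, r0: float, cache: bool = True
) -> ModeBasis:
    """Solve the per-degree boundary-value problem up to ``lmax``.

    The dimensionless tables depend only on (lmax, nu) and are cached on
    disk so repeated runs reuse the precomputed solution templates.
    """
    if lmax < 0:
        raise ValueError("lmax must be non-negative")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    beta = tau_rr = tau_rt = None
    path = _cache_path(lmax, material.nu)
    if cache and path.exists():
        try:
            with open(path) as fh:
                data = json.load(fh)
            beta = np.array(data["beta"])
            tau_rr = np.array(data["tau_rr"])
            tau_rt = np.array(data["tau_rt"])
        except (json.JSONDecodeError, KeyError, OSError):
            beta = None
    if beta is None:
        beta, tau_rr, tau_rt = _dimensionless_traction_tables(lmax, material.nu)
        if cache:
            try:
                path.parent.mkdir(parents=True, exist_ok=True)
                with open(path, "w") as fh:
                    json.dump({
                        "beta": [None if np.isnan(x) else x for x in beta],
                        "tau_rr": list(tau_rr), "tau_rt": list(tau_rt),
                    }, fh)
            except OSError:
                pass
        beta = np.array([np.nan if x is None else x for x in beta], dtype=float)
    return ModeBasis(
        lmax=lmax, material=material, r0=float(r0),
        beta=np.asarray(beta, dtype=float),
        tau_rr=np.asarray(tau_rr, dtype=float),
        tau_rt=np.asarray(tau_rt, dtype=float),
    )


@dataclass
class StressMap:
    """Radial deformation and traction sampled on a full-sphere grid.

    ``theta`` (Gauss-Legendre colatitudes) and ``phi`` (uniform azimuths)
    are 1-D; ``weights`` (2-D, summing to 4 pi) are solid-angle quadrature
    weights.  ``traction_xyz`` holds the Cartesian components of the full
    surface traction vector for diagnostics.
    """

    theta: np.ndarray
    phi: np.ndarray
    weights: np.ndarray
    radial_traction: np.ndarray
    radial_deformation: np.ndarray
    traction_xyz: np.ndarray
    material: MaterialParams
    r0: float


def stress_map(
    exp: SHExpansion,
    material: MaterialParams,
    r0_override: float | None = None,
    grid_resolution: int | None = None,
    basis: ModeBasis | None = None,
) -> StressMap:
    """Surface traction map of the bead described by ``exp``.

    Deformation coefficients equal the shape coefficients for l >= 1; the
    l = 0 deformation is c_{0,0} - sqrt(4 pi) r0, which vanishes when r0 is
    inferred from the expansion (volume conservation) and is nonzero when
    an independently known undeformed radius is supplied via
    ``r0_override``.
    """
    r0 = float(r0_override) if r0_override is not None else equivalent_radius(exp)
    if basis is None:
        basis = build_mode_basis(max(exp.lmax, DEFAULT_BASIS_LMAX), material, r0)
    if exp.lmax > basis.lmax:
        raise ValueError(
            f"expansion degree {exp.lmax} exceeds basis degree {basis.lmax}; "
            "rebuild the basis with a larger lmax"
        )
    if abs(basis.r0 - r0) > 1e-9 * max(r0, basis.r0):
        raise ValueError("basis was built for a different reference radius r0")
    if basis.material != material:
        raise ValueError("basis was built for different material parameters")

    defc = exp.coeffs.copy()
    defc[0] = exp.coeffs[0] - np.sqrt(4.0 * np.pi) * r0

    n_theta = grid_resolution or max(2 * exp.lmax + 2, 16)
    theta, phi, weights = _sh.gauss_sphere_grid(n_theta, 2 * n_theta)
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    st, ct = np.sin(TH), np.cos(TH)
    sp, cp = np.sin(PH), np.cos(PH)
    e_r = np.stack([st * cp, st * sp, ct])
    e_th = np.stack([ct * cp, ct * sp, -st])
    e_ph = np.stack([-sp, cp, np.zeros_like(sp)])

    rr = basis.rr_scale
    rt = basis.rt_scale
    t_rr = np.zeros_like(TH)
    u_rad = np.zeros_like(TH)
    t_vec = np.zeros((3,) + TH.shape)
    for l, m in _sh.mode_list(exp.lmax):
        c = defc[_sh.mode_index(l, m)]
        if c == 0.0:
            continue
        Y, dth, dph = _sh.real_sh_grad(l, m, TH, PH)
        u_rad += c * Y
        t_rr += c * rr[l] * Y
        with np.errstate(divide="ignore", invalid="ignore"):
            dps = np.where(st > 1e-12, dph / np.where(st > 0, st, 1.0), 0.0)
        t_vec += c * (rr[l] * Y * e_r + rt[l] * (dth * e_th + dps * e_ph))
    return StressMap(
        theta=theta, phi=phi, weights=weights,
        radial_traction=t_rr, radial_deformation=u_rad,
        traction_xyz=t_vec, material=material, r0=r0,
    )


@dataclass
class ForceResult:
    """Integrated surface force (N) plus the net vector diagnostic."""

    force: float
    net_vector: np.ndarray
    statistic: str


FORCE_STATISTICS = ("abs_radial", "compressive", "traction_magnitude")


def total_force(smap: StressMap, statistic: str = "abs_radial") -> ForceResult:
    """Integrate the surface traction into a scalar force.

    ``abs_radial`` (default) integrates |T_rr| dA; ``compressive``
    integrates only the inward radial traction max(-T_rr, 0) dA;
    ``traction_magnitude`` integrates |T . e_r| (full vector norm) dA.
    The signed vector integral of the traction (returned as diagnostic)
    vanishes for an equilibrium field.
    """
    if statistic not in FORCE_STATISTICS:
        raise ValueError(f"unknown force statistic {statistic!r}")
    dA = smap.weights * smap.r0**2  # um^2
    if statistic == "abs_radial":
        dens = np.abs(smap.radial_traction)
    elif statistic == "compressive":
        dens = np.maximum(-smap.radial_traction, 0.0)
    else:
        dens = np.linalg.norm(smap.traction_xyz, axis=0)
    force = float(np.sum(dens * dA) * PA_UM2_TO_N)
    net = np.sum(smap.traction_xyz * dA, axis=(1, 2)) * PA_UM2_TO_N
    return ForceResult(force=force, net_vector=net, statistic=statistic)


#: degree-2 power below which no compression direction is defined
P2_AXIS_TOL = 1e-10


def compression_axis(exp: SHExpansion, tol: float = P2_AXIS_TOL):
    """Unit vector of maximum compression from the degree-2 quadrupole.

    Returns ``(axis, degenerate)``; for near-spherical shapes
    (P_2 < tol) the axis is NaN and ``degenerate`` is True.  The sign is
    fixed so the z component is non-negative.
    """
    if exp.lmax < 2:
        raise ValueError("compression axis requires lmax >= 2")
    if power_spectrum(exp)[2] < tol:
        return np.full(3, np.nan), True
    Q = quadrupole_tensor(exp)
    evals, evecs = np.linalg.eigh(Q)
    v = evecs[:, 0]  # most negative radial perturbation
    if v[2] < 0 or (v[2] == 0 and (v[0] < 0 or (v[0] == 0 and v[1] < 0))):
        v = -v
    return v, False


def _hessian_stencil(h: float):
    """Offsets and assembly for 4th-order FD Hessians of a vector field."""
    offsets = [np.zeros(3)]
    # pure second derivatives: +-h, +-2h along each axis
    for ax in range(3):
        for k in (-2, -1, 1, 2):
            o = np.zeros(3)
            o[ax] = k * h
            offsets.append(o)
    # mixed: tensor product of two 4-point first-derivative stencils
    pairs = [(0, 1), (0, 2), (1, 2)]
    for a, b in pairs:
        for ka in (-2, -1, 1, 2):
            for kb in (-2, -1, 1, 2):
                o = np.zeros(3)
                o[a] = ka * h
                o[b] = kb * h
                offsets.append(o)
    return np.array(offsets), pairs


_D1 = {-2: 1.0 / 12.0, -1: -8.0 / 12.0, 1: 8.0 / 12.0, 2: -1.0 / 12.0}
_D2 = {0: -30.0 / 12.0, -2: -1.0 / 12.0, -1: 16.0 / 12.0, 1: 16.0 / 12.0, 2: -1.0 / 12.0}


def _field_hessians(field, points: np.ndarray, h: float):
    """Hessians H[p, c, i, j] and gradients D[p, c, i] of a 3-vector field."""
    offsets, pairs = _hessian_stencil(h)
    n = len(points)
    stencil_pts = (points[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    vals = field(stencil_pts).reshape(n, len(offsets), 3)
    H = np.zeros((n, 3, 3, 3))
    D = np.zeros((n, 3, 3))
    # pure second derivatives (and first derivatives from the same stencil)
    pos = 1
    for ax in range(3):
        acc = _D2[0] * vals[:, 0, :]
        acc1 = np.zeros((n, 3))
        for k in (-2, -1, 1, 2):
            acc = acc + _D2[k] * vals[:, pos, :]
            acc1 = acc1 + _D1[k] * vals[:, pos, :]
            pos += 1
        H[:, :, ax, ax] = acc / h**2
        D[:, :, ax] = acc1 / h
    # mixed
    for a, b in pairs:
        acc = np.zeros((n, 3))
        for ka in (-2, -1, 1, 2):
            for kb in (-2, -1, 1, 2):
                acc = acc + _D1[ka] * _D1[kb] * vals[:, pos, :]
                pos += 1
        H[:, :, a, b] = acc / h**2
        H[:, :, b, a] = H[:, :, a, b]
    return H, D


def navier_residual(
    basis: ModeBasis,
    n_probe: int = 50,
    seed: int = 0,
    a_scale: float = 1.0,
    b_scale: float = 1.0,
    beta_scale: float = 1.0,
) -> float:
    """Max relative residual of the Navier-Lame equation over all modes.

    The left side 1/(1-2 nu) grad(div u) + laplace(u) is evaluated by
    4th-order finite differences at seeded random interior points and
    normalized by the local Hessian magnitude of the mode's displacement.
    The unperturbed basis evaluates to FD-roundoff level; ``beta_scale``
    perturbs the second solution family's internal coupling and makes the
    residual rise, while ``a_scale``/``b_scale`` mis-weight the families
    (still exact interior solutions) and leave it at FD level.
    """
    rng = np.random.default_rng(seed)
    r0 = basis.r0
    # interior probes, away from center, surface and the polar axis
    pts = []
    while len(pts) < n_probe:
        v = rng.normal(size=3)
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        v = v / nv
        if abs(v[2]) > 0.95:
            continue
        pts.append(v * rng.uniform(0.3, 0.7) * r0)
    pts = np.array(pts)
    h = 1e-3 * r0
    inv = 1.0 / (1.0 - 2.0 * basis.material.nu)
    worst = 0.0
    for l, m in _sh.mode_list(basis.lmax):
        H, D = _field_hessians(
            lambda p: basis.displacement(l, m, p, a_scale, b_scale, beta_scale),
            pts, h,
        )
        lap = np.einsum("pcjj->pc", H)
        grad_div = np.einsum("pjij->pi", H)
        res = inv * grad_div + lap
        # second-derivative magnitude, floored by the gradient scale / r0
        # so pure rigid-like fields (zero Hessian) stay well-posed
        scale = 3.0 * (
            np.sqrt(np.mean(H**2, axis=(1, 2, 3)))
            + np.sqrt(np.mean(D**2, axis=(1, 2))) / r0
        )
        worst = max(worst, float(np.max(np.abs(res) / scale[:, None])))
    return worst
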