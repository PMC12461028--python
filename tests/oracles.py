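"""Independent reference solutions used only by the tests.

These deliberately avoid the package's solver internals: the elastic
boundary-value problem is re-solved by dense least-squares collocation on a
generic regular solid-harmonic (Papkovich-Neuber) displacement basis, with
surface tractions obtained by finite-difference differentiation of the
fitted field, and shape alignment is cross-checked by brute-force rotation
grid search.
"""

from __future__ import annotations

import numpy as np

from beadforce import _sh


def _spherical(points):
    r = np.linalg.norm(points, axis=-1)
    theta = np.arccos(np.clip(points[..., 2] / np.where(r > 0, r, 1.0), -1, 1))
    phi = np.mod(np.arctan2(points[..., 1], points[..., 0]), 2 * np.pi)
    return r, theta, phi


def _solid_harmonic(lam, mu, points, scale):
    """S = (r/scale)^lam Y_{lam,mu} and grad S (1/um) at Cartesian points."""
    r, th, ph = _spherical(points)
    Y, dth, dph = _sh.real_sh_grad(lam, mu, th, ph)
    st, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    e_r = np.stack([st * cp, st * sp, ct], axis=-1)
    e_th = np.stack([ct * cp, ct * sp, -st], axis=-1)
    e_ph = np.stack([-sp, cp, np.zeros_like(sp)], axis=-1)
    rho = r / scale
    S = rho**lam * Y
    with np.errstate(divide="ignore", invalid="ignore"):
        dps = np.where(st > 1e-12, dph / np.where(st > 0, st, 1.0), 0.0)
    gradS = (rho ** (lam - 1) / scale)[..., None] * (
        lam * Y[..., None] * e_r + dth[..., None] * e_th + dps[..., None] * e_ph
    )
    if lam == 0:
        gradS = np.zeros_like(gradS)
    return S, gradS


def _pn_basis(L, nu, points, scale):
    """All Papkovich-Neuber displacement basis fields: (K, N, 3).

    u = psi - 1/(4(1-nu)) grad(x . psi + phi0), with phi0 and each
    Cartesian component of psi running over regular solid harmonics of
    degree <= L.  Every field satisfies the Navier equation identically.
    """
    kappa = 1.0 / (4.0 * (1.0 - nu))
    fields = []
    for lam in range(1, L + 1):
        for mu in range(-lam, lam + 1):
            _, gS = _solid_harmonic(lam, mu, points, scale)
            fields.append(gS)
    for i in range(3):
        e_i = np.zeros(3)
        e_i[i] = 1.0
        for lam in range(0, L + 1):
            for mu in range(-lam, lam + 1):
                S, gS = _solid_harmonic(lam, mu, points, scale)
                u = S[..., None] * e_i - kappa * (
                    S[..., None] * e_i + points[..., i:i + 1] * gS
                )
                fields.append(u)
    return np.array(fields)


_FD1 = {-2: 1.0 / 12.0, -1: -8.0 / 12.0, 1: 8.0 / 12.0, 2: -1.0 / 12.0}


class RadialBVPOracle:
    """Collocation solve of the radial-displacement boundary-value problem.

    Precomputes the collocation system and the finite-difference stencil
    evaluations of the basis on an output grid once, so many coefficient
    sets can be checked cheaply against the analytic per-mode solution.
    """

    def __init__(self, lmax, r0, G, nu, theta_out, phi_out):
        self.lmax, self.r0, self.G, self.nu = lmax, r0, G, nu
        L = lmax + 2
        self.L = L
        tc, pc, _ = _sh.gauss_sphere_grid(L + 6, 2 * (L + 6))
        self.TC, self.PC = np.meshgrid(tc, pc, indexing="ij")
        st, ct = np.sin(self.TC), np.cos(self.TC)
        sp, cp = np.sin(self.PC), np.cos(self.PC)
        self.n_colloc = np.stack([st * cp, st * sp, ct], axis=-1)
        pts = (r0 * self.n_colloc).reshape(-1, 3)
        B = _pn_basis(L, nu, pts, r0)
        K = B.shape[0]
        M = B.transpose(1, 2, 0).reshape(-1, K)
        self._norms = np.linalg.norm(M, axis=0)
        self._norms[self._norms == 0] = 1.0
        self._M = M / self._norms

        TH, PH = np.meshgrid(theta_out, phi_out, indexing="ij")
        stg, ctg = np.sin(TH), np.cos(TH)
        spg, cpg = np.sin(PH), np.cos(PH)
        self.n_out = np.stack([stg * cpg, stg * spg, ctg], axis=-1)
        self._out_shape = TH.shape
        surf = (r0 * self.n_out).reshape(-1, 3)
        h = 1e-3 * r0
        self._h = h
        # basis evaluated on the 12 first-derivative stencil points
        self._stencil = []
        for ax in range(3):
            for k in _FD1:
                off = np.zeros(3)
                off[ax] = k * h
                self._stencil.append((ax, k, _pn_basis(L, nu, surf + off, r0)))

    def solve_weights(self, def_coeffs):
        g = (
            _sh.evaluate(def_coeffs, self.TC, self.PC)[..., None] * self.n_colloc
        ).reshape(-1)
        w, *_ = np.linalg.lstsq(self._M, g, rcond=1e-12)
        return w / self._norms

    def radial_traction(self, def_coeffs):
        """Radial surface traction (Pa) on the output grid."""
        w = self.solve_weights(def_coeffs)
        n_pts = self.n_out.reshape(-1, 3).shape[0]
        gradu = np.zeros((n_pts, 3, 3))
        for ax, k, B in self._stencil:
            us = np.einsum("k,knc->nc", w, B)
            gradu[:, :, ax] += _FD1[k] * us / self._h
        eps = 0.5 * (gradu + gradu.transpose(0, 2, 1))
        lam_e = 2.0 * self.G * self.nu / (1.0 - 2.0 * self.nu)
        tr = np.einsum("nii->n", eps)
        sig = lam_e * tr[:, None, None] * np.eye(3) + 2.0 * self.G * eps
        nf = self.n_out.reshape(-1, 3)
        t_r = np.einsum("ni,nij,nj->n", nf, sig, nf)
        return t_r.reshape(self._out_shape)


def fibonacci_directions(n):
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def rotation_to_z(v):
    """Any proper rotation carrying unit vector v to the z axis."""
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    a = helper - (helper @ v) * v
    a /= np.linalg.norm(a)
    b = np.cross(v, a)
    return np.array([a, b, v])


def c20_of_rotated(coeffs, R, n_theta=24, n_phi=48):
    """c_{2,0} of the actively rotated radius function, by quadrature."""
    th, ph, w = _sh.gauss_sphere_grid(n_theta, n_phi)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    n = np.stack([
        np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH),
    ], axis=-1)
    nr = n @ np.asarray(R)
    thr = np.arccos(np.clip(nr[..., 2], -1, 1))
    phr = np.mod(np.arctan2(nr[..., 1], nr[..., 0]), 2 * np.pi)
    f = _sh.evaluate(coeffs, thr, phr)
    return float(np.sum(f * _sh.real_sh(2, 0, TH, PH) * w))


def grid_search_min_c20(coeffs, n_axes=600):
    """Brute-force search of the rotation minimizing c_{2,0}.

    Returns (min c20, best axis mapped to z).
    """
    best = (np.inf, None)
    for v in fibonacci_directions(n_axes):
        c20 = c20_of_rotated(coeffs, rotation_to_z(v))
        if c20 < best[0]:
            best = (c20, v)
    return best


def grid_search_min_radius_direction(coeffs_deg2, n_axes=4000):
    """Direction minimizing the degree-2 radius perturbation, brute force."""
    dirs = fibonacci_directions(n_axes)
    th = np.arccos(np.clip(dirs[:, 2], -1, 1))
    ph = np.mod(np.arctan2(dirs[:, 1], dirs[:, 0]), 2 * np.pi)
    f = np.zeros(len(dirs))
    for j, m in enumerate(range(-2, 3)):
        f += coeffs_deg2[j] * _sh.real_sh(2, m, th, ph)
    return dirs[np.argmin(f)]
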