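"""Real orthonormal spherical harmonics.

Convention used throughout the package: real-valued spherical harmonics
Y_{l,m}(theta, phi) orthonormal on the unit sphere, i.e.

    integral |Y_{l,m}|^2 dOmega = 1,     Y_{0,0} = 1 / sqrt(4 pi),

with theta the colatitude (polar angle from +z, in [0, pi]) and phi the
azimuth in [0, 2 pi).  No Condon-Shortley phase enters the real basis.
Coefficient tables are stored flat in (l, m) order with index l^2 + l + m.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import sph_harm_y

__all__ = [
    "n_modes",
    "mode_index",
    "mode_list",
    "real_sh",
    "real_sh_grad",
    "design_matrix",
    "gauss_sphere_grid",
]


def n_modes(lmax: int) -> int:
    """Number of (l, m) modes up to and including degree ``lmax``."""
    return (lmax + 1) ** 2


def mode_index(l: int, m: int) -> int:
    """Flat index of mode (l, m) in a coefficient table."""
    if abs(m) > l:
        raise ValueError(f"order |m|={abs(m)} exceeds degree l={l}")
    return l * l + l + m


def mode_list(lmax: int) -> list[tuple[int, int]]:
    """All (l, m) pairs up to ``lmax`` in flat-index order."""
    return [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]


def real_sh(l: int, m: int, theta, phi):
    """Evaluate the real orthonormal harmonic Y_{l,m} at (theta, phi)."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if m == 0:
        return sph_harm_y(l, 0, theta, phi).real.copy()
    mm = abs(m)
    y = sph_harm_y(l, mm, theta, phi)
    scale = np.sqrt(2.0) * (-1.0) ** mm
    return scale * (y.real if m > 0 else y.imag)


def real_sh_grad(l: int, m: int, theta, phi):
    """Y_{l,m} and its exact partial derivatives d/dtheta, d/dphi."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    mm = abs(m)
    y, dy = sph_harm_y(l, mm, theta, phi, diff_n=1)
    dth, dph = dy[..., 0], dy[..., 1]
    if m == 0:
        return y.real.copy(), dth.real.copy(), dph.real.copy()
    scale = np.sqrt(2.0) * (-1.0) ** mm
    if m > 0:
        return scale * y.real, scale * dth.real, scale * dph.real
    return scale * y.imag, scale * dth.imag, scale * dph.imag


def design_matrix(lmax: int, theta, phi) -> np.ndarray:
    """Matrix of all Y_{l,m}(theta_i, phi_i), shape (n_points, (lmax+1)^2)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).ravel()
    phi = np.atleast_1d(np.asarray(phi, dtype=float)).ravel()
    cols = [real_sh(l, m, theta, phi) for l, m in mode_list(lmax)]
    return np.column_stack(cols)


def lmax_of(coeffs) -> int:
    """Degree of a flat coefficient table; validates the length."""
    n = len(coeffs)
    lmax = int(round(np.sqrt(n))) - 1
    if n_modes(lmax) != n:
        raise ValueError(f"coefficient table length {n} is not a perfect square")
    return lmax


def evaluate(coeffs, theta, phi):
    """Evaluate sum_{l,m} c_{l,m} Y_{l,m} at (theta, phi).

    ``coeffs`` is a flat table in mode_index order; broadcasting follows the
    shape of theta/phi.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    theta = np.asarray(theta, dtype=float)
    lmax = lmax_of(coeffs)
    out = np.zeros(np.broadcast(theta, np.asarray(phi)).shape, dtype=float)
    for (l, m), c in zip(mode_list(lmax), coeffs):
        if c != 0.0:
            out += c * real_sh(l, m, theta, phi)
    return out


def gauss_sphere_grid(n_theta: int, n_phi: int):
    """Product quadrature grid on the sphere.

    Gauss-Legendre nodes in cos(theta) crossed with a uniform azimuth grid.
    Returns 1-D ``theta`` (length n_theta), 1-D ``phi`` (length n_phi) and a
    2-D weight array summing to 4 pi.  The rule integrates spherical
    polynomials of degree <= min(2 n_theta - 1, n_phi - 1) exactly.
    """
    x, w = leggauss(n_theta)
    theta = np.arccos(x[::-1])  # increasing colatitude
    w = w[::-1]
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    weights = np.outer(w, np.full(n_phi, 2.0 * np.pi / n_phi))
    return theta, phi, weights
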