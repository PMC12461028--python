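"""Elastic solver: closed forms, equilibrium, oracle agreement, residuals."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import RadialBVPOracle, grid_search_min_radius_direction
from beadforce import _sh
from beadforce.elastic import (
    MaterialParams, build_mode_basis, compression_axis, navier_residual,
    stress_map, total_force,
)
from beadforce.fixtures import sphere_coeffs
from beadforce.shape import SHExpansion, align_shape, rotate_expansion


def make_expansion(coeffs):
    lmax = int(round(np.sqrt(len(coeffs)))) - 1
    return SHExpansion(lmax=lmax, coeffs=np.asarray(coeffs, float), center=np.zeros(3))


def random_expansion(rng, lmax=6, r0=5.0, scale=0.15):
    c = sphere_coeffs(r0, lmax)
    c[1:] += rng.normal(scale=scale, size=len(c) - 1)
    return make_expansion(c)


class TestMaterialParams:
    @pytest.mark.parametrize("G,nu", [(-1.0, 0.3), (0.0, 0.3), (100.0, 0.5), (100.0, -1.0)])
    def test_invalid_rejected(self, G, nu):
        with pytest.raises(ValueError):
            MaterialParams(G=G, nu=nu)

    def test_lame_lambda(self):
        mat = MaterialParams(G=1000.0, nu=0.25)
        assert mat.lame_lambda == pytest.approx(1000.0)


class TestHydrostatic:
    @pytest.mark.parametrize("G", [100.0, 1000.0, 10000.0])
    @pytest.mark.parametrize("nu", [0.3, 0.45, 0.49])
    def test_uniform_inflation_closed_form(self, G, nu):
        """l = 0 traction is 2G(1+nu)/(1-2nu) * u0/r0, uniformly."""
        r0, frac = 5.0, 0.01
        mat = MaterialParams(G=G, nu=nu)
        c = sphere_coeffs(r0 * (1 + frac), 2)
        smap = stress_map(make_expansion(c), mat, r0_override=r0)
        expected = 2 * G * (1 + nu) / (1 - 2 * nu) * frac
        np.testing.assert_allclose(smap.radial_traction, expected, rtol=1e-8)

    def test_compression_sign(self):
        mat = MaterialParams(G=1000.0, nu=0.45)
        c = sphere_coeffs(5.0 * (1 - 0.01), 2)  # fitted radius 4.95, true 5
        smap = stress_map(make_expansion(c), mat, r0_override=5.0)
        expected = -2 * 1000 * 1.45 / 0.1 * 0.01
        np.testing.assert_allclose(smap.radial_traction, expected, rtol=1e-8)


class TestStressMap:
    def test_sphere_inferred_radius_is_stress_free(self):
        mat = MaterialParams(G=1000.0, nu=0.45)
        smap = stress_map(make_expansion(sphere_coeffs(5.0, 4)), mat)
        assert np.max(np.abs(smap.radial_traction)) < 1e-10

    def test_superposition(self):
        mat = MaterialParams(G=500.0, nu=0.4)
        rng = np.random.default_rng(0)
        a = random_expansion(rng)
        b_coeffs = a.coeffs.copy()
        b_coeffs[1:] = rng.normal(scale=0.1, size=len(b_coeffs) - 1)
        b = make_expansion(b_coeffs)
        both = make_expansion(np.concatenate([[a.coeffs[0]], a.coeffs[1:] + b.coeffs[1:]]))
        r0 = 5.0
        sa = stress_map(a, mat, r0_override=r0)
        sb = stress_map(b, mat, r0_override=r0)
        sab = stress_map(both, mat, r0_override=r0)
        # l >= 1 parts superpose; the l = 0 deformation differs via c00
        delta = sa.radial_traction + sb.radial_traction - sab.radial_traction
        l0 = (
            (a.coeffs[0] + b.coeffs[0] - both.coeffs[0]) - np.sqrt(4 * np.pi) * r0
        )
        basis = build_mode_basis(0, mat, r0, cache=False)
        offset = l0 * basis.rr_scale[0] * _sh.real_sh(0, 0, 0.0, 0.0)
        np.testing.assert_allclose(delta, offset, rtol=1e-9, atol=1e-9)

    def test_linear_in_shear_modulus(self):
        rng = np.random.default_rng(4)
        exp = random_expansion(rng)
        s1 = stress_map(exp, MaterialParams(G=100.0, nu=0.4))
        s2 = stress_map(exp, MaterialParams(G=300.0, nu=0.4))
        np.testing.assert_allclose(3 * s1.radial_traction, s2.radial_traction, rtol=1e-10)

    def test_lmax_exceeding_basis_advises_rebuild(self):
        mat = MaterialParams(G=1000.0, nu=0.45)
        exp = random_expansion(np.random.default_rng(1), lmax=6)
        basis = build_mode_basis(4, mat, 5.0, cache=False)
        with pytest.raises(ValueError, match="rebuild"):
            stress_map(exp, mat, r0_override=5.0, basis=basis)

    def test_grid_weights_cover_sphere(self):
        exp = random_expansion(np.random.default_rng(2))
        smap = stress_map(exp, MaterialParams(G=1000.0, nu=0.45))
        assert np.all(smap.weights > 0)
        assert smap.weights.sum() == pytest.approx(4 * np.pi)


class TestTotalForce:
    def test_zero_map(self):
        smap = stress_map(make_expansion(sphere_coeffs(5.0, 2)),
                          MaterialParams(G=1000.0, nu=0.45))
        assert total_force(smap).force == pytest.approx(0.0, abs=1e-18)

    def test_hydrostatic_force_value(self):
        # |T_rr| = 290 Pa over a 5 um sphere: F = 290 * 4 pi (5e-6)^2 m^2
        mat = MaterialParams(G=1000.0, nu=0.45)
        c = sphere_coeffs(5.0 * 1.01, 2)
        smap = stress_map(make_expansion(c), mat, r0_override=5.0)
        fr = total_force(smap)
        assert fr.force == pytest.approx(290.0 * 4 * np.pi * 25e-12, rel=1e-8)

    def test_force_linear_in_amplitude(self):
        mat = MaterialParams(G=1000.0, nu=0.45)
        rng = np.random.default_rng(3)
        c = sphere_coeffs(5.0, 6)
        d = rng.normal(scale=0.1, size=len(c) - 1)
        c1 = c.copy(); c1[1:] += d
        c2 = c.copy(); c2[1:] += 2 * d
        f1 = total_force(stress_map(make_expansion(c1), mat, r0_override=5.0)).force
        f2 = total_force(stress_map(make_expansion(c2), mat, r0_override=5.0)).force
        assert f2 == pytest.approx(2 * f1, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equilibrium_net_traction_vanishes(self, seed):
        """Divergence-free stress: the signed vector integral is ~0."""
        mat = MaterialParams(G=1000.0, nu=0.45)
        exp = random_expansion(np.random.default_rng(seed))
        smap = stress_map(exp, mat)
        fr = total_force(smap)
        assert np.linalg.norm(fr.net_vector) < 1e-6 * fr.force

    def test_statistics_ordering(self):
        mat = MaterialParams(G=1000.0, nu=0.45)
        exp = random_expansion(np.random.default_rng(5))
        smap = stress_map(exp, mat)
        f_abs = total_force(smap, "abs_radial").force
        f_comp = total_force(smap, "compressive").force
        f_mag = total_force(smap, "traction_magnitude").force
        assert f_comp <= f_abs <= f_mag


class TestOracleAgreement:
    def test_quadrupole_mode_matches_collocation(self):
        """l=2, m=0 traction vs the independent Papkovich-Neuber solve."""
        G, nu, r0 = 1000.0, 0.49, 5.0
        mat = MaterialParams(G=G, nu=nu)
        c = sphere_coeffs(r0, 2)
        c[_sh.mode_index(2, 0)] = 0.3
        exp = make_expansion(c)
        smap = stress_map(exp, mat)
        defc = c.copy()
        defc[0] = 0.0
        oracle = RadialBVPOracle(2, r0, G, nu, smap.theta, smap.phi)
        t_ref = oracle.radial_traction(defc)
        num = np.sqrt(np.sum(smap.weights * (smap.radial_traction - t_ref) ** 2))
        den = np.sqrt(np.sum(smap.weights * t_ref**2))
        assert num / den < 0.01


class TestCompressionAxis:
    def test_oblate_squashed_along_y(self):
        c = sphere_coeffs(5.0, 2)
        c[_sh.mode_index(2, 0)] = -0.8
        base = make_expansion(c)  # squashed along z
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()  # z -> y
        tilted = rotate_expansion(base, R)
        axis, degen = compression_axis(tilted)
        assert not degen
        assert np.abs(axis @ np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0, abs=1e-8)

    def test_aligned_shape_axis_is_z(self):
        rng = np.random.default_rng(7)
        exp = random_expansion(rng, lmax=4)
        aligned, _ = align_shape(exp)
        axis, degen = compression_axis(aligned)
        assert not degen
        assert abs(axis[2]) == pytest.approx(1.0, abs=1e-8)

    def test_random_quadrupole_matches_grid_search(self):
        rng = np.random.default_rng(11)
        c = sphere_coeffs(5.0, 2)
        c[4:9] = rng.normal(scale=0.5, size=5)
        axis, degen = compression_axis(make_expansion(c))
        assert not degen
        ref = grid_search_min_radius_direction(c[4:9])
        assert abs(axis @ ref) > 0.999

    def test_sphere_is_degenerate(self):
        axis, degen = compression_axis(make_expansion(sphere_coeffs(5.0, 2)))
        assert degen
        assert np.all(np.isnan(axis))


class TestNavierResidual:
    def test_clean_basis_below_fd_limit(self):
        mat = MaterialParams(G=1000.0, nu=0.45)
        basis = build_mode_basis(5, mat, 5.0, cache=False)
        assert navier_residual(basis, n_probe=20, seed=0) < 1e-5

    def test_broken_family_coupling_detected(self):
        mat = MaterialParams(G=1000.0, nu=0.45)
        basis = build_mode_basis(4, mat, 5.0, cache=False)
        assert navier_residual(basis, n_probe=10, seed=0, beta_scale=1.1) > 1e-3

    def test_family_weights_still_solve_bulk_equation(self):
        # mis-weighted families break the BC, not the interior equation
        mat = MaterialParams(G=1000.0, nu=0.45)
        basis = build_mode_basis(4, mat, 5.0, cache=False)
        assert navier_residual(basis, n_probe=10, seed=0, b_scale=1.2) < 1e-5

    def test_seed_stability(self):
        mat = MaterialParams(G=1000.0, nu=0.3)
        basis = build_mode_basis(3, mat, 5.0, cache=False)
        r = [navier_residual(basis, n_probe=15, seed=s) for s in (1, 2)]
        assert 0.1 < r[0] / r[1] < 10.0


class TestBasisEngineering:
    def test_slicing_matches_direct_build(self):
        mat = MaterialParams(G=700.0, nu=0.42)
        full = build_mode_basis(15, mat, 5.0, cache=False)
        for lmax in (0, 3, 6):
            direct = build_mode_basis(lmax, mat, 5.0, cache=False)
            sliced = full.slice(lmax)
            np.testing.assert_array_equal(sliced.tau_rr, direct.tau_rr)
            np.testing.assert_array_equal(sliced.tau_rt, direct.tau_rt)

    def test_disk_cache_round_trip(self, tmp_path, monkeypatch):
        monkeypatch.setenv("XDG_CACHE_HOME", str(tmp_path))
        mat = MaterialParams(G=700.0, nu=0.42)
        a = build_mode_basis(8, mat, 5.0, cache=True)
        assert (tmp_path / "beadforce").exists()
        b = build_mode_basis(8, mat, 5.0, cache=True)  # from disk
        np.testing.assert_allclose(a.tau_rr, b.tau_rr)
        np.testing.assert_allclose(a.tau_rt, b.tau_rt)

    def test_nu_continuity(self):
        # (1 - 2 nu) * tau_rr stays bounded and smooth over the admissible
        # range; tau_rr itself diverges like the Lame lambda at nu -> 1/2
        nus = np.linspace(-0.9, 0.49, 140)
        taus = np.array([
            (1 - 2 * nu)
            * build_mode_basis(4, MaterialParams(G=1.0, nu=nu), 1.0, cache=False).tau_rr
            for nu in nus
        ])
        assert np.all(np.isfinite(taus))
        steps = np.abs(np.diff(taus, axis=0))
        assert steps.max() < 0.5
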