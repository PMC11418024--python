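"""Refinement algorithms against closed forms and the grid-descent oracle."""

import numpy as np
import pytest

from nanoreactor import units
from nanoreactor.refine import (constrained_scan, fd_hessian,
                                hessian_frequencies, irc, minimize, neb,
                                prereaction_complex, ts_optimize)


class Quadratic:
    """V = ½ Σ_i k_i (x_i − c_i)²; negative k_i makes a saddle direction."""

    def __init__(self, k, center):
        self.k = np.asarray(k, dtype=float)
        self.center = np.asarray(center, dtype=float)

    def evaluate(self, positions, elements=()):
        d = np.asarray(positions, dtype=float).ravel() - self.center
        e = 0.5 * float(np.sum(self.k * d**2))
        return e, (-self.k * d).reshape(np.shape(positions))


class Quartic1D:
    """Symmetric double well V = (x² − 1)²; minima ±1, barrier 1 at x = 0."""

    def evaluate(self, positions, elements=()):
        x = float(np.asarray(positions).ravel()[0])
        return (x**2 - 1) ** 2, np.array([[-4 * x * (x**2 - 1)]])


class PairSpring:
    """Diatomic with harmonic bond V = ½ kf (r − r0)²."""

    def __init__(self, kf, r0):
        self.kf, self.r0 = kf, r0

    def evaluate(self, positions, elements=()):
        vec = positions[1] - positions[0]
        r = float(np.linalg.norm(vec))
        e = 0.5 * self.kf * (r - self.r0) ** 2
        u = vec / r
        f = np.zeros_like(positions)
        f[1] = -self.kf * (r - self.r0) * u
        f[0] = +self.kf * (r - self.r0) * u
        return e, f


class TestMinimize:
    def test_already_at_minimum_stops_immediately(self):
        q = Quadratic([1.0, 1.0], [0.3, -0.2])
        res = minimize(np.array([[0.3, -0.2]]), q, grad_tol=1e-10)
        assert res.converged and res.n_iterations == 0
        np.testing.assert_array_equal(res.positions, [[0.3, -0.2]])

    def test_harmonic_well_converges_to_center(self):
        q = Quadratic([0.5], [1.7])
        res = minimize(np.array([[0.0]]), q, max_step=0.1, grad_tol=1e-8)
        assert res.converged
        assert res.positions.ravel()[0] == pytest.approx(1.7, abs=1e-8 / 0.5)

    def test_mb_basins_match_oracle(self, mb_surface, mb_stationary_points):
        for target, e_ref, _ in mb_stationary_points["minima"]:
            start = target + np.array([0.05, -0.04])
            res = minimize(start.reshape(1, 2), mb_surface, max_step=0.05,
                           grad_tol=1e-8)
            assert res.converged
            np.testing.assert_allclose(res.positions.ravel(), target, atol=1e-4)

    def test_never_increases_energy(self, mb_surface):
        rng = np.random.default_rng(0)
        for _ in range(5):
            start = rng.uniform([-1.5, -0.2], [1.0, 2.0]).reshape(1, 2)
            e0, _ = mb_surface.evaluate(start)
            res = minimize(start, mb_surface, max_step=0.05, grad_tol=1e-6)
            assert res.energy <= e0 + 1e-12

    def test_iteration_cap_returns_unconverged(self):
        q = Quadratic([1e-9], [1e6])
        res = minimize(np.array([[0.0]]), q, max_step=0.015, max_iter=5)
        assert not res.converged


class TestNEB:
    def test_degenerate_endpoints_rejected(self, mb_surface):
        a = np.array([[0.5, 0.5]])
        with pytest.raises(ValueError, match="degenerate"):
            neb(a, a.copy(), mb_surface)

    def test_quartic_double_well_barrier(self):
        surf = Quartic1D()
        path = neb(np.array([[-1.0]]), np.array([[1.0]]), surf, n_images=11,
                   spring_k=1.0, climbing=True, tol=1e-6, max_disp=0.05)
        top = path.energies.max()
        assert top == pytest.approx(1.0, rel=1e-3)
        assert path.images[path.highest_index].ravel()[0] == pytest.approx(0.0, abs=1e-3)

    def test_mb_climbing_image_finds_oracle_saddle(self, mb_surface,
                                                   mb_stationary_points):
        minima = mb_stationary_points["minima"]
        # the deepest minimum (A) and the shallow central one (C) flank the
        # higher-energy of the two saddles
        saddle_pos, saddle_e, _ = mb_stationary_points["saddles"][1]
        a = min(minima, key=lambda m: m[1])[0]
        c = sorted(minima, key=lambda m: m[1])[2][0]
        path = neb(a.reshape(1, 2), c.reshape(1, 2), mb_surface, n_images=15,
                   spring_k=50.0, climbing=True, tol=0.5, max_iter=8000,
                   max_disp=0.02)
        ci = path.images[path.highest_index].ravel()
        e_ci = path.energies[path.highest_index]
        assert abs(e_ci - saddle_e) / abs(saddle_e) <= 1e-3
        np.testing.assert_allclose(ci, saddle_pos, atol=5e-3)


class TestTSOptimize:
    def test_exact_quadratic_saddle_immediate(self):
        q = Quadratic([-0.5, 1.0], [0.0, 0.0])
        res = ts_optimize(np.array([[0.0, 0.0]]), q, grad_tol=1e-10,
                          displacement=1e-4)
        assert res.converged and res.n_imaginary == 1 and res.n_iterations == 0

    def test_mb_saddles_match_oracle(self, mb_surface, mb_stationary_points):
        for saddle_pos, saddle_e, _ in mb_stationary_points["saddles"]:
            start = saddle_pos + np.array([0.02, -0.015])
            res = ts_optimize(start.reshape(1, 2), mb_surface, grad_tol=1e-8,
                              max_step=0.05, displacement=1e-4)
            assert res.converged and res.n_imaginary == 1
            np.testing.assert_allclose(res.positions.ravel(), saddle_pos, atol=1e-4)
            assert res.energy == pytest.approx(saddle_e, rel=1e-6)

    def test_single_well_flagged_failure(self):
        q = Quadratic([1.0, 2.0], [0.0, 0.0])
        res = ts_optimize(np.array([[0.4, 0.3]]), q, grad_tol=1e-10,
                          displacement=1e-4)
        # no saddle exists: the search must come back flagged, never as a
        # successful first-order saddle
        assert res.n_imaginary == 0
        assert not res.is_first_order


class TestIRC:
    def test_double_well_branches_mirror(self):
        surf = Quartic1D()
        res = irc(np.array([[0.0]]), surf, masses=np.array([1.0]),
                  step=0.01, grad_tol=1e-8, displacement=1e-4)
        ends = sorted([res.path_minus.endpoint.positions.ravel()[0],
                       res.path_plus.endpoint.positions.ravel()[0]])
        np.testing.assert_allclose(ends, [-1.0, 1.0], atol=1e-6)

    def test_mb_saddles_connect_adjacent_minima(self, mb_surface,
                                                mb_stationary_points):
        minima = [m[0] for m in mb_stationary_points["minima"]]
        for saddle_pos, _, _ in mb_stationary_points["saddles"]:
            res = irc(saddle_pos.reshape(1, 2), mb_surface,
                      masses=np.array([1.0]), step=0.01, grad_tol=1e-7,
                      displacement=1e-4)
            ends = [res.path_minus.endpoint.positions.ravel(),
                    res.path_plus.endpoint.positions.ravel()]
            matched = set()
            for e in ends:
                dists = [np.linalg.norm(e - m) for m in minima]
                k = int(np.argmin(dists))
                assert dists[k] <= 1e-3
                matched.add(k)
            assert len(matched) == 2   # two different basins

    def test_no_imaginary_mode_rejected(self):
        q = Quadratic([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="imaginary"):
            irc(np.array([[0.0, 0.0]]), q, masses=np.array([1.0]),
                displacement=1e-4)


class TestFrequencies:
    def test_harmonic_diatomic_closed_form(self):
        kf, r0 = 0.3, 1.2
        m = np.array([1.008, 12.011])
        mu = m[0] * m[1] / m.sum()
        surf = PairSpring(kf, r0)
        pos = np.array([[0, 0, 0], [0, 0, r0]])
        res = hessian_frequencies(pos, surf, m)
        nu_expect = np.sqrt(kf / mu) / (2 * np.pi) * units.FS_INV_TO_CM_INV
        assert len(res.frequencies_cm) == 1     # 3N − 5 for a linear molecule
        assert res.frequencies_cm[0] == pytest.approx(nu_expect, rel=1e-3)

    def test_morse_dimer_analytic_frequency(self, morse, table):
        prm = table.morse("H", "H")
        m = np.array([1.008, 1.008])
        mu = m[0] * m[1] / m.sum()
        pos = np.array([[0, 0, 0], [0, 0, prm.re]])
        res = hessian_frequencies(pos, morse, m, ("H", "H"))
        nu_expect = prm.a * np.sqrt(2 * prm.De / mu) / (2 * np.pi) * units.FS_INV_TO_CM_INV
        assert res.frequencies_cm[-1] == pytest.approx(nu_expect, rel=5e-3)

    def test_mb_saddle_single_negative_eigenvalue(self, mb_surface,
                                                  mb_stationary_points):
        for saddle_pos, _, _ in mb_stationary_points["saddles"]:
            H = fd_hessian(saddle_pos.reshape(1, 2), mb_surface,
                           displacement=1e-4)
            eig = np.linalg.eigvalsh(H)
            assert (eig < 0).sum() == 1

    def test_zpve_rotation_invariant(self, morse):
        from scipy.spatial.transform import Rotation
        m = np.array([1.008, 1.008])
        pos = np.array([[0, 0, 0], [0, 0, 0.741]])
        # small displacement: the h² anharmonic contamination of the FD
        # Hessian is the only orientation-dependent term
        res0 = hessian_frequencies(pos, morse, m, ("H", "H"), displacement=5e-4)
        rot = Rotation.from_euler("xyz", [33, -71, 140], degrees=True)
        res1 = hessian_frequencies(rot.apply(pos), morse, m, ("H", "H"),
                                   displacement=5e-4)
        assert res1.zpve_kj_per_mol == pytest.approx(res0.zpve_kj_per_mol,
                                                     rel=1e-6)

    def test_classification_stable_under_displacement_halving(self, leps):
        # toy exchange saddle: same imaginary count at h and h/2
        pos = np.array([[0, 0, 0], [0.994, 0, 0], [0.994 + 1.284, 0, 0]])
        ts = ts_optimize(pos, leps, ("H", "H", "C"), grad_tol=1e-8)
        m = np.array([1.008, 1.008, 12.011])
        r1 = hessian_frequencies(ts.positions, leps, m, ("H", "H", "C"),
                                 displacement=0.005)
        r2 = hessian_frequencies(ts.positions, leps, m, ("H", "H", "C"),
                                 displacement=0.0025)
        assert r1.n_imaginary == r2.n_imaginary == 1

    def test_nonstationary_geometry_warns(self, morse):
        pos = np.array([[0, 0, 0], [0, 0, 1.1]])
        with pytest.warns(UserWarning, match="non-stationary"):
            hessian_frequencies(pos, morse, np.array([1.008, 1.008]), ("H", "H"))


class ZeroCross:
    """Two fragments with no inter-fragment interaction at all."""

    def evaluate(self, positions, elements=()):
        return 0.0, np.zeros_like(positions)


class TestPrereactionComplex:
    def test_noninteracting_fragments_zero_binding(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[1.0, 0, 0]])
        res = prereaction_complex(a, b, a, b + 6.0, ZeroCross(), ("He", "He"),
                                  grad_tol=1e-12)
        assert res.binding_energy == 0.0

    def test_two_lj_helium_atoms(self, morse, table):
        lj = table.lj("He", "He")
        a = np.array([[0.0, 0, 0]])
        b = np.array([[0.0, 0, 1.0]])
        template_b = np.array([[0.0, 0, 6.0]])
        res = prereaction_complex(a, b, a, template_b, morse, ("He", "He"),
                                  grad_tol=1e-10, max_step=0.05)
        r = np.linalg.norm(res.opt.positions[1] - res.opt.positions[0])
        assert r == pytest.approx(2 ** (1 / 6) * lj.sigma, rel=1e-4)
        assert res.binding_energy == pytest.approx(-lj.eps, rel=1e-4)

    def test_initial_separation_exceeds_five_angstrom(self, morse):
        a = np.array([[0.0, 0, 0], [0, 0, 0.741]])
        b = np.array([[0.0, 0, 2.0]])
        res = prereaction_complex(a, b, a, b, morse, ("H", "H", "H"),
                                  grad_tol=1e-3)
        d0 = np.linalg.norm(
            res.initial_positions[:2, None, :] - res.initial_positions[None, 2:, :],
            axis=-1)
        assert d0.min() > 5.0

    def test_coincident_centroids_rejected(self):
        a = np.array([[0.0, 0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            prereaction_complex(a, a.copy(), a, a.copy(), ZeroCross(), ("He", "He"))


class TestConstrainedScan:
    def test_diatomic_scan_reproduces_morse_curve(self, morse, table):
        prm = table.morse("H", "H")
        grid = np.linspace(0.5, 2.0, 16)
        pos = np.array([[0, 0, 0], [0, 0, 0.9]])
        prof = constrained_scan(pos, morse, ("H", "H"), (0, 1), grid)
        for d, e, _ in prof:
            expect = prm.De * ((1 - np.exp(-prm.a * (d - prm.re))) ** 2 - 1)
            assert e == pytest.approx(expect, abs=1e-10)

    def test_profile_maximum_near_saddle_pair_distance(self, leps):
        """Scanning the C···H approach distance of the H2 + C entrance
        channel (relaxing everything else) peaks within one grid spacing
        of the saddle's C–H distance — the standard entrance-barrier
        search."""
        ts = ts_optimize(np.array([[0, 0, 0], [0.994, 0, 0], [2.278, 0, 0]]),
                         leps, ("H", "H", "C"), grad_tol=1e-8)
        r_saddle = np.linalg.norm(ts.positions[2] - ts.positions[1])
        grid = np.arange(3.0, 1.0, -0.1)
        start = np.array([[0, 0, 0], [0.741, 0, 0], [0.741 + 3.0, 0, 0]])
        prof = constrained_scan(start, leps, ("H", "H", "C"), (1, 2), grid,
                                grad_tol=1e-6)
        ds = [p[0] for p in prof]
        es = [p[1] for p in prof]
        assert abs(ds[int(np.argmax(es))] - r_saddle) <= 0.1 + 1e-9

    def test_single_point_grid_matches_constrained_minimum(self, morse):
        pos = np.array([[0, 0, 0], [0, 0, 1.0]])
        prof = constrained_scan(pos, morse, ("H", "H"), (0, 1), [1.0])
        assert len(prof) == 1
        assert np.linalg.norm(prof[0][2][1] - prof[0][2][0]) == pytest.approx(1.0)

    def test_identical_atoms_rejected(self, morse):
        with pytest.raises(ValueError, match="distinct"):
            constrained_scan(np.zeros((2, 3)), morse, ("H", "H"), (1, 1), [1.0])

    def test_non_monotone_grid_rejected(self, morse):
        with pytest.raises(ValueError, match="monotone"):
            constrained_scan(np.array([[0, 0, 0], [0, 0, 1.0]]), morse,
                             ("H", "H"), (0, 1), [1.0, 0.8, 1.2])
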