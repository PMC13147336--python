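"""Geometric primitives against analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hemebundle.errors import (
    DegenerateGeometryError,
    ElementError,
    InsufficientDataError,
)
from hemebundle.geometry import (
    center_of_mass,
    dihedral,
    ensemble_rmsd,
    fit_helix_axis,
    fit_plane,
    sasa,
    superpose,
)
from hemebundle.structure_io import AtomRecord, Model, SelectionSpec
from hemebundle.synthetic import SandwichBlueprint, assemble_sandwich, build_ideal_helix


def _atom(name, element, pos, resnum=1):
    return AtomRecord("A", resnum, "UNK", name, element, np.asarray(pos, float))


# ---------------------------------------------------------------------------
# fit_plane
# ---------------------------------------------------------------------------

class TestFitPlane:
    def test_unit_square_in_z0(self):
        pts = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        p = fit_plane(pts)
        assert abs(abs(p.unit_normal[2]) - 1.0) < 1e-12
        assert p.rms_residual < 1e-12

    def test_three_points_zero_residual(self, rng):
        pts = rng.normal(size=(3, 3))
        assert fit_plane(pts).rms_residual < 1e-10

    def test_noisy_plane_recovery_monte_carlo(self, rng):
        # 100 points on a known tilted plane + N(0, 0.05 Å) noise:
        # recovered normal within 2° of truth
        true_n = np.array([1.0, 2.0, 3.0])
        true_n = true_n / np.linalg.norm(true_n)
        basis = np.linalg.svd(np.outer(true_n, true_n))[0][:, 1:]
        for _ in range(20):
            uv = rng.uniform(-5, 5, size=(100, 2))
            pts = uv @ basis.T + rng.normal(0, 0.05, size=(100, 3))
            p = fit_plane(pts)
            ang = np.degrees(np.arccos(min(abs(p.unit_normal @ true_n), 1.0)))
            assert ang < 2.0

    def test_reference_up_fixes_sign(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        up = np.array([0.0, 0.0, -1.0])
        p = fit_plane(pts, reference_up=up)
        assert p.unit_normal @ up >= 0

    def test_collinear_rejected(self):
        pts = [(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3)]
        with pytest.raises(DegenerateGeometryError):
            fit_plane(pts)


# ---------------------------------------------------------------------------
# fit_helix_axis
# ---------------------------------------------------------------------------

class TestHelixAxis:
    def test_canonical_alpha_helix_rise(self):
        m = build_ideal_helix(["ALA"] * 12, -57.0, -47.0)
        ca = np.array([a.position for a in m.atoms if a.atom_name == "CA"])
        axis = fit_helix_axis(ca)
        assert axis.rise_per_residue == pytest.approx(1.5, abs=0.1)

    def test_rotation_equivariance(self, rng):
        m = build_ideal_helix(["ALA"] * 10, -57.0, -47.0)
        ca = np.array([a.position for a in m.atoms if a.atom_name == "CA"])
        d0 = fit_helix_axis(ca).unit_direction
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            d1 = fit_helix_axis(ca @ R.T).unit_direction
            assert np.allclose(d1, R @ d0, atol=1e-6)

    def test_collinear_points_direct_line(self):
        pts = np.outer(np.arange(6), [1.0, 1.0, 0.0])
        axis = fit_helix_axis(pts)
        want = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        assert np.allclose(np.abs(axis.unit_direction @ want), 1.0, atol=1e-9)
        # oriented first -> last residue
        assert axis.unit_direction @ (pts[-1] - pts[0]) > 0

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_helix_axis(np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# dihedral
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p4,expected",
    [
        ((1.0, 1.0, 1.0), 0.0),      # cis: p4 on the same side as p1
        ((1.0, -1.0, 1.0), 180.0),   # trans
    ],
)
def test_dihedral_planar_conventions(p4, expected):
    ang = dihedral((1, 1, 0), (1, 0, 0), (1, 0, 1), p4)
    assert ang == pytest.approx(expected, abs=1e-9)


def test_dihedral_rigid_invariance(rng):
    pts = rng.normal(size=(4, 3)) * 3
    ref = dihedral(*pts)
    for _ in range(10):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3)
        moved = pts @ R.T + t
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-8)


def test_dihedral_coincident_points_rejected():
    with pytest.raises(DegenerateGeometryError):
        dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))


# ---------------------------------------------------------------------------
# superpose
# ---------------------------------------------------------------------------

class TestSuperpose:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        r = superpose(x, x)
        assert r.rmsd < 1e-9
        assert np.allclose(r.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovered(self, rng):
        x = rng.normal(size=(25, 3)) * 4
        R = Rotation.random(rng=rng).as_matrix()
        y = x @ R.T + np.array([1.0, -2.0, 3.0])
        r = superpose(x, y)
        assert r.rmsd < 1e-9
        assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_vs_brute_force_quaternion_search(self, rng):
        # independent oracle: seeded coarse-to-fine random search over
        # rotations (translation solved by centroid matching); no use of
        # the analytic Kabsch solution
        x = rng.normal(size=(50, 3)) * 3
        y = x + rng.normal(0, 0.5, size=x.shape)
        got = superpose(x, y).rmsd

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)

        def score(mats):
            trial = np.einsum("rij,nj->rni", mats, yc)
            return np.sqrt(np.mean(np.sum((trial - xc) ** 2, axis=2), axis=1))

        orng = np.random.default_rng(0)
        cand = Rotation.random(4000, rng=orng)
        best_rot = cand[int(np.argmin(score(cand.as_matrix())))]
        best = float(score(best_rot.as_matrix()[None])[0])
        for angle in (0.2, 0.05, 0.01, 0.002):
            perturb = Rotation.from_rotvec(
                orng.normal(0, angle, size=(2000, 3)))
            cand = perturb * best_rot
            s = score(cand.as_matrix())
            k = int(np.argmin(s))
            if s[k] < best:
                best, best_rot = float(s[k]), cand[k]
        assert got <= best + 1e-9           # ours is the optimum
        assert got == pytest.approx(best, rel=0.10)

    def test_rmsd_symmetric(self, rng):
        x = rng.normal(size=(12, 3))
        y = x + rng.normal(0, 0.3, size=x.shape)
        assert superpose(x, y).rmsd == pytest.approx(superpose(y, x).rmsd, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            superpose(np.zeros((5, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# ensemble_rmsd
# ---------------------------------------------------------------------------

class TestEnsembleRMSD:
    def test_identical_models_zero(self, clean_sandwich):
        ens, _ = clean_sandwich
        r = ensemble_rmsd(ens)
        assert r.mean == pytest.approx(0.0, abs=1e-9)
        assert r.sd == pytest.approx(0.0, abs=1e-9)

    def test_jittered_vs_simulation_oracle(self):
        # independent oracle: mean RMS deviation to the sample mean for
        # iid N(0, σ²) per-coordinate noise, estimated by direct
        # simulation without any superposition machinery
        sigma, n_models, n_atoms = 0.3, 20, 120
        orng = np.random.default_rng(99)
        vals = []
        for _ in range(200):
            x = orng.normal(0, sigma, size=(n_models, n_atoms, 3))
            mean = x.mean(axis=0)
            vals.append(
                np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=1)).mean()
            )
        oracle = float(np.mean(vals))

        bp = SandwichBlueprint(jitter_sd=sigma, n_models=n_models, seed=4)
        ens, _ = assemble_sandwich(bp)
        got = ensemble_rmsd(ens, SelectionSpec.make(atom_names={"N", "CA", "C", "O"}))
        assert got.mean == pytest.approx(oracle, rel=0.15)


# ---------------------------------------------------------------------------
# center_of_mass
# ---------------------------------------------------------------------------

class TestCenterOfMass:
    def test_symmetric_pair(self):
        atoms = [_atom("C1", "C", (1, 0, 0)), _atom("C2", "C", (-1, 0, 0))]
        assert np.allclose(center_of_mass(atoms), 0.0)

    def test_single_atom(self):
        a = _atom("O", "O", (2.0, -1.0, 0.5))
        assert np.allclose(center_of_mass([a]), a.position)

    def test_mass_weighting_co_pair(self):
        atoms = [_atom("C", "C", (0, 0, 0)), _atom("O", "O", (0, 0, 1))]
        com = center_of_mass(atoms, weighting="mass")
        # z = m_O / (m_C + m_O)
        assert com[2] == pytest.approx(15.999 / (12.011 + 15.999), abs=1e-6)

    def test_unknown_element_rejected(self):
        with pytest.raises(ElementError):
            center_of_mass([_atom("Q1", "Qq", (0, 0, 0))], weighting="mass")


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_model(positions, r_element="C"):
    return Model(
        index=1,
        atoms=[_atom(f"C{i}", r_element, p, resnum=i + 1)
               for i, p in enumerate(positions)],
    )


class TestSASA:
    def test_isolated_sphere_area(self):
        # r = 1.6 + probe 1.4 -> 4π·3² = 113.097 Å²
        m = _sphere_model([(0, 0, 0)])
        areas, total = sasa(m, probe_radius=1.4, n_sphere_points=960,
                            radii={"C": 1.6})
        assert total == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_distant_spheres_unoccluded(self):
        m = _sphere_model([(0, 0, 0), (10.0, 0, 0)])
        areas, total = sasa(m, probe_radius=1.4, n_sphere_points=960,
                            radii={"C": 1.6})
        iso = 4 * np.pi * 3.0**2
        assert np.allclose(areas, iso, rtol=1e-9)

    def test_two_overlapping_spheres_analytic(self):
        # equal solvent spheres R at center distance d: each loses a cap
        # of height h = R - d/2; accessible = 2·(4πR² - 2πRh)
        R, d = 1.6 + 1.4, 2.0
        m = _sphere_model([(0, 0, 0), (d, 0, 0)])
        _, total = sasa(m, probe_radius=1.4, n_sphere_points=2000,
                        radii={"C": 1.6})
        h = R - d / 2
        analytic = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
        assert total == pytest.approx(analytic, rel=0.02)

    def test_monotone_in_context_removal(self, rng):
        pts = rng.normal(0, 2.0, size=(8, 3))
        m_full = _sphere_model(pts)
        spec = SelectionSpec.make(residue_range=(1, 7))
        full_areas, _ = sasa(m_full, spec, n_sphere_points=500)
        m_less = _sphere_model(pts[:-1])   # drop one context atom
        less_areas, _ = sasa(m_less, spec, n_sphere_points=500)
        assert np.all(less_areas >= full_areas - 1e-9)
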