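import math

import numpy as np
import pytest
from scipy.integrate import quad

from iwmgb.constants import ALPB_ALPHA
from iwmgb.electrostatics import (
    DielectricModel,
    atom_average_scd,
    electrostatic_size,
    scd_on_mesh,
    total_induced_charge,
)
from iwmgb.model_io import Atom, Molecule
from iwmgb.surfaces import assign_nearest_atoms, icosphere
from tests.conftest import single_atom


def _diel(esize, kappa=0.0):
    return DielectricModel(esize=esize, kappa=kappa)


def _charged_sphere(q=1.0, R=2.0, sub=4):
    mol = single_atom(radius=R, charge=q)
    mesh = icosphere(np.zeros(3), R, sub)
    return mol, mesh


class TestElectrostaticSize:
    def test_single_atom_is_its_radius(self):
        assert electrostatic_size(single_atom(radius=3.0)) == pytest.approx(3.0, abs=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(scale=2.0, size=(5, 3))
        rad = rng.uniform(1.0, 2.0, size=5)
        mols = [
            Molecule(f"s{s}", [
                Atom(i, "C", s * pos[i], 0.0, s * rad[i]) for i in range(5)
            ])
            for s in (1.0, 2.0)
        ]
        assert electrostatic_size(mols[1]) == pytest.approx(
            2.0 * electrostatic_size(mols[0]), rel=1e-10
        )

    def test_linear_shape_larger_than_compact_at_equal_volume(self):
        lin = Molecule("lin", [
            Atom(i, "C", np.array([2.5 * i, 0.0, 0.0]), 0.0, 1.5) for i in range(3)
        ])
        verts = 2.5 * np.array([[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]])
        tri = Molecule("tri", [Atom(i, "C", verts[i], 0.0, 1.5) for i in range(3)])
        assert electrostatic_size(lin) > electrostatic_size(tri)

    def test_against_numeric_capacitance_oracle(self):
        # independent oracle: direct quadrature of the ellipsoid capacitance
        lin = Molecule("lin", [
            Atom(i, "C", np.array([2.0 * i, 0.0, 0.0]), 0.0, 1.3) for i in range(4)
        ])
        pos, rad = lin.positions, lin.radii
        w = rad**3 / (rad**3).sum()
        c = (w[:, None] * pos).sum(axis=0)
        cov = np.einsum("i,ij,ik->jk", w, pos - c, pos - c)
        cov += np.eye(3) * (w * rad**2).sum() / 5.0
        a2 = 5.0 * np.linalg.eigvalsh(cov)
        val, _ = quad(lambda t: ((t + a2[0]) * (t + a2[1]) * (t + a2[2])) ** -0.5,
                      0, np.inf, limit=200)
        assert electrostatic_size(lin) == pytest.approx(2.0 / val, rel=1e-8)

    def test_fallback_estimator_positive(self):
        assert electrostatic_size(single_atom(radius=2.0), fallback=True) > 0


class TestScd:
    def test_zero_charges_zero_field(self):
        mol, mesh = _charged_sphere(q=0.0)
        f = scd_on_mesh(mol, mesh, _diel(2.0))
        assert np.all(f.sigma_T == 0.0)

    def test_linearity_and_sign_flip(self):
        mol, mesh = _charged_sphere(q=0.7)
        d = _diel(2.0)
        base = scd_on_mesh(mol, mesh, d).sigma_T
        mol.atoms[0].charge *= 2
        np.testing.assert_allclose(scd_on_mesh(mol, mesh, d).sigma_T, 2 * base, rtol=1e-12)
        mol.atoms[0].charge = -0.7
        np.testing.assert_allclose(scd_on_mesh(mol, mesh, d).sigma_T, -base, rtol=1e-12)

    def test_central_charge_sphere_uniform_and_matches_closed_form(self):
        q, R = 1.0, 2.0
        mol, mesh = _charged_sphere(q=q, R=R)
        d = _diel(R)  # A = R for a sphere
        f = scd_on_mesh(mol, mesh, d)
        spread = (f.sigma_T.max() - f.sigma_T.min()) / abs(f.sigma_T.mean())
        assert spread < 0.01
        # independent closed-form evaluation on the sphere: the radial kernel
        # is (1/R^2 + alpha*beta/(A R)) with A = R
        beta = d.beta
        ab = ALPB_ALPHA * beta
        expected = (
            -(1 / (4 * math.pi)) * (1 - beta) / (1 + ab) * q
            * (1.0 / R**2 + ab / (R * R))
        )
        assert f.sigma_T.mean() == pytest.approx(expected, rel=1e-3)

    def test_total_induced_charge_opposes_source(self):
        q = 1.0
        mol, mesh = _charged_sphere(q=q, R=2.0, sub=4)
        f = scd_on_mesh(mol, mesh, _diel(2.0))
        induced = total_induced_charge(f)
        assert induced < 0
        # brute-force vertex-quadrature oracle of the same surface integral
        beta = 1 / 80.0
        expected = -q * (1 - beta)
        assert induced == pytest.approx(expected, rel=0.005)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(5)
        mol = Molecule("pair", [
            Atom(0, "O", np.array([0.4, 0.1, -0.2]), -0.5, 1.5),
            Atom(1, "H", np.array([-0.6, 0.3, 0.5]), 0.5, 1.2),
        ])
        mesh = icosphere(np.zeros(3), 3.0, 3)
        d = _diel(3.0)
        base = scd_on_mesh(mol, mesh, d).sigma_T
        # random rotation applied to both molecule and mesh
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        rot_mol = Molecule("rot", [
            Atom(a.index, a.element, Q @ a.position, a.charge, a.radius)
            for a in mol.atoms
        ])
        rot_mesh = type(mesh)(
            vertices=mesh.vertices @ Q.T, triangles=mesh.triangles, kind="SES"
        )
        rot = scd_on_mesh(rot_mol, rot_mesh, d).sigma_T
        np.testing.assert_allclose(rot, base, rtol=1e-10)

    def test_vertex_on_charge_rejected(self):
        mol = single_atom(radius=1.0, charge=1.0)
        mesh = icosphere(np.zeros(3), 1e-8, 1)
        with pytest.raises(ValueError, match="coincides"):
            scd_on_mesh(mol, mesh, _diel(1.0))


class TestAtomAverages:
    def test_uniform_field_gives_uniform_atom_values(self):
        mol, mesh = _charged_sphere(q=1.0)
        mesh = assign_nearest_atoms(mesh, mol)
        f = scd_on_mesh(mol, mesh, _diel(2.0))
        f = atom_average_scd(f, len(mol))
        assert f.sigma_atom[0] == pytest.approx(f.sigma_T.mean(), rel=1e-9)

    def test_plain_mean_over_owned_triangles(self):
        mol, mesh = _charged_sphere()
        mesh = assign_nearest_atoms(mesh, mol)
        f = scd_on_mesh(mol, mesh, _diel(2.0))
        f.sigma_T = np.zeros_like(f.sigma_T)
        f.sigma_T[:3] = [0.1, 0.2, 0.3]
        f = atom_average_scd(f, 1)
        assert f.sigma_atom[0] == pytest.approx(f.sigma_T.mean())

    def test_buried_atom_flagged_not_zeroed(self):
        mol = Molecule("two", [
            Atom(0, "C", np.zeros(3), 0.0, 2.0),
            Atom(1, "O", np.array([0.1, 0.0, 0.0]), 0.5, 0.5),
        ])
        mesh = icosphere(np.zeros(3), 2.0, 2)
        mesh.nearest_atom_T = np.zeros(mesh.n_triangles, dtype=np.int64)  # atom 1 buried
        f = scd_on_mesh(mol, mesh, _diel(2.0))
        f = atom_average_scd(f, 2)
        assert np.isfinite(f.sigma_atom[0])
        assert np.isnan(f.sigma_atom[1])
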