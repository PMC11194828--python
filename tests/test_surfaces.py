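import numpy as np
import pytest

from iwmgb.model_io import Atom, Molecule
from iwmgb.surfaces import (
    MeshError,
    assign_nearest_atoms,
    build_surfaces,
    export_mesh,
    icosphere,
    import_mesh,
    sasa,
)
from tests.conftest import single_atom


def sphere_area(r):
    return 4.0 * np.pi * r**2


class TestBuildSurfaces:
    def test_single_sphere_areas_within_one_percent(self):
        sp = build_surfaces(single_atom(radius=2.0), probe_radius=1.4, grid_spacing=0.25)
        assert sp.ses.total_area() == pytest.approx(sphere_area(2.0), rel=0.01)
        assert sp.sas.total_area() == pytest.approx(sphere_area(3.4), rel=0.01)

    def test_distant_dimer_gives_two_components_additive_area(self):
        mol = Molecule("far", [
            Atom(0, "C", np.zeros(3), 0.0, 2.0),
            Atom(1, "C", np.array([100.0, 0.0, 0.0]), 0.0, 2.0),
        ])
        sp = build_surfaces(mol, probe_radius=1.4, grid_spacing=0.25)
        assert sp.ses.total_area() == pytest.approx(2 * sphere_area(2.0), rel=0.01)
        owners = np.bincount(sp.ses.nearest_atom_T, minlength=2)
        assert owners[0] > 0 and owners[1] > 0

    def test_single_sphere_convergence_under_grid_halving(self):
        mol = single_atom(radius=2.5)
        exact = sphere_area(2.5)
        a_h = build_surfaces(mol, 1.4, 0.25).ses.total_area()
        a_h2 = build_surfaces(mol, 1.4, 0.125).ses.total_area()
        assert abs(a_h2 - a_h) / exact < 0.005
        # order >= 1: the finer mesh is strictly closer to the analytic area
        assert abs(a_h2 - exact) < abs(a_h - exact)

    def test_coincident_atoms_rejected(self):
        mol = Molecule("dup", [
            Atom(0, "C", np.zeros(3), 0.0, 1.7),
            Atom(1, "O", np.zeros(3), 0.0, 1.5),
        ])
        with pytest.raises(MeshError, match="coincident"):
            build_surfaces(mol, 0.8, 0.5)

    def test_bad_probe_or_grid_rejected(self):
        with pytest.raises(MeshError):
            build_surfaces(single_atom(), probe_radius=-1.0, grid_spacing=0.5)
        with pytest.raises(MeshError):
            build_surfaces(single_atom(), probe_radius=0.8, grid_spacing=2.0)

    @pytest.mark.parametrize("probe,grid", [(0.8, 0.5), (1.4, 0.4)])
    def test_closed_mesh_invariants(self, probe, grid):
        mol = Molecule("dimer", [
            Atom(0, "C", np.zeros(3), 0.0, 1.7),
            Atom(1, "O", np.array([1.4, 0.0, 0.0]), 0.0, 1.5),
        ])
        sp = build_surfaces(mol, probe, grid)
        for mesh in (sp.ses, sp.sas):
            assert mesh.signed_volume() > 0
            assert np.all(mesh.area_T > 0)
            np.testing.assert_allclose(
                np.linalg.norm(mesh.normal_T, axis=1), 1.0, atol=1e-8
            )
            # Gauss: the vector area of any closed surface vanishes
            vec_area = (mesh.normal_T * mesh.area_T[:, None]).sum(axis=0)
            assert np.abs(vec_area).max() < 1e-6 * mesh.total_area()

    def test_sas_encloses_ses(self):
        sp = build_surfaces(single_atom(radius=2.0), 1.0, 0.4)
        r_ses = np.linalg.norm(sp.ses.vertices, axis=1).max()
        r_sas = np.linalg.norm(sp.sas.vertices, axis=1).min()
        assert r_sas > r_ses


class TestNearestAtoms:
    def test_single_atom_owns_everything(self):
        mesh = icosphere(np.zeros(3), 2.0, 3)
        mol = single_atom(radius=2.0)
        mesh = assign_nearest_atoms(mesh, mol)
        assert np.all(mesh.nearest_atom_T == 0)

    def test_homonuclear_diatomic_splits_evenly(self):
        mol = Molecule("h2", [
            Atom(0, "C", np.array([-1.0, 0.0, 0.0]), 0.0, 1.7),
            Atom(1, "C", np.array([+1.0, 0.0, 0.0]), 0.0, 1.7),
        ])
        sp = build_surfaces(mol, 0.8, 0.25)
        counts = np.bincount(sp.ses.nearest_atom_T, minlength=2)
        assert abs(counts[0] - counts[1]) / counts.sum() < 0.02

    def test_tie_breaks_to_lowest_index(self):
        # both atoms equidistant from every vertex of a mid-plane mesh
        mesh = icosphere(np.zeros(3), 1.0, 2)
        mol = Molecule("tie", [
            Atom(0, "C", np.array([0.0, 0.0, 5.0]), 0.0, 1.0),
            Atom(1, "C", np.array([0.0, 0.0, -5.0]), 0.0, 1.0),
        ])
        mesh = assign_nearest_atoms(mesh, mol)
        first = mesh.vertices[mesh.triangles[:, 0]]
        equidistant = np.isclose(
            np.linalg.norm(first - mol.atoms[0].position, axis=1),
            np.linalg.norm(first - mol.atoms[1].position, axis=1),
        )
        assert np.all(mesh.nearest_atom_T[equidistant] == 0)


class TestSasa:
    def test_isolated_sphere_value(self):
        # NC carbon: rho 1.63 Å + probe 0.80 Å
        sp = build_surfaces(single_atom(radius=1.63), 0.80, 0.25)
        assert sasa(sp.sas) == pytest.approx(sphere_area(2.43), rel=0.01)

    def test_requires_sas_kind(self):
        sp = build_surfaces(single_atom(), 0.8, 0.5)
        with pytest.raises(MeshError, match="SAS"):
            sasa(sp.ses)

    def test_fused_dimer_smaller_than_sum(self):
        mol = Molecule("fused", [
            Atom(0, "C", np.zeros(3), 0.0, 1.7),
            Atom(1, "C", np.array([1.5, 0.0, 0.0]), 0.0, 1.7),
        ])
        sp = build_surfaces(mol, 0.8, 0.25)
        isolated = 2 * sphere_area(2.5)
        assert sasa(sp.sas) < isolated
        # numeric point-sampling oracle for the buried fraction
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= 2.5
        exposed0 = np.linalg.norm(pts - [1.5, 0, 0], axis=1) > 2.5
        exposed1 = np.linalg.norm(pts + [1.5, 0, 0], axis=1) > 2.5
        oracle = sphere_area(2.5) * (exposed0.mean() + exposed1.mean())
        assert sasa(sp.sas) == pytest.approx(oracle, rel=0.02)


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_export_import_roundtrip(self, tmp_path, ext):
        mol = single_atom(radius=2.0)
        sp = build_surfaces(mol, 0.8, 0.4)
        path = tmp_path / f"ses.{ext}"
        export_mesh(sp.ses, path)
        back = import_mesh(path, mol, kind="SES")
        assert back.n_triangles == sp.ses.n_triangles
        assert back.total_area() == pytest.approx(sp.ses.total_area(), rel=1e-6)

    def test_inward_normals_fixed_on_import(self, tmp_path):
        mesh = icosphere(np.zeros(3), 2.0, 3)
        flipped = type(mesh)(
            vertices=mesh.vertices, triangles=mesh.triangles[:, ::-1], kind="SES"
        )
        path = tmp_path / "flipped.off"
        export_mesh(flipped, path)
        back = import_mesh(path, single_atom(radius=2.0), kind="SES")
        assert back.signed_volume() > 0

    def test_open_mesh_rejected(self, tmp_path):
        mesh = icosphere(np.zeros(3), 2.0, 2)
        holey = type(mesh)(
            vertices=mesh.vertices, triangles=mesh.triangles[:-5], kind="SES"
        )
        path = tmp_path / "open.off"
        export_mesh(holey, path)
        with pytest.raises(MeshError, match="open mesh"):
            import_mesh(path, single_atom(radius=2.0), kind="SES")
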