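"""Triangulated dielectric-boundary (SES) and solvent-accessible (SAS) surfaces.

The SES is extracted as the zero level of a probe-rolled signed field on a
Cartesian grid: the exact distance field of the probe-inflated atom spheres
defines the probe-center region, and an EDT with sub-voxel refinement erodes
it back by the probe radius; marching cubes triangulates the result. The SAS
is the union-of-spheres surface at atom radius + probe radius. An analytic
icosphere mesher is provided for sphere fixtures.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from scipy.sparse.csgraph import connected_components
from skimage.measure import marching_cubes

from .constants import GRID_SPACING_DEFAULT
from .model_io import Molecule

log = logging.getLogger(__name__)


class MeshError(ValueError):
    pass


@dataclass
class TriMesh:
    """A closed, outward-oriented triangle mesh with per-triangle geometry."""

    vertices: np.ndarray          # (nv, 3) Å
    triangles: np.ndarray         # (nt, 3) int vertex indices
    kind: str                     # "SES" | "SAS"
    area_T: np.ndarray = field(init=False)
    normal_T: np.ndarray = field(init=False)
    centroid_T: np.ndarray = field(init=False)
    nearest_atom_T: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("SES", "SAS"):
            raise MeshError(f"kind must be SES or SAS, got {self.kind!r}")
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("mesh vertices must be finite")
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        area2 = np.linalg.norm(cross, axis=1)
        keep = area2 > 1e-14
        dropped = int((~keep).sum())
        if dropped:
            log.warning("dropping %d zero-area triangles", dropped)
            t = t[keep]
            cross = cross[keep]
            area2 = area2[keep]
            self.triangles = t
        self.area_T = 0.5 * area2
        self.normal_T = cross / area2[:, None]
        self.centroid_T = v[t].mean(axis=1)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def signed_volume(self) -> float:
        v = self.vertices
        t = self.triangles
        return float(np.einsum("ij,ij->", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]]))) / 6.0

    def total_area(self) -> float:
        return float(self.area_T.sum())


@dataclass
class SurfacePair:
    ses: TriMesh
    sas: TriMesh
    grid_spacing: float

    def __post_init__(self) -> None:
        if not self.grid_spacing > 0:
            raise MeshError("grid_spacing must be > 0")


# ---------------------------------------------------------------------------
# analytic sphere fixture
# ---------------------------------------------------------------------------

def icosphere(center, radius: float, subdivisions: int = 4, kind: str = "SES") -> TriMesh:
    """Icosphere with vertices exactly on the sphere (fixture-grade surface)."""
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = base.vertices / np.linalg.norm(base.vertices, axis=1)[:, None]
    verts = verts * radius + np.asarray(center, dtype=float)
    mesh = TriMesh(vertices=verts, triangles=np.array(base.faces), kind=kind)
    mesh.nearest_atom_T = np.zeros(mesh.n_triangles, dtype=np.int64)
    return mesh


# ---------------------------------------------------------------------------
# grid-based SES / SAS construction
# ---------------------------------------------------------------------------

def _clusters(mol: Molecule, probe_radius: float) -> list[np.ndarray]:
    """Groups of atoms whose SAS spheres can touch; meshed independently."""
    pos = mol.positions
    rad = mol.radii
    n = len(pos)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    touch = d < (rad[:, None] + rad[None, :] + 2.0 * probe_radius)
    ncomp, labels = connected_components(csr_matrix(touch), directed=False)
    return [np.flatnonzero(labels == c) for c in range(ncomp)]


def _sample_grid(pos, rad_inflated, spacing, pad):
    lo = pos.min(axis=0) - rad_inflated.max() - pad
    hi = pos.max(axis=0) + rad_inflated.max() + pad
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grid], axis=1)
    # exact distance to the union of inflated spheres (exact outside the union)
    d = np.full(len(pts), np.inf)
    for p, r in zip(pos, rad_inflated):
        np.minimum(d, np.linalg.norm(pts - p, axis=1) - r, out=d)
    return lo, axes, d.reshape(grid[0].shape)


def _extract(volume, level, lo, spacing, kind) -> tuple[np.ndarray, np.ndarray]:
    verts, faces, _, _ = marching_cubes(volume, level=level, spacing=(spacing,) * 3)
    return verts + lo, faces


def _orient_outward(verts, faces) -> tuple[np.ndarray, np.ndarray]:
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True, validate=False)
    trimesh.repair.fix_normals(tm, multibody=True)
    if tm.volume < 0:
        tm.invert()
    return np.array(tm.vertices), np.array(tm.faces)


def _closest_tri_dist(p, a, b, c):
    """Distance from point p[i] to triangle (a,b,c)[i], vectorized."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0.0, 1.0)
        t_ac = np.clip(d2 / (d2 - d6), 0.0, 1.0)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    closest = a + ab * np.nan_to_num(v)[:, None] + ac * np.nan_to_num(w)[:, None]
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest[on_bc] = b[on_bc] + (c - b)[on_bc] * np.nan_to_num(t_bc)[on_bc, None]
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest[on_ac] = a[on_ac] + ac[on_ac] * np.nan_to_num(t_ac)[on_ac, None]
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest[on_ab] = a[on_ab] + ab[on_ab] * np.nan_to_num(t_ab)[on_ab, None]
    at_c = (d6 >= 0) & (d5 <= d6)
    closest[at_c] = c[at_c]
    at_b = (d3 >= 0) & (d4 <= d3)
    closest[at_b] = b[at_b]
    at_a = (d1 <= 0) & (d2 <= 0)
    closest[at_a] = a[at_a]
    return np.linalg.norm(p - closest, axis=1)


def _dist_to_surface(points, verts, faces, k: int = 6):
    """Exact distance from each point to the triangle mesh (KD-tree prefilter)."""
    tree = cKDTree(verts)
    _, near_v = tree.query(points, k=k)
    # vertex -> incident faces (CSR layout)
    nv = len(verts)
    counts = np.zeros(nv, dtype=np.int64)
    np.add.at(counts, faces.ravel(), 1)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    fill = offsets[:-1].copy()
    vert_faces = np.empty(offsets[-1], dtype=np.int64)
    for fi, tri in enumerate(faces):
        for v in tri:
            vert_faces[fill[v]] = fi
            fill[v] += 1

    best = np.full(len(points), np.inf)
    # gather (point, candidate-face) pairs and take the min per point
    pair_p, pair_f = [], []
    for col in range(near_v.shape[1]):
        vs = near_v[:, col]
        for pi, v in enumerate(vs):
            fs = vert_faces[offsets[v]:offsets[v + 1]]
            pair_p.append(np.full(len(fs), pi))
            pair_f.append(fs)
    pair_p = np.concatenate(pair_p)
    pair_f = np.concatenate(pair_f)
    tri = verts[faces[pair_f]]
    d = _closest_tri_dist(points[pair_p], tri[:, 0], tri[:, 1], tri[:, 2])
    np.minimum.at(best, pair_p, d)
    return best


def _mesh_cluster(pos, rad, probe_radius, spacing):
    pad = 2.0 * probe_radius + 3.0 * spacing
    # SAS: zero level of the exact inflated-sphere distance field
    lo, axes, d1 = _sample_grid(pos, rad + probe_radius, spacing, pad)
    sas_v, sas_f = _extract(-d1, 0.0, lo, spacing, "SAS")

    # SES: a point is solvent-excluded iff it lies >= probe_radius from every
    # allowed probe center, i.e. its distance to the SAS surface (measured
    # from inside the inflated union) exceeds probe_radius. The SAS level set
    # above is sub-voxel accurate, so point-to-mesh distances give a smooth
    # erosion field.
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grid], axis=1)
    d1f = d1.ravel()
    inside = d1f < 0
    psi = np.where(inside, 0.0, -probe_radius - d1f)

    tree = cKDTree(sas_v)
    approx, _ = tree.query(pts[inside])
    dist_in = approx.copy()
    # exact point-to-triangle distance in a band around the SES level
    band = np.abs(approx - probe_radius) < 2.0 * spacing
    if band.any():
        dist_in[band] = _dist_to_surface(pts[inside][band], sas_v, sas_f)
    psi[inside] = dist_in - probe_radius
    ses_v, ses_f = _extract(psi.reshape(d1.shape), 0.0, lo, spacing, "SES")
    return (ses_v, ses_f), (sas_v, sas_f)


def build_surfaces(
    mol: Molecule,
    probe_radius: float,
    grid_spacing: float = GRID_SPACING_DEFAULT,
) -> SurfacePair:
    """Build the SES (dielectric boundary) and SAS meshes of a molecule.

    Disjoint atom clusters are meshed on independent local grids, so widely
    separated fragments cost no extra memory. Both meshes are closed,
    outward-oriented and carry the nearest-atom map.
    """
    if not probe_radius > 0:
        raise MeshError("probe_radius must be > 0")
    if not (0 < grid_spacing <= 1.0):
        raise MeshError("grid_spacing must be in (0, 1] Å")
    pos = mol.positions
    if len(pos) > 1:
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise MeshError("degenerate geometry: two coincident atom centers")

    ses_parts, sas_parts = [], []
    for cluster in _clusters(mol, probe_radius):
        ses, sas = _mesh_cluster(pos[cluster], mol.radii[cluster], probe_radius, grid_spacing)
        ses_parts.append(ses)
        sas_parts.append(sas)

    def combine(parts, kind):
        verts, faces, off = [], [], 0
        for v, f in parts:
            v, f = _orient_outward(v, f)
            verts.append(v)
            faces.append(f + off)
            off += len(v)
        mesh = TriMesh(np.vstack(verts), np.vstack(faces), kind=kind)
        if mesh.signed_volume() <= 0:
            raise MeshError(f"{kind} mesh is not closed/outward (signed volume <= 0)")
        return assign_nearest_atoms(mesh, mol)

    return SurfacePair(
        ses=combine(ses_parts, "SES"),
        sas=combine(sas_parts, "SAS"),
        grid_spacing=grid_spacing,
    )


# ---------------------------------------------------------------------------
# nearest-atom map, SASA, mesh IO
# ---------------------------------------------------------------------------

def assign_nearest_atoms(mesh: TriMesh, mol: Molecule) -> TriMesh:
    """Map each triangle to the atom nearest its *first* vertex.

    Exact distance ties break to the lowest atom index (argmin order), which
    keeps the assignment deterministic for a fixed input ordering.
    """
    first_vertex = mesh.vertices[mesh.triangles[:, 0]]
    d = np.linalg.norm(first_vertex[:, None, :] - mol.positions[None, :, :], axis=2)
    mesh.nearest_atom_T = np.argmin(d, axis=1).astype(np.int64)
    return mesh


def sasa(mesh: TriMesh) -> float:
    """Total solvent-accessible surface area (sum of SAS triangle areas)."""
    if mesh.kind != "SAS":
        raise MeshError(f"sasa requires a SAS mesh, got kind={mesh.kind!r}")
    return mesh.total_area()


def export_mesh(mesh: TriMesh, path: str | Path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(str(path))


def import_mesh(path: str | Path, mol: Molecule, kind: str) -> TriMesh:
    """Import an OFF/PLY triangle mesh, fix orientation, map nearest atoms."""
    tm = trimesh.load(str(path), force="mesh", process=True)
    if tm.faces.shape[1] != 3:
        raise MeshError(f"{path}: non-triangular faces are not supported")
    if not tm.is_watertight:
        raise MeshError(
            f"{path}: open mesh (watertightness test failed); "
            f"{len(tm.faces)} faces, euler number {tm.euler_number}"
        )
    trimesh.repair.fix_normals(tm, multibody=True)
    if tm.volume < 0:
        tm.invert()
    mesh = TriMesh(np.array(tm.vertices), np.array(tm.faces), kind=kind)
    if mesh.signed_volume() <= 0:
        raise MeshError(f"{path}: signed volume <= 0 after orientation fix")
    return assign_nearest_atoms(mesh, mol)
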