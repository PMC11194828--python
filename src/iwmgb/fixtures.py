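"""Synthetic molecules, analytic meshes and brute-force reference oracles.

Everything here exists so that the full pipeline is testable offline:
Born ions with exact icosphere surfaces probe the analytic limits, the toy
polyatomic generator stands in for a small-molecule training set, and
``oracle_energy`` recomputes every surface sum with naive double loops —
no caching, no vectorized shortcuts — as an independent cross-check of the
assembler. Synthetic optimization references are generated from the oracle
(not the pipeline) to avoid shared-bug blindness.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from .assembler import EnergyBreakdown
from .constants import ALPB_ALPHA, COULOMB_KCAL, R6_UNIFORM_CORRECTION_B
from .model_io import (
    Atom,
    Molecule,
    MultipoleParams,
    NonpolarParams,
    ParameterSet,
    dispersion_prefactor,
)
from .surfaces import SurfacePair, TriMesh, icosphere

_FIXTURE_RADII = {"H": 1.20, "O": 1.50, "N": 1.55, "C": 1.70}


def make_born_ion(
    q: float,
    radius: float,
    probe_radius: float = 0.8,
    subdivisions: int = 4,
) -> tuple[Molecule, SurfacePair]:
    """A single ion at the origin with exact icosphere SES/SAS meshes."""
    if not radius > 0:
        raise ValueError("radius must be > 0")
    mol = Molecule(
        "born_ion",
        [Atom(index=0, element="O", position=np.zeros(3), charge=q, radius=radius)],
    )
    ses = icosphere(np.zeros(3), radius, subdivisions, kind="SES")
    sas = icosphere(np.zeros(3), radius + probe_radius, subdivisions, kind="SAS")
    # analytic meshes carry no grid; record the edge scale instead
    edge = float(np.median(np.sqrt(ses.area_T)))
    return mol, SurfacePair(ses=ses, sas=sas, grid_spacing=edge)


def born_ion_parameter_set(
    radius: float,
    probe_radius: float = 0.8,
    multipole: MultipoleParams | None = None,
    gamma0: float = 0.0,
    xi: float = 0.0,
    coupling: str = "none",
) -> ParameterSet:
    """Minimal parameter set matching a Born-ion fixture (element O)."""
    return ParameterSet(
        radii_by_element={"O": radius},
        probe_radius=probe_radius,
        multipole=multipole or MultipoleParams(),
        nonpolar=NonpolarParams(
            gamma0=gamma0,
            xi_by_element={"*": xi},
            probe_radius=probe_radius,
            coupling=coupling,
        ),
        label="custom",
    )


def make_toy_set(n: int, seed: int) -> list[Molecule]:
    """Deterministic random small polyatomics (2–12 atoms of H/O/N/C).

    Atoms are attached one by one at bonded distances (1.0–1.5 Å) from a
    random existing atom, rejecting placements closer than 0.9 Å to any
    other atom. Partial charges are drawn uniformly and recentered so every
    molecule is net neutral, mirroring a neutral small-molecule set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    elements = np.array(["H", "O", "N", "C"])
    weights = np.array([0.35, 0.15, 0.15, 0.35])
    mols = []
    for m in range(n):
        n_atoms = int(rng.integers(2, 13))
        pos = [np.zeros(3)]
        while len(pos) < n_atoms:
            anchor = pos[int(rng.integers(len(pos)))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = anchor + direction * rng.uniform(1.0, 1.5)
            if all(np.linalg.norm(cand - p) >= 0.9 for p in pos):
                pos.append(cand)
        els = rng.choice(elements, size=n_atoms, p=weights)
        q = rng.uniform(-0.6, 0.6, size=n_atoms)
        q -= q.mean()  # exact neutrality
        atoms = [
            Atom(index=i, element=els[i], position=pos[i], charge=float(q[i]),
                 radius=_FIXTURE_RADII[els[i]])
            for i in range(n_atoms)
        ]
        mols.append(Molecule(f"toy_{m:03d}", atoms))
    return mols


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_esize(pos, rad):
    """Electrostatic size by direct numerical capacitance integration."""
    vol = [r**3 for r in rad]
    wsum = sum(vol)
    center = sum(v * p for v, p in zip(vol, pos)) / wsum
    cov = np.zeros((3, 3))
    trace_r = 0.0
    for v, p, r in zip(vol, pos, rad):
        d = p - center
        cov += (v / wsum) * np.outer(d, d)
        trace_r += (v / wsum) * r**2 / 5.0
    cov += np.eye(3) * trace_r
    a2 = np.clip(5.0 * np.linalg.eigvalsh(cov), 1e-12, None)

    def integrand(t):
        return 1.0 / math.sqrt((t + a2[0]) * (t + a2[1]) * (t + a2[2]))

    val, _ = quad(integrand, 0.0, np.inf, limit=200)
    return 2.0 / val


def _oracle_vertex_normals(mesh: TriMesh):
    vnorm = np.zeros_like(mesh.vertices)
    for tidx, tri in enumerate(mesh.triangles):
        for v in tri:
            vnorm[v] += mesh.normal_T[tidx] * mesh.area_T[tidx]
    for i in range(len(vnorm)):
        nn = np.linalg.norm(vnorm[i])
        if nn > 0:
            vnorm[i] /= nn
    return vnorm


def _oracle_scd(mol, mesh, eps_in, eps_out, esize):
    beta = eps_in / eps_out
    ab = ALPB_ALPHA * beta
    pref = -(1.0 / (4.0 * math.pi)) * (1.0 / eps_in) * (1.0 - beta) / (1.0 + ab)
    vnorm = _oracle_vertex_normals(mesh)
    sigma_v = np.zeros(len(mesh.vertices))
    for vi in range(len(mesh.vertices)):
        s = 0.0
        for atom in mol.atoms:
            t = mesh.vertices[vi] - atom.position
            r = math.sqrt(t @ t)
            s += atom.charge * (float(vnorm[vi] @ t) / r**3 + ab / (esize * r))
        sigma_v[vi] = pref * s
    sigma_T = np.array([sigma_v[tri].mean() for tri in mesh.triangles])
    return sigma_T


def _oracle_born(mol, ses, B):
    R = np.zeros(len(mol))
    for i, atom in enumerate(mol.atoms):
        acc = 0.0
        for tidx in range(ses.n_triangles):
            t = ses.centroid_T[tidx] - atom.position
            r = math.sqrt(t @ t)
            acc += ses.area_T[tidx] * float(ses.normal_T[tidx] @ t) / r**6
        inv3 = max(acc / (4.0 * math.pi), 1e-12)
        inv = max(inv3 ** (1.0 / 3.0) - B, 1.0 / (10.0 * mol.radii.max()))
        R[i] = 1.0 / inv
    return R


def oracle_energy(
    mol: Molecule,
    params: ParameterSet,
    meshes: SurfacePair,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
    born_B: float = R6_UNIFORM_CORRECTION_B,
) -> EnergyBreakdown:
    """Reference energy breakdown by direct, unvectorized summation.

    Shares only the mesh geometry with the pipeline; every derived quantity
    (electrostatic size, SCD, Born radii, all surface sums) is recomputed
    with plain Python double loops.
    """
    if len(mol) > 12:
        raise ValueError("oracle is intended for small fixtures (<= 12 atoms)")
    radii = np.array([params.radii_by_element[a.element] for a in mol.atoms])
    atoms = [
        Atom(a.index, a.element, a.position.copy(), a.charge, radii[i],
             disp_a=dispersion_prefactor(a.element, params.element_lj, params.water_lj),
             disp_xi=params.nonpolar.xi_for(a.element))
        for i, a in enumerate(mol.atoms)
    ]
    pmol = Molecule(mol.name, atoms)
    ses, sas = meshes.ses, meshes.sas
    esize = _oracle_esize(list(pmol.positions), list(radii))
    beta = eps_in / eps_out
    ab = ALPB_ALPHA * beta

    # dipole-level ALPB, explicit double loop
    R = _oracle_born(pmol, ses, born_B)
    e_dip = 0.0
    for i, ai in enumerate(pmol.atoms):
        for j, aj in enumerate(pmol.atoms):
            rij2 = float(np.sum((ai.position - aj.position) ** 2))
            f = math.sqrt(rij2 + R[i] * R[j] * math.exp(-rij2 / (4.0 * R[i] * R[j])))
            e_dip += ai.charge * aj.charge * (1.0 / f + ab / esize)
    e_dip *= -0.5 * COULOMB_KCAL / eps_in * (1.0 - beta) / (1.0 + ab)
    if not any(a.charge for a in pmol.atoms):
        e_dip = 0.0

    # multipole corrections, triple loop
    sigma_ses = _oracle_scd(pmol, ses, eps_in, eps_out, esize)
    e_cha = e_quad = e_oct = 0.0
    for i, atom in enumerate(pmol.atoms):
        for tidx in range(ses.n_triangles):
            d = math.sqrt(float(np.sum((atom.position - ses.centroid_T[tidx]) ** 2)))
            A_T = ses.area_T[tidx]
            s_T = sigma_ses[tidx]
            e_cha += atom.charge * abs(s_T) * A_T / d**4
            e_quad += atom.charge * s_T * A_T / d**3
            e_oct += atom.charge * s_T * A_T / d**4
    F = params.multipole
    e_cha *= COULOMB_KCAL * F.F0
    e_quad *= COULOMB_KCAL * F.F1
    e_oct *= COULOMB_KCAL * F.F2

    # nonpolar: cavity over SAS triangles, dispersion over atoms
    p = params.nonpolar
    if p.coupling == "quartic":
        sigma_sas = _oracle_scd(pmol, sas, eps_in, eps_out, esize)
    else:
        sigma_sas = np.zeros(sas.n_triangles)
    cavity = 0.0
    for tidx in range(sas.n_triangles):
        s = sigma_sas[tidx]
        if p.coupling == "quartic":
            gam = p.gamma0 * (1.0 + p.g1 * s**2 + p.g2 * s**4)
        else:
            gam = p.gamma0
        cavity += gam * sas.area_T[tidx]

    # per-atom SES sigma averages for the D coupling
    owner = ses.nearest_atom_T
    vdw = 0.0
    for i, atom in enumerate(pmol.atoms):
        if p.coupling == "quartic":
            mine = [sigma_ses[t] for t in range(ses.n_triangles) if owner[t] == i]
            s_i = sum(mine) / len(mine) if mine else 0.0
            D = abs(p.probe_radius * (1.0 + p.c1 * s_i**2 + p.c2 * s_i**4))
        else:
            D = p.probe_radius
        vdw -= atom.disp_xi * atom.disp_a / (R[i] + D) ** 3
    return EnergyBreakdown(
        el_dipole=e_dip, el_cha=e_cha, el_quadrupole=e_quad,
        el_linear_octupole=e_oct, cavity=cavity, vdw=vdw,
    )
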