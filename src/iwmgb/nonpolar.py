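"""Cavity + van der Waals nonpolar solvation energy, optionally field-coupled.

The cavity cost is a surface-tension sum over the SAS triangles and the
dispersion gain an atomwise sum over effective Born radii:

    dG_np = sum_{T'} gamma(s_{T'}) A_{T'}  -  sum_i xi_i a_i / (R_i + |D_i|)^3

In the NC (no-coupling) variant gamma = gamma0 and D_i = rho_w are
constants. In the WC (with-coupling) variant both become even quartic
functions of the local "surface charge density" — the formal Eq-7 SCD on
the SAS for gamma, and the per-atom SES average s_i for D_i — so the
polar/nonpolar coupling vanishes quadratically as the charges go to zero.
The absolute value on D_i keeps the effective SAS position outside the
dielectric boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .electrostatics import ScdField
from .gb_core import BornRadii
from .model_io import Molecule, NonpolarParams
from .surfaces import TriMesh

log = logging.getLogger(__name__)


@dataclass
class NonpolarBreakdown:
    cavity: float   # kcal/mol, > 0 for gamma0 > 0
    vdw: float      # kcal/mol, always <= 0

    @property
    def total(self) -> float:
        return self.cavity + self.vdw


def gamma_of_sigma(sigma, p: NonpolarParams):
    """Surface tension gamma(sigma), kcal/mol/Å². Even; gamma(0) = gamma0."""
    sigma = np.asarray(sigma, dtype=float)
    if p.coupling == "none":
        return np.full_like(sigma, p.gamma0)
    s2 = sigma**2
    return p.gamma0 * (1.0 + p.g1 * s2 + p.g2 * s2**2)


def D_of_sigma(sigma_i, p: NonpolarParams):
    """DB-to-SAS offset D(sigma_i), Å. Even, non-negative; D(0) = rho_w."""
    sigma_i = np.asarray(sigma_i, dtype=float)
    if p.coupling == "none":
        return np.full_like(sigma_i, p.probe_radius)
    s2 = sigma_i**2
    return np.abs(p.probe_radius * (1.0 + p.c1 * s2 + p.c2 * s2**2))


def nonpolar_energy(
    mol: Molecule,
    sas: TriMesh,
    radii: BornRadii,
    p: NonpolarParams,
    sas_field: ScdField | None = None,
    atom_field: ScdField | None = None,
) -> NonpolarBreakdown:
    """Cavity and dispersion parts of the nonpolar energy, kcal/mol.

    The WC variant requires the formal SCD on the SAS (for gamma) and the
    per-atom SES averages (for D_i); buried atoms with undefined sigma_i
    fall back to the zero-field coupling (sigma_i = 0) with a logged count.
    """
    if sas.kind != "SAS":
        raise ValueError("nonpolar cavity term requires the SAS mesh")
    if p.coupling == "quartic":
        if sas_field is None or atom_field is None:
            raise ValueError(
                "coupling='quartic' needs the SAS SCD field and the per-atom "
                "SES SCD averages"
            )
        gam = gamma_of_sigma(sas_field.sigma_T, p)
        sigma_i = np.asarray(atom_field.sigma_atom, dtype=float)
        buried = ~np.isfinite(sigma_i)
        if buried.any():
            log.info("%d buried atoms use zero-field coupling", int(buried.sum()))
            sigma_i = np.where(buried, 0.0, sigma_i)
    else:
        gam = np.full(sas.n_triangles, p.gamma0)
        sigma_i = np.zeros(len(mol))
    cavity = float(gam @ sas.area_T)

    a = np.array([np.nan if at.disp_a is None else at.disp_a for at in mol.atoms], dtype=float)
    if np.any(~np.isfinite(a)):
        raise ValueError("dispersion prefactors a_i unset; apply a ParameterSet first")
    xi = np.array([p.xi_for(at.element) for at in mol.atoms])
    D = D_of_sigma(sigma_i, p)
    vdw = -float(np.sum(xi * a / (radii.R + D) ** 3))
    return NonpolarBreakdown(cavity=cavity, vdw=vdw)
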