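"""Effective Born radii (R6 surface integral) and the ALPB dipole energy.

The "R6" effective Born radius of atom i derives from a surface integral
over the dielectric boundary,

    R_i^{-3} = (1/4pi) ∮ n.(r - r_i) / |r - r_i|^6 dA,

exact for a sphere centered on the atom. A uniform correction B is applied
to the inverse radius (1/R = 1/R_raw - B), which enlarges effective radii to
compensate the systematic R6 underestimation for buried atoms.

The dipole-level electrostatic solvation energy uses the ALPB form, which
carries the correct dependence on both dielectric constants through
alpha = 0.580127 and the electrostatic size A:

    dG_el^dipole = -(ke/2) (1/eps_in) (1 - beta e^{-kappa f_ij})/(1 + alpha beta)
                   * sum_ij q_i q_j [ 1/f_ij + alpha beta / A ]

with f_ij = sqrt(r_ij^2 + R_i R_j exp(-r_ij^2 / (4 R_i R_j))). At kappa = 0
this collapses, for a centered charge in a sphere with R = A, to the Born
formula -(ke q^2 / 2R)(1/eps_in - 1/eps_out).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    COULOMB_KCAL,
    KAPPA_SQRT_PREFACTOR,
    R6_UNIFORM_CORRECTION_B,
)
from .electrostatics import DielectricModel
from .model_io import Molecule
from .surfaces import TriMesh


@dataclass
class BornRadii:
    inv_raw: np.ndarray        # Å⁻¹, before the uniform correction
    inv_corrected: np.ndarray  # Å⁻¹, after it (clamped positive)
    R: np.ndarray              # Å, effective radii 1/inv_corrected
    B: float                   # Å⁻¹, the uniform correction applied


def r6_born_radii(
    mol: Molecule,
    ses: TriMesh,
    B: float = R6_UNIFORM_CORRECTION_B,
) -> BornRadii:
    """Per-atom R6 effective Born radii from the SES triangle quadrature.

    The corrected inverse radius is clamped from below at 1/(10 max rho) so
    deeply buried atoms keep a finite, positive effective radius.
    """
    pos = mol.positions
    t = ses.centroid_T[:, None, :] - pos[None, :, :]   # (nt, na, 3)
    r = np.linalg.norm(t, axis=2)
    if r.min() < 1e-6:
        raise ValueError("SES triangle centroid coincides with an atom center")
    integrand = np.einsum("tj,taj->ta", ses.normal_T, t) / r**6
    inv3 = (ses.area_T @ integrand) / (4.0 * np.pi)
    inv3 = np.clip(inv3, 1e-12, None)  # guard against quadrature noise
    inv_raw = inv3 ** (1.0 / 3.0)
    floor = 1.0 / (10.0 * mol.radii.max())
    inv_corr = np.clip(inv_raw - B, floor, None)
    return BornRadii(inv_raw=inv_raw, inv_corrected=inv_corr, R=1.0 / inv_corr, B=B)


def gb_pair_function(rij: np.ndarray, Ri: np.ndarray, Rj: np.ndarray) -> np.ndarray:
    """Smooth GB pair distance f_ij (Still's interpolation)."""
    prod = Ri * Rj
    return np.sqrt(rij**2 + prod * np.exp(-(rij**2) / (4.0 * prod)))


def alpb_dipole_energy(
    mol: Molecule,
    radii: BornRadii,
    diel: DielectricModel,
) -> float:
    """Dipole-level electrostatic solvation energy, kcal/mol (<= 0)."""
    if diel.kappa < 0:
        raise ValueError("kappa must be >= 0")
    q = mol.charges
    if not np.any(q):
        return 0.0
    pos = mol.positions
    rij = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    f = gb_pair_function(rij, radii.R[:, None], radii.R[None, :])
    ab = diel.alpha * diel.beta
    screen = diel.beta * np.exp(-diel.kappa * f)
    kernel = (1.0 - screen) / (1.0 + ab) * (1.0 / f + ab / diel.esize)
    e = -0.5 * COULOMB_KCAL / diel.eps_in * (q[:, None] * q[None, :] * kernel).sum()
    return float(e)


def kappa_from_ionic_strength(molarity: float, ) -> float:
    """Inverse Debye length (Å⁻¹) from ionic strength (mol/L) in water, 298 K."""
    if molarity < 0:
        raise ValueError("ionic strength must be >= 0")
    return KAPPA_SQRT_PREFACTOR * float(np.sqrt(molarity))
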