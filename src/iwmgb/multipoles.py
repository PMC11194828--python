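"""Beyond-dipole water-multipole corrections to the electrostatic energy.

Orientational polarization of water quadrupoles and octupoles in the first
hydration shell adds reaction-field components on top of the dipole-level
GB description. With the first shell collapsed onto the dielectric boundary
the corrections become surface sums over the SES triangles:

    dG_corr = ke * sum_i q_i sum_T A_T [ F0 |s_T| / d^4      (cubic octupole, CHA)
                                       + F1  s_T  / d^3      (quadrupole)
                                       + F2  s_T  / d^4 ]    (linear octupole)

where s_T is the triangle SCD, d = |r_i - r_T| the atom-centroid distance,
and F0 (Å³), F1 (Å²), F2 (Å³) absorb the water multipole moments and their
scaling coefficients. The kernels follow the multipole decay orders
(quadrupole reaction field ~ 1/r³, octupole ~ 1/r⁴). The CHA term carries
|s_T|, making its potential independent of the sign of the dipole
polarization: under a global charge flip it is odd (the signature of charge
hydration asymmetry) while the F1/F2 terms are even.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KCAL
from .electrostatics import ScdField
from .model_io import Molecule, MultipoleParams
from .surfaces import TriMesh

log = logging.getLogger(__name__)

#: kernel table locking the reconstruction: (weight name, sigma power
#: treatment, inverse-distance exponent). "abs" marks the charge-asymmetric
#: term. Tests pin the parities; changing an entry breaks them loudly.
KERNEL_TABLE = (
    ("F0", "abs", 4),
    ("F1", "signed", 3),
    ("F2", "signed", 4),
)


@dataclass
class MultipoleBreakdown:
    cha: float                # F0 cubic-octupole (charge-asymmetric) term
    quadrupole: float         # F1 term
    linear_octupole: float    # F2 term

    @property
    def total(self) -> float:
        return self.cha + self.quadrupole + self.linear_octupole


def multipole_surface_sums(mol: Molecule, ses: TriMesh, field: ScdField) -> np.ndarray:
    """The three F-independent surface sums S_k (kcal/mol per unit F_k).

    Precomputing these makes the correction linear in (F0, F1, F2), which
    the parameter-optimization inner loop exploits.
    """
    if ses.kind != "SES":
        raise ValueError("multipole corrections are defined on the SES, not the SAS")
    if field.mesh_ref is not ses:
        raise ValueError("SCD field was not computed on the supplied SES mesh")
    d = np.linalg.norm(ses.centroid_T[:, None, :] - mol.positions[None, :, :], axis=2)
    if d.min() < 1e-6:
        raise ValueError("atom center coincides with a triangle centroid")
    q = mol.charges
    a_sig = field.sigma_T * ses.area_T
    a_abs = np.abs(field.sigma_T) * ses.area_T
    sums = []
    for _, sig_kind, p in KERNEL_TABLE:
        w = a_abs if sig_kind == "abs" else a_sig
        sums.append(COULOMB_KCAL * float(w @ (1.0 / d**p) @ q))
    return np.array(sums)


def multipole_correction(
    mol: Molecule,
    ses: TriMesh,
    field: ScdField,
    F: MultipoleParams,
) -> MultipoleBreakdown:
    """Per-term multipole correction energies, kcal/mol."""
    s0, s1, s2 = multipole_surface_sums(mol, ses, field)
    return MultipoleBreakdown(cha=F.F0 * s0, quadrupole=F.F1 * s1, linear_octupole=F.F2 * s2)


def multipole_fraction_report(
    breakdowns: list[MultipoleBreakdown],
    dipole_energies: list[float],
    names: list[str] | None = None,
) -> dict:
    """Per-molecule and set-average ratios of each term to the dipole energy.

    Molecules with zero dipole energy are excluded with a warning. The
    set-level report carries the arithmetic mean of each ratio and the
    maximum |total| fraction.
    """
    if len(breakdowns) != len(dipole_energies):
        raise ValueError("breakdowns and dipole energies must align")
    names = names or [str(i) for i in range(len(breakdowns))]
    rows = []
    for name, b, e_dip in zip(names, breakdowns, dipole_energies):
        if e_dip == 0.0:
            log.warning("molecule %s excluded from fraction report: zero dipole energy", name)
            continue
        row = {
            "name": name,
            "cha": b.cha / e_dip,
            "quadrupole": b.quadrupole / e_dip,
            "linear_octupole": b.linear_octupole / e_dip,
        }
        row["total"] = row["cha"] + row["quadrupole"] + row["linear_octupole"]
        rows.append(row)
    if not rows:
        return {"per_molecule": [], "average": {}, "max_abs_total": float("nan")}
    avg = {
        k: float(np.mean([r[k] for r in rows]))
        for k in ("cha", "quadrupole", "linear_octupole", "total")
    }
    return {
        "per_molecule": rows,
        "average": avg,
        "max_abs_total": float(max(abs(r["total"]) for r in rows)),
    }
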