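"""Physical constants and model-wide defaults.

Units follow the AMBER convention throughout the package: lengths in Å,
charges in elementary charges e, energies in kcal/mol.
"""

#: Coulomb constant, kcal·Å/(mol·e²) (AMBER convention).
COULOMB_KCAL = 332.0636

#: ALPB shape parameter (dimensionless, exact value from the ALPB theory).
ALPB_ALPHA = 0.580127

#: Default solute / solvent dielectric constants.
EPS_IN_DEFAULT = 1.0
EPS_OUT_DEFAULT = 80.0

#: Uniform correction to the inverse R6 Born radius, Å⁻¹. Applied as
#: 1/R = 1/R_raw - B, which enlarges effective radii to compensate the
#: systematic R6 underestimation for buried atoms. Kept as a single module
#: constant so the sign convention lives in exactly one place.
R6_UNIFORM_CORRECTION_B = 0.028

#: Default surface-construction grid spacing, Å.
GRID_SPACING_DEFAULT = 0.5

#: Water number density at 298 K, Å⁻³ (used to form dispersion prefactors).
WATER_NUMBER_DENSITY = 0.033428

#: TIP3P water-oxygen Lennard-Jones parameters (Rmin/2 in Å, epsilon in
#: kcal/mol), the reference partner for Lorentz–Berthelot combination when
#: per-atom dispersion prefactors a_i are derived from solute LJ entries.
TIP3P_OXYGEN_LJ = (1.7683, 0.1521)

#: Default solute LJ parameters per element, (Rmin/2 Å, epsilon kcal/mol).
#: GAFF-flavored generic values; users supplying force-field-specific LJ
#: pairs override these through the parameter file.
DEFAULT_ELEMENT_LJ = {
    "H": (1.4870, 0.0157),
    "C": (1.9080, 0.1094),
    "N": (1.8240, 0.1700),
    "O": (1.6612, 0.2100),
    "S": (2.0000, 0.2500),
}

#: Conversion for the Debye screening parameter: kappa [Å⁻¹] =
#: KAPPA_SQRT_PREFACTOR * sqrt(I [mol/L]) in water at 298 K.
KAPPA_SQRT_PREFACTOR = 0.3287
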