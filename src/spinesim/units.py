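"""Unit conventions and conversion helpers.

Geometry is in µm, time in s.  Concentrations are handled in µM inside the
solver (state vectors stay O(1)-O(100) so residual norms are meaningful);
membrane flux densities cross the API in mol s⁻¹ µm⁻², the unit the
physiological literature prints them in.

Conversions used throughout:

* 1 µM = 1e-21 mol/µm³  (1 M = 1e-15 mol/µm³)
* flux density: 1 mol s⁻¹ µm⁻² = 1e21 µM µm s⁻¹
"""

AVOGADRO = 6.02214076e23  # 1/mol

#: mol/µm³ per µM
MOL_PER_UM3_PER_UM = 1.0e-21

#: nM, mM expressed in µM
NM = 1.0e-3
MM = 1.0e3


def uM_to_mol_per_um3(c_uM: float) -> float:
    """Concentration µM -> mol/µm³."""
    return c_uM * MOL_PER_UM3_PER_UM


def mol_per_um3_to_uM(c):
    """Concentration mol/µm³ -> µM."""
    return c / MOL_PER_UM3_PER_UM


def flux_mol_to_uM_um(j):
    """Flux density mol s⁻¹ µm⁻² -> µM µm s⁻¹ (solver-internal)."""
    return j / MOL_PER_UM3_PER_UM


def ions(mol: float) -> float:
    """Amount of substance mol -> number of ions."""
    return mol * AVOGADRO
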