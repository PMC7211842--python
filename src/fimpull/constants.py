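"""Physical constants and unit conversions used throughout the package.

All mechanics is done in single-molecule units: force in pN, length in nm,
energy in pN·nm.  Energies are reported per mole of molecules in kcal/mol
where stated.
"""

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K, 1 pN·nm = 1e-21 J).
KB_PN_NM_PER_K: float = 1.380649e-2

#: kB·T at 300 K in pN·nm.
KBT_300K: float = KB_PN_NM_PER_K * 300.0  # = 4.141947

#: 1 kcal/mol expressed in pN·nm per molecule (4184 J/mol / N_A / 1e-21).
PN_NM_PER_KCAL_MOL: float = 6.9477

#: Default temperature (K) for experimental fits; the simulations run at 300 K.
DEFAULT_TEMPERATURE: float = 300.0


def kbt(temperature: float) -> float:
    """kB·T in pN·nm at the given temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_PN_NM_PER_K * temperature


def pn_nm_to_kcal_mol(energy_pn_nm: float) -> float:
    """Convert an energy from pN·nm (per molecule) to kcal/mol."""
    return energy_pn_nm / PN_NM_PER_KCAL_MOL


def kcal_mol_to_pn_nm(energy_kcal_mol: float) -> float:
    """Convert an energy from kcal/mol to pN·nm per molecule."""
    return energy_kcal_mol * PN_NM_PER_KCAL_MOL
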