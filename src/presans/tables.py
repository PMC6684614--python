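"""Neutron scattering-length and amino-acid composition tables.

Coherent bound scattering lengths are in femtometres (fm); residue volumes
in cubic aangstroems.  Residue compositions are for the residue *as part of
a polypeptide chain* (amino acid minus one water), with Asp/Glu carboxylates
deprotonated and Lys/Arg side chains protonated, i.e. the ionisation state
expected near neutral pH.  Hydrogens are split into non-exchangeable
(carbon-bound, set by the expression medium) and exchangeable (N-H, O-H,
S-H, set by the buffer D2O fraction).
"""

from __future__ import annotations

# Coherent neutron scattering lengths, fm (Sears compilation).
B_COHERENT: dict[str, float] = {
    "H": -3.739,
    "D": 6.671,
    "C": 6.646,
    "N": 9.360,
    "O": 5.803,
    "S": 2.847,
}

# Molecular volume of one water molecule, A^3 (bulk density).
WATER_VOLUME = 30.0

# Scattering length of one solvent molecule, fm.
B_H2O = 2.0 * B_COHERENT["H"] + B_COHERENT["O"]
B_D2O = 2.0 * B_COHERENT["D"] + B_COHERENT["O"]


def solvent_density(f_d2o: float) -> float:
    """Solvent scattering-length density in fm/A^3, linear in the D2O fraction."""
    if not 0.0 <= f_d2o <= 1.0:
        raise ValueError(f"D2O fraction must be in [0,1], got {f_d2o}")
    b = (1.0 - f_d2o) * B_H2O + f_d2o * B_D2O
    return b / WATER_VOLUME


# Per-residue heavy-atom counts, hydrogen counts (non-exchangeable /
# exchangeable) and volumes (A^3, Chothia-style consensus values).
# keys: C, N, O, S, H_nonexch, H_exch, volume
RESIDUES: dict[str, dict[str, float]] = {
    "GLY": {"C": 2, "N": 1, "O": 1, "S": 0, "H_nonexch": 2, "H_exch": 1, "volume": 60.1},
    "ALA": {"C": 3, "N": 1, "O": 1, "S": 0, "H_nonexch": 4, "H_exch": 1, "volume": 88.6},
    "VAL": {"C": 5, "N": 1, "O": 1, "S": 0, "H_nonexch": 8, "H_exch": 1, "volume": 140.0},
    "LEU": {"C": 6, "N": 1, "O": 1, "S": 0, "H_nonexch": 10, "H_exch": 1, "volume": 166.7},
    "ILE": {"C": 6, "N": 1, "O": 1, "S": 0, "H_nonexch": 10, "H_exch": 1, "volume": 166.7},
    "PRO": {"C": 5, "N": 1, "O": 1, "S": 0, "H_nonexch": 7, "H_exch": 0, "volume": 112.7},
    "PHE": {"C": 9, "N": 1, "O": 1, "S": 0, "H_nonexch": 8, "H_exch": 1, "volume": 189.9},
    "TRP": {"C": 11, "N": 2, "O": 1, "S": 0, "H_nonexch": 8, "H_exch": 2, "volume": 227.8},
    "MET": {"C": 5, "N": 1, "O": 1, "S": 1, "H_nonexch": 8, "H_exch": 1, "volume": 162.9},
    "SER": {"C": 3, "N": 1, "O": 2, "S": 0, "H_nonexch": 3, "H_exch": 2, "volume": 89.0},
    "THR": {"C": 4, "N": 1, "O": 2, "S": 0, "H_nonexch": 5, "H_exch": 2, "volume": 116.1},
    "CYS": {"C": 3, "N": 1, "O": 1, "S": 1, "H_nonexch": 3, "H_exch": 2, "volume": 108.5},
    "TYR": {"C": 9, "N": 1, "O": 2, "S": 0, "H_nonexch": 7, "H_exch": 2, "volume": 193.6},
    "ASN": {"C": 4, "N": 2, "O": 2, "S": 0, "H_nonexch": 3, "H_exch": 3, "volume": 114.1},
    "GLN": {"C": 5, "N": 2, "O": 2, "S": 0, "H_nonexch": 5, "H_exch": 3, "volume": 143.8},
    "ASP": {"C": 4, "N": 1, "O": 3, "S": 0, "H_nonexch": 3, "H_exch": 1, "volume": 111.1},
    "GLU": {"C": 5, "N": 1, "O": 3, "S": 0, "H_nonexch": 5, "H_exch": 1, "volume": 138.4},
    "LYS": {"C": 6, "N": 2, "O": 1, "S": 0, "H_nonexch": 9, "H_exch": 4, "volume": 168.6},
    "ARG": {"C": 6, "N": 4, "O": 1, "S": 0, "H_nonexch": 7, "H_exch": 6, "volume": 173.4},
    "HIS": {"C": 6, "N": 3, "O": 1, "S": 0, "H_nonexch": 5, "H_exch": 2, "volume": 153.2},
}

# Methyl carbon atom names by residue type, for the "methyl-carbon" selection.
METHYL_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CG1", "CG2"),
    "LEU": ("CD1", "CD2"),
    "ILE": ("CD1", "CG2"),
    "THR": ("CG2",),
    "MET": ("CE",),
}


def residue_scattering_length(
    resname: str,
    deuteration: float,
    f_d2o: float,
    exchange_efficiency: float = 0.9,
) -> float:
    """Excess scattering length (fm) of one residue bead.

    ``deuteration`` is the fraction of non-exchangeable hydrogens replaced by
    deuterium (growth labelling of the chain); exchangeable hydrogens follow
    the buffer with the given exchange efficiency.  The excluded-volume term
    subtracts solvent displaced by the residue.
    """
    try:
        comp = RESIDUES[resname.upper()]
    except KeyError:
        raise KeyError(f"no composition table entry for residue {resname!r}") from None
    if not 0.0 <= deuteration <= 1.0:
        raise ValueError(f"deuteration fraction must be in [0,1], got {deuteration}")
    b = (
        comp["C"] * B_COHERENT["C"]
        + comp["N"] * B_COHERENT["N"]
        + comp["O"] * B_COHERENT["O"]
        + comp["S"] * B_COHERENT["S"]
    )
    b_h = B_COHERENT["H"]
    b_d = B_COHERENT["D"]
    b += comp["H_nonexch"] * ((1.0 - deuteration) * b_h + deuteration * b_d)
    f_exch = f_d2o * exchange_efficiency
    b += comp["H_exch"] * ((1.0 - f_exch) * b_h + f_exch * b_d)
    b -= solvent_density(f_d2o) * comp["volume"]
    return b
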