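"""Monoisotopic mass constants and elementary mass arithmetic.

Everything downstream (glycan Y ions, peptide b/y ladders, precursor
deductions) is computed on the NEUTRAL monoisotopic scale in daltons;
singly-protonated (MH+) values appear only at report boundaries, because
printed glycopeptide backbone masses are conventionally MH+.

The residue symbol ``J`` denotes an asparagine inside an N-glycosylation
sequon (N-X-S/T/C, X != P).  It has exactly the mass of N; the distinct
symbol restricts where the HexNAc modification may be placed.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

from pyteomics import mass as _pt_mass

__all__ = [
    "WATER",
    "PROTON",
    "CROSS_RING_02X_OFFSET",
    "AA_RESIDUE_MASSES",
    "MONOSACCHARIDES",
    "MONOSACCHARIDE_SYMBOLS",
    "MOD_MASSES",
    "OXONIUM_LOSSES",
    "peptide_neutral_mass",
    "mz_from_neutral",
    "neutral_from_mz",
    "ppm_error",
    "oxonium_mz",
]

WATER: float = 18.010565
PROTON: float = 1.007276

#: Glycan residue masses (attached residues, i.e. no terminal water).
MONOSACCHARIDES: dict[str, float] = {
    "Hex": 162.052824,
    "HexNAc": 203.079373,
    "NeuAc": 291.095417,
    "NeuGc": 307.090331,
    "dHex": 146.057909,
}

#: One-letter symbols used by the bracketed glycan encoding.
MONOSACCHARIDE_SYMBOLS: dict[str, str] = {
    "H": "Hex",
    "N": "HexNAc",
    "A": "NeuAc",
    "G": "NeuGc",
    "F": "dHex",
}

#: 0,2X cross-ring fragment of the reducing-end HexNAc retained on the
#: peptide: HexNAc residue minus C4H8O4.
CROSS_RING_02X_OFFSET: float = 83.037114

MOD_MASSES: dict[str, float] = {
    "carbamidomethyl_C": 57.021464,
    "oxidation_M": 15.994915,
    "HexNAc_J": 203.079373,
}

# Amino-acid residue masses: the 20 standard residues plus J (== N).
AA_RESIDUE_MASSES: dict[str, float] = {
    aa: m for aa, m in _pt_mass.std_aa_mass.items() if len(aa) == 1 and aa.isupper()
}
AA_RESIDUE_MASSES["J"] = AA_RESIDUE_MASSES["N"]

#: Small-molecule neutral losses seen on oxonium ions.
OXONIUM_LOSSES: dict[str, float] = {
    "H2O": WATER,
    "CH2O": 30.010565,
}


class UnknownResidueError(KeyError):
    """A peptide sequence contained a symbol outside the residue table."""


def peptide_neutral_mass(
    sequence: str, mods: Iterable[Tuple[int, float]] = ()
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide.

    Parameters
    ----------
    sequence:
        Residue-symbol string (standard 20 letters plus ``J``).
    mods:
        ``(position, delta_mass_da)`` pairs; positions are 0-based indexes
        into ``sequence`` and are not validated beyond range.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER
    for aa in sequence:
        try:
            total += AA_RESIDUE_MASSES[aa]
        except KeyError:
            raise UnknownResidueError(f"unknown residue symbol {aa!r}") from None
    n = len(sequence)
    for pos, delta in mods:
        if not 0 <= pos < n:
            raise ValueError(f"modification position {pos} outside sequence")
        total += delta
    return total


def mz_from_neutral(neutral: float, charge: int) -> float:
    """m/z of a neutral mass carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    """Inverse of :func:`mz_from_neutral`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def oxonium_mz(composition: Sequence[str], losses: Sequence[str] = ()) -> float:
    """Protonated oxonium-ion m/z for a small glycan fragment.

    ``composition`` lists monosaccharide names (e.g. ``["HexNAc"]``);
    ``losses`` lists small-molecule losses from :data:`OXONIUM_LOSSES`.
    The oxonium of a residue X is protonated X with the glycosidic oxygen
    retained, numerically the residue mass plus a proton; e.g. the HexNAc
    oxonium is 204.0867 and its -CH2O -2·H2O secondary fragment is the
    138.0550 trigger ion.
    """
    if not composition:
        raise ValueError("empty composition")
    mz = sum(MONOSACCHARIDES[name] for name in composition) + PROTON
    mz -= sum(OXONIUM_LOSSES[loss] for loss in losses)
    if mz <= 0:
        raise ValueError("losses exceed fragment mass")
    return mz
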