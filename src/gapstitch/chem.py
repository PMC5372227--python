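"""Amino-acid monoisotopic masses and sequence-mass arithmetic.

All mass bookkeeping in this package runs through this module. Masses are
monoisotopic residue masses in daltons, taken from :mod:`pyteomics.mass`.
``sequence_mass`` deliberately excludes the terminal water: gap arithmetic on
mass offsets only balances for pure residue-mass sums, because every constant
term (ion type, water, proton) shared by a pair of tags cancels in their
offset difference.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

__all__ = [
    "RESIDUE_MASSES",
    "WATER",
    "STANDARD_RESIDUES",
    "residue_mass",
    "sequence_mass",
    "match_amino_acid",
    "reverse",
]

#: Letter -> monoisotopic residue mass (Da), 20 standard residues. I and L are
#: isobaric (113.08406 Da); both letters are accepted everywhere.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Monoisotopic mass of water (Da), used for precursor/peak reflection.
WATER: float = _pmass.calculate_mass(formula="H2O")

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

# Canonical residues for mass -> letter inference: I is dropped so that an
# isobaric match always reports "L" (I/L cannot be told apart by mass).
_CANONICAL: list[tuple[str, float]] = sorted(
    ((aa, m) for aa, m in RESIDUE_MASSES.items() if aa != "I"),
    key=lambda t: t[1],
)


def residue_mass(aa: str) -> float:
    """Monoisotopic residue mass of a single amino-acid letter.

    Raises
    ------
    KeyError
        If *aa* is not one of the 20 standard residue letters.
    """
    try:
        return RESIDUE_MASSES[aa]
    except KeyError:
        raise KeyError(f"unknown amino-acid letter {aa!r}") from None


def sequence_mass(s: str) -> float:
    """Sum of residue masses of *s* (no water term); 0.0 for the empty string."""
    total = 0.0
    for aa in s:
        total += residue_mass(aa)
    return total


def match_amino_acid(delta: float, tol: float) -> str | None:
    """Return the residue whose mass lies within *tol* Da of *delta*.

    Returns ``None`` when no residue matches (a valid outcome, not an error).
    If more than one residue falls inside the window the nearest one wins;
    the isobaric I/L pair is always reported as ``"L"``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    best: str | None = None
    best_err = tol
    for aa, m in _CANONICAL:
        err = abs(m - delta)
        if err <= best_err:
            best, best_err = aa, err
    return best


def reverse(s: str) -> str:
    """Reversed copy of an amino-acid string."""
    return s[::-1]
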