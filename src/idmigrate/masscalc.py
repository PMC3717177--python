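"""Monoisotopic mass and m/z arithmetic for the precursor delta-m/z check.

The delta m/z of a peptide-spectrum match (PSM) is the signed difference
between the precursor m/z measured by the instrument and the m/z computed
from the identified sequence, its modifications, and the annotated charge:

    theoretical m/z = (M + z * m_proton) / z
    delta m/z       = observed m/z - theoretical m/z   [thomson, Th]

where M is the monoisotopic peptide mass (sum of residue masses + H2O + the
monoisotopic deltas of all modifications). On a correctly annotated PSM the
delta is close to zero; systematic offsets betray annotation defects — a
missing methionine-oxidation annotation shifts it by +15.994915/z, a
spuriously added fixed label shifts it by -(label delta)/z, and a wrong
charge annotation moves it by many Th.

All arithmetic is monoisotopic. Isoleucine and leucine share one mass; no
attempt is made to distinguish them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

__all__ = [
    "PhysicalConstants",
    "DEFAULT_CONSTANTS",
    "MassError",
    "peptide_mass",
    "theoretical_mz",
    "delta_mz",
    "infer_charge",
]


class MassError(ValueError):
    """Raised on invalid sequences, charges or m/z values."""


# Monoisotopic residue masses of the 20 standard amino acids, Da.
# Residue mass = mass of the amino acid minus one water (the peptide-bond
# condensation); a peptide's neutral mass is the residue sum plus one H2O.
_RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "G": 57.02146374,
        "A": 71.03711381,
        "S": 87.03202844,
        "P": 97.05276385,
        "V": 99.06841395,
        "T": 101.04767851,
        "C": 103.00918448,
        "L": 113.08406401,
        "I": 113.08406401,
        "N": 114.04292747,
        "D": 115.02694306,
        "Q": 128.05857754,
        "K": 128.09496305,
        "E": 129.04259313,
        "M": 131.04048463,
        "H": 137.05891189,
        "F": 147.06841395,
        "R": 156.10111105,
        "Y": 163.06332858,
        "W": 186.07931298,
    }
)

_WATER_MASS = 18.01056468   # monoisotopic H2O, Da
_PROTON_MASS = 1.00727646688  # monoisotopic proton, Da


@dataclass(frozen=True)
class PhysicalConstants:
    """Frozen table of monoisotopic constants used by the validator.

    Attributes
    ----------
    residue_masses:
        The 20 standard single-letter amino-acid codes mapped to their
        monoisotopic residue masses in Da.
    water_mass:
        Monoisotopic mass of H2O in Da (added once per peptide).
    proton_mass:
        Monoisotopic proton mass in Da (added once per charge).
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: _RESIDUE_MASSES
    )
    water_mass: float = _WATER_MASS
    proton_mass: float = _PROTON_MASS

    def __post_init__(self) -> None:
        if len(self.residue_masses) != 20:
            raise MassError(
                f"residue table must have exactly 20 entries, "
                f"got {len(self.residue_masses)}"
            )
        for aa, m in self.residue_masses.items():
            if not (math.isfinite(m) and m > 0):
                raise MassError(f"residue {aa!r} has invalid mass {m!r}")
        if not (self.water_mass > 0 and self.proton_mass > 0):
            raise MassError("water_mass and proton_mass must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()


def peptide_mass(
    sequence: str,
    modifications: Sequence[tuple[int, float]] = (),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Monoisotopic neutral mass of a (modified) peptide, Da.

    Parameters
    ----------
    sequence:
        Uppercase amino-acid string over the 20-letter standard alphabet.
    modifications:
        ``(position, mono_delta)`` pairs. Position 0 denotes the N-terminus,
        ``len(sequence) + 1`` the C-terminus, and 1..len(sequence) the
        1-based residue index. Only the position's validity is checked here;
        residue specificity is the modification table's concern.

    Raises
    ------
    MassError
        On an empty sequence, a character outside the 20-letter alphabet
        (B, J, O, U, X, Z included), a non-finite delta, or an out-of-range
        position.
    """
    if not sequence:
        raise MassError("empty peptide sequence")
    masses = constants.residue_masses
    total = constants.water_mass
    for i, aa in enumerate(sequence):
        try:
            total += masses[aa]
        except KeyError:
            raise MassError(
                f"unknown residue {aa!r} at position {i + 1} in {sequence!r}"
            ) from None
    n = len(sequence)
    for pos, delta in modifications:
        if not 0 <= pos <= n + 1:
            raise MassError(
                f"modification position {pos} out of range 0..{n + 1} "
                f"for sequence of length {n}"
            )
        if not math.isfinite(delta):
            raise MassError(f"non-finite modification delta at position {pos}")
        total += delta
    return total


def theoretical_mz(
    mass: float,
    charge: int,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """m/z of the [M + zH]^z+ ion: ``(mass + charge * m_proton) / charge``.

    Raises :class:`MassError` for charge <= 0 — a zero charge reaching mass
    arithmetic means an uncorrected missing-charge record slipped through.
    """
    if charge <= 0:
        raise MassError(f"charge must be >= 1, got {charge}")
    return (mass + charge * constants.proton_mass) / charge


def delta_mz(observed_mz: float, theoretical: float) -> float:
    """Signed precursor error ``observed_mz - theoretical`` in Th."""
    for name, value in (("observed_mz", observed_mz), ("theoretical_mz", theoretical)):
        if not math.isfinite(value) or value <= 0:
            raise MassError(f"{name} must be finite and > 0, got {value!r}")
    return observed_mz - theoretical


def infer_charge(
    theoretical_mass: float,
    observed_mz: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    max_charge: int = 8,
) -> int:
    """Recover a missing precursor charge from mass and measured m/z.

    The charge is the ratio of the theoretical neutral mass to the measured
    m/z minus one proton, rounded to the nearest integer (ties round half
    away from zero, implemented explicitly for platform determinism) and
    clamped to >= 1.

    Raises
    ------
    MassError
        If ``observed_mz`` does not exceed the proton mass, or if the
        rounded charge exceeds ``max_charge`` (implausible precursor).
    """
    if observed_mz <= constants.proton_mass:
        raise MassError(
            f"observed m/z {observed_mz} not above proton mass; "
            "cannot infer charge"
        )
    ratio = theoretical_mass / (observed_mz - constants.proton_mass)
    charge = max(1, math.floor(ratio + 0.5))
    if charge > max_charge:
        raise MassError(
            f"inferred charge {charge} exceeds maximum plausible "
            f"charge {max_charge} (mass {theoretical_mass:.4f}, "
            f"m/z {observed_mz:.4f})"
        )
    return charge
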