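"""Geometry-to-stoichiometry conversions for amyloid-beta assemblies.

Two routes connect measured geometry to molecule counts:

* map volume -> mass, via the standard protein density conversion of
  825 Da per cubic angstrom, then mass -> monomers;
* filament length -> monomers, assuming each added monomer contributes one
  cross-beta strand of 0.48 nm rise along the long axis.

The monomer mass is the average (isotope-weighted) mass of the 42-residue
amyloid-beta peptide, frozen below from its sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "AB42_SEQUENCE",
    "AB42_MONOMER_MASS_DA",
    "AB42_CORE_MASS_DA",
    "StoichiometryConstants",
    "StoichiometryResult",
    "volume_to_mass",
    "mass_to_monomers",
    "length_to_monomers",
    "rate_to_monomer_rate",
    "format_kda",
]

#: Canonical human amyloid-beta 1-42 sequence.
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

# Average masses computed from the sequence with the standard amino-acid
# residue mass table (monoisotopic tables give ~2.8 Da less for the full
# peptide; average masses are what densitometry-style conversions assume):
#   full 1-42:            4514.04 Da
#   ordered core 15-42:   2833.35 Da  (N-terminal 14 residues are typically
#                                      too disordered to contribute density)
AB42_MONOMER_MASS_DA = 4514.04
AB42_CORE_MASS_DA = 2833.35


@dataclass(frozen=True)
class StoichiometryConstants:
    """Fixed conversion constants.

    density_conversion : Da per cubic nanometre of map volume (825; often
        misprinted as Da per cubic angstrom — standard protein density is
        ~0.825 Da/A^3, i.e. 825 Da/nm^3, which is what makes 64,000 A^3
        come out at 52.8 kDa).
    strand_rise_nm     : axial rise per monomer in a cross-beta stack (0.48).
    monomer_mass_da    : average mass of one monomer.
    """

    density_conversion: float = 825.0
    strand_rise_nm: float = 0.48
    monomer_mass_da: float = AB42_MONOMER_MASS_DA

    def __post_init__(self) -> None:
        if min(self.density_conversion, self.strand_rise_nm, self.monomer_mass_da) <= 0:
            raise ValueError("all constants must be positive")

    def truncated(self) -> "StoichiometryConstants":
        """Constants using the mass of the ordered core (residues 15-42) only."""
        return replace(self, monomer_mass_da=AB42_CORE_MASS_DA)


@dataclass(frozen=True)
class StoichiometryResult:
    input_kind: str              # "volume" | "length" | "mass"
    input_value: float           # cubic angstrom, nm, or Da
    mass_da: float
    monomer_count_exact: float
    monomer_count: int

    def as_dict(self) -> dict:
        return {
            "input_kind": self.input_kind,
            "input_value": self.input_value,
            "mass_da": self.mass_da,
            "mass_kda_2sf": format_kda(self.mass_da),
            "monomer_count_exact": self.monomer_count_exact,
            "monomer_count": self.monomer_count,
        }


def format_kda(mass_da: float) -> float:
    """Mass in kDa rounded to two significant figures (reporting convention)."""
    kda = mass_da / 1000.0
    if kda == 0:
        return 0.0
    from math import floor, log10

    return round(kda, -int(floor(log10(abs(kda)))) + 1)


def volume_to_mass(volume_a3: float, c: StoichiometryConstants = StoichiometryConstants()) -> float:
    """Map volume (cubic angstrom) -> molecular mass (Da).

    ``density_conversion`` is in Da/nm^3; 1 nm^3 = 1000 A^3.
    """
    if volume_a3 <= 0:
        raise ValueError("volume must be positive")
    return volume_a3 * c.density_conversion / 1000.0


def mass_to_monomers(
    mass_da: float,
    c: StoichiometryConstants = StoichiometryConstants(),
    truncated: bool = False,
) -> StoichiometryResult:
    """Mass (Da) -> monomer count.

    With ``truncated=True`` the count is computed against the mass of the
    ordered core (residues 15-42), appropriate when the measured density
    likely excludes the disordered N-terminus.
    """
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    cc = c.truncated() if truncated else c
    exact = mass_da / cc.monomer_mass_da
    return StoichiometryResult("mass", mass_da, mass_da, exact, int(round(exact)))


def length_to_monomers(
    length_nm: float, c: StoichiometryConstants = StoichiometryConstants()
) -> StoichiometryResult:
    """Filament length (nm) -> monomer count via the 0.48 nm strand rise."""
    if length_nm <= 0:
        raise ValueError("length must be positive")
    exact = length_nm / c.strand_rise_nm
    mass = exact * c.monomer_mass_da
    return StoichiometryResult("length", length_nm, mass, exact, int(round(exact)))


def volume_to_monomers(
    volume_a3: float,
    c: StoichiometryConstants = StoichiometryConstants(),
    truncated: bool = False,
) -> StoichiometryResult:
    """Convenience composition: volume -> mass -> monomers."""
    mass = volume_to_mass(volume_a3, c)
    res = mass_to_monomers(mass, c, truncated=truncated)
    return StoichiometryResult("volume", volume_a3, mass, res.monomer_count_exact, res.monomer_count)


def rate_to_monomer_rate(
    rate_nm_per_min: float, c: StoichiometryConstants = StoichiometryConstants()
) -> float:
    """Elongation rate (nm/min) -> monomer addition rate (1/min) at one end."""
    if rate_nm_per_min < 0:
        raise ValueError("rate must be non-negative")
    return rate_nm_per_min / c.strand_rise_nm
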