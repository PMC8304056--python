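"""Isotope scattering constants, material SLDs, contrast mixing and critical edges.

The scattering length density (SLD) of a medium is the volume density of coherent
scattering lengths, ``rho = n_fu * sum_j b_j`` with ``n_fu`` the number of formula
units per unit volume.  For neutrons the ``b_j`` are the isotope-specific coherent
scattering lengths; for X-rays ``b_j = r0 * Z_j`` with ``r0`` the Thomson electron
radius (no anomalous-dispersion terms here: f1 = Z, f2 = 0).

Unit conventions used across the package: lengths in Å, momentum transfer Q in
Å⁻¹, scattering lengths stored in fm (1 fm = 1e-5 Å), SLDs stored in Å⁻² and
conventionally quoted in units of 1e-6 Å⁻².

The isotope table is shipped as a JSON data file (``data/isotopes.json``) with
coherent scattering lengths frozen from Sears' 1992 compilation; ``"D"``/``"T"``
are aliases for ``"2H"``/``"3H"`` and a bare element symbol refers to the natural
element (for hydrogen, the 1H value, which is what contrast arithmetic needs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "IsotopeTable",
    "Material",
    "SldValue",
    "default_table",
    "material_sld",
    "mix_solvent_sld",
    "solve_match_fraction",
    "refractive_index",
    "critical_q",
]

#: Avogadro constant, mol⁻¹.
N_AVOGADRO = 6.02214076e23
#: Thomson scattering length (classical electron radius), fm.
R_ELECTRON_FM = 2.8179403262
#: fm → Å.
FM_TO_ANGSTROM = 1.0e-5

_ALIASES = {"D": "2H", "T": "3H", "1H": "H"}


class UnknownIsotopeError(KeyError):
    """Raised when an isotope label is not present in the table."""


@dataclass(frozen=True)
class SldValue:
    """A (possibly complex) scattering length density in Å⁻²."""

    real: float
    imag: float = 0.0

    def __post_init__(self) -> None:
        if self.imag < 0:
            raise ValueError("imaginary SLD (absorption) must be >= 0")

    def __complex__(self) -> complex:
        return complex(self.real, self.imag)

    @property
    def in_1e6(self) -> float:
        """Real part in the conventional 1e-6 Å⁻² display units."""
        return self.real * 1e6


class IsotopeTable:
    """Lookup of coherent scattering lengths (fm) and atomic numbers per isotope."""

    def __init__(self, entries: Mapping[str, Mapping[str, float]]):
        self._entries = {k: dict(v) for k, v in entries.items() if not k.startswith("_")}

    @classmethod
    def from_package_data(cls) -> "IsotopeTable":
        with resources.files("memscatter.data").joinpath("isotopes.json").open() as fh:
            return cls(json.load(fh))

    def _resolve(self, label: str) -> dict:
        key = _ALIASES.get(label, label)
        try:
            return self._entries[key]
        except KeyError:
            raise UnknownIsotopeError(
                f"isotope label {label!r} not in table "
                f"(known: {', '.join(sorted(self._entries))})"
            ) from None

    def b_coherent(self, label: str) -> float:
        """Coherent neutron scattering length in fm."""
        return float(self._resolve(label)["b_coh_fm"])

    def atomic_number(self, label: str) -> int:
        return int(self._resolve(label)["Z"])

    def mass(self, label: str) -> float:
        """Atomic mass in u (g/mol)."""
        return float(self._resolve(label)["mass_u"])

    def b_incoherent(self, label: str) -> float | None:
        """Incoherent scattering length in fm where tabulated (background heuristics)."""
        val = self._resolve(label).get("b_inc_fm")
        return None if val is None else float(val)

    def __contains__(self, label: str) -> bool:
        return _ALIASES.get(label, label) in self._entries


_DEFAULT: IsotopeTable | None = None


def default_table() -> IsotopeTable:
    """The package-wide isotope table loaded from the shipped JSON data file."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = IsotopeTable.from_package_data()
    return _DEFAULT


@dataclass(frozen=True)
class Material:
    """A homogeneous material: isotope counts per formula unit plus mass density.

    Parameters
    ----------
    formula : mapping of isotope label -> count per formula unit (> 0).
    mass_density : g/cm³.
    """

    formula: Mapping[str, float]
    mass_density: float
    table: IsotopeTable = field(default_factory=default_table, compare=False)

    def __post_init__(self) -> None:
        if not self.formula:
            raise ValueError("empty formula")
        if any(c <= 0 for c in self.formula.values()):
            raise ValueError("formula counts must be > 0")
        if self.mass_density <= 0:
            raise ValueError("mass density must be > 0")

    @property
    def molar_mass(self) -> float:
        """g/mol of one formula unit."""
        return sum(n * self.table.mass(lbl) for lbl, n in self.formula.items())

    @property
    def number_density(self) -> float:
        """Formula units per Å³."""
        return self.mass_density * N_AVOGADRO / self.molar_mass * 1e-24


def material_sld(material: Material, probe: str = "neutron") -> SldValue:
    """SLD of a material, neutron (Σ b_j) or X-ray (r0 Σ Z_j) branch, in Å⁻²."""
    n_fu = material.number_density
    if probe == "neutron":
        total_b = sum(
            n * material.table.b_coherent(lbl) for lbl, n in material.formula.items()
        )
    elif probe == "xray":
        total_b = R_ELECTRON_FM * sum(
            n * material.table.atomic_number(lbl) for lbl, n in material.formula.items()
        )
    else:
        raise ValueError(f"probe must be 'neutron' or 'xray', got {probe!r}")
    return SldValue(n_fu * total_b * FM_TO_ANGSTROM)


def mix_solvent_sld(sld_a: SldValue, sld_b: SldValue, fraction_b: float) -> SldValue:
    """Linear volume-fraction mix of two solvents (e.g. H2O/D2O contrast series)."""
    if not 0.0 <= fraction_b <= 1.0:
        raise ValueError(f"fraction_b must be in [0, 1], got {fraction_b}")
    f = fraction_b
    return SldValue(
        (1 - f) * sld_a.real + f * sld_b.real,
        (1 - f) * sld_a.imag + f * sld_b.imag,
    )


def solve_match_fraction(
    sld_target: SldValue, sld_a: SldValue, sld_b: SldValue, clip: bool = True
) -> float:
    """Fraction of component b whose a/b mixture matches ``sld_target``.

    The linear mixing rule is inverted exactly.  A result outside [0, 1] means the
    target cannot be reached with this solvent pair; it is clipped (default) after
    a warning, or returned as-is with ``clip=False``.
    """
    denom = sld_b.real - sld_a.real
    if denom == 0.0:
        raise ValueError("solvent endpoints have identical SLD; no match solution")
    f = (sld_target.real - sld_a.real) / denom
    if not 0.0 <= f <= 1.0:
        import warnings

        warnings.warn(
            f"match fraction {f:.3f} outside [0, 1]: target unreachable with "
            "these endpoints",
            stacklevel=2,
        )
        if clip:
            f = min(max(f, 0.0), 1.0)
    return f


def refractive_index(sld: SldValue, wavelength: float) -> float:
    """Refractive index n = 1 − λ²ρ/(2π) for a medium of real SLD ρ."""
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    return 1.0 - wavelength**2 * sld.real / (2.0 * math.pi)


def critical_q(sld_fronting: SldValue, sld_backing: SldValue) -> float:
    """Critical momentum transfer for total external reflection, Å⁻¹.

    Qc = sqrt(16π Δρ) for positive contrast Δρ = ρ_backing − ρ_fronting; zero when
    the backing SLD does not exceed the fronting one (no total reflection).
    """
    delta = sld_backing.real - sld_fronting.real
    if delta <= 0.0:
        return 0.0
    return math.sqrt(16.0 * math.pi * delta)
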