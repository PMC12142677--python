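"""Exact-mass and m/z arithmetic for small-molecule ion species.

Monoisotopic masses, adduct m/z values, ppm errors, carbon-isotope spacing,
charge-state inference from isotope spacing and ion--gas reduced mass: the
arithmetic that every calibration and annotation decision downstream is
attached to.

m/z convention
--------------
By default, adduct m/z values are computed by adding *neutral-atom*
monoisotopic masses (H, Na, K) to the neutral (or pre-charged cation) mass
and dividing by the charge, with the electron mass ignored entirely.  This is
the convention under which TOF instruments calibrated against neutral-atom
reference tables report m/z, and it is the convention that reproduces
sub-ppm-consistent mass errors for quaternary-ammonium cations observed as
[M]+ and [M+H]2+.  Pass ``electron_correction=True`` to subtract ``z``
electron masses instead (proton-mass convention) for data processed the
other way.
"""

from __future__ import annotations

import json
import re
from collections.abc import Mapping
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, NamedTuple, Union

__all__ = [
    "ATOMIC_MASS_VERSION",
    "MONOISOTOPIC_MASS",
    "C13_C12_SPACING",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "Adduct",
    "ADDUCTS",
    "IonSpecies",
    "DriftGas",
    "N2",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "isotope_mz",
    "infer_charge",
    "ChargeInference",
    "reduced_mass",
]

_table = json.loads(
    resources.files("cimccs").joinpath("data/atomic_masses.json").read_text()
)

#: Version tag of the shipped atomic-mass table.
ATOMIC_MASS_VERSION: str = _table["version"]

#: Element symbol -> monoisotopic mass (Da).
MONOISOTOPIC_MASS: dict[str, float] = dict(_table["masses"])

#: Mass difference between 13C and 12C (Da); used as a single-parameter
#: approximation for isotopologue spacing (carbon-driven for organics).
C13_C12_SPACING = 1.003355

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = 1.007276466622

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_HILL_OK = re.compile(r"(?:[A-Z][a-z]?\d*)*")


class ElementalFormula(Mapping):
    """Immutable element -> count mapping with element-wise algebra.

    Accepts a Hill-notation string (``"C32H53N2O4"``), a mapping, or keyword
    counts.  Counts must be non-negative integers; zero counts are dropped.
    Subtraction raising below zero for any element is an error (you cannot
    lose atoms a molecule does not have).
    """

    __slots__ = ("_counts",)

    def __init__(
        self,
        counts: Union[str, Mapping[str, int], None] = None,
        **kwargs: int,
    ) -> None:
        merged: dict[str, int] = {}
        if isinstance(counts, str):
            merged.update(self._parse(counts))
        elif counts is not None:
            for el, n in counts.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in kwargs.items():
            merged[el] = merged.get(el, 0) + int(n)
        clean: dict[str, int] = {}
        for el, n in merged.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if n:
                clean[str(el)] = n
        self._counts: dict[str, int] = clean

    @staticmethod
    def _parse(formula: str) -> dict[str, int]:
        s = formula.strip()
        if _HILL_OK.fullmatch(s) is None:
            raise ValueError(f"cannot parse formula string {formula!r}")
        counts: dict[str, int] = {}
        for el, num in _TOKEN.findall(s):
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        # reject strings with stray characters (fullmatch above catches most,
        # but an empty match on e.g. "c32" would silently return {})
        rebuilt = sum(counts.values())
        if s and rebuilt == 0:
            raise ValueError(f"cannot parse formula string {formula!r}")
        return counts

    # -- Mapping protocol ---------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._counts))

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        out = dict(self._counts)
        for el, n in other._counts.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        out = dict(self._counts)
        for el, n in other._counts.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count "
                    f"({out.get(el, 0)} - {n})"
                )
            out[el] = new
        return ElementalFormula(out)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    @property
    def hill(self) -> str:
        """Hill-notation string: C, then H, then other elements alphabetically."""
        parts = []
        for el in ("C", "H"):
            n = self._counts.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(self._counts):
            if el in ("C", "H"):
                continue
            n = self._counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill!r})"


def monoisotopic_mass(formula: Union[ElementalFormula, str, Mapping[str, int]]) -> float:
    """Sum of per-atom monoisotopic masses (Da), no electron correction.

    Raises ``KeyError`` for element symbols absent from the shipped table.
    The empty formula has mass 0.
    """
    if not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    total = 0.0
    for el, n in formula.items():
        try:
            total += MONOISOTOPIC_MASS[el] * n
        except KeyError:
            raise KeyError(
                f"element {el!r} not in atomic-mass table "
                f"({ATOMIC_MASS_VERSION})"
            ) from None
    return total


@dataclass(frozen=True)
class Adduct:
    """Ionized form descriptor: atoms added to M (as neutral atoms) and charge."""

    label: str
    z: int
    atoms: ElementalFormula


#: Supported positive-mode adducts.  ``[M]+`` covers pre-charged cations
#: (e.g. quaternary ammonium species) and ``[M+H]2+`` their protonated,
#: doubly charged form.
ADDUCTS: dict[str, Adduct] = {
    a.label: a
    for a in (
        Adduct("[M+H]+", 1, ElementalFormula(H=1)),
        Adduct("[M+Na]+", 1, ElementalFormula(Na=1)),
        Adduct("[M+K]+", 1, ElementalFormula(K=1)),
        Adduct("[M+2H]2+", 2, ElementalFormula(H=2)),
        Adduct("[M]+", 1, ElementalFormula()),
        Adduct("[M+H]2+", 2, ElementalFormula(H=1)),
    )
}


def adduct_mz(mass: float, adduct: str, *, electron_correction: bool = False) -> float:
    """m/z of ``mass`` observed as ``adduct``.

    ``mass`` is the neutral monoisotopic mass, or the cation mass for
    pre-charged species observed as ``[M]+`` / ``[M+H]2+``.  Added H/Na/K are
    counted as neutral atoms; with ``electron_correction`` the total charge's
    electron mass is subtracted from the numerator.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    try:
        spec = ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        ) from None
    numerator = mass + monoisotopic_mass(spec.atoms)
    if electron_correction:
        numerator -= spec.z * ELECTRON_MASS
    return numerator / spec.z


@dataclass(frozen=True)
class IonSpecies:
    """An elemental composition observed as a particular adduct."""

    formula: ElementalFormula
    adduct: str
    mz: float
    z: int

    @classmethod
    def from_formula(
        cls,
        formula: Union[ElementalFormula, str],
        adduct: str,
        *,
        electron_correction: bool = False,
    ) -> "IonSpecies":
        if not isinstance(formula, ElementalFormula):
            formula = ElementalFormula(formula)
        mz = adduct_mz(
            monoisotopic_mass(formula), adduct, electron_correction=electron_correction
        )
        return cls(formula=formula, adduct=adduct, mz=mz, z=ADDUCTS[adduct].z)


@dataclass(frozen=True)
class DriftGas:
    """Mobility drift/buffer gas."""

    name: str
    mass: float  # monoisotopic mass, Da

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("drift-gas mass must be positive")


#: Default drift gas: molecular nitrogen, monoisotopic mass.
N2 = DriftGas("N2", 28.00615)


def ppm_error(measured: float, theoretical: float) -> float:
    """(measured - theoretical) / theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


def isotope_mz(mz: float, z: int = 1, k: int = 1) -> float:
    """m/z of the k-th carbon isotopologue of an ion at charge z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    if k < 0:
        raise ValueError("isotopologue index must be >= 0")
    return mz + k * C13_C12_SPACING / z


class ChargeInference(NamedTuple):
    z: int
    #: observed spacing minus the ideal 13C spacing at the inferred charge (Da)
    residual_da: float


def infer_charge(mz_mono: float, mz_iso: float, z_max: int = 4) -> ChargeInference:
    """Charge state implied by the monoisotopic/first-isotopologue spacing.

    A spacing of ~1.0034 Th implies z = 1, ~0.5017 implies z = 2, etc.
    Raises if the implied charge falls outside [1, z_max].
    """
    spacing = mz_iso - mz_mono
    if spacing <= 0:
        raise ValueError("isotopologue m/z must exceed monoisotopic m/z")
    z = round(C13_C12_SPACING / spacing)
    if z < 1 or z > z_max:
        raise ValueError(
            f"spacing {spacing:.6f} Th implies charge {z}, outside [1, {z_max}]"
        )
    return ChargeInference(z=z, residual_da=spacing - C13_C12_SPACING / z)


def reduced_mass(m_ion: float, m_gas: float) -> float:
    """Reduced mass of the ion--gas pair: 1/mu = 1/m_ion + 1/m_gas."""
    if m_ion <= 0 or m_gas <= 0:
        raise ValueError("masses must be positive")
    return 1.0 / (1.0 / m_ion + 1.0 / m_gas)
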