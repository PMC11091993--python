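"""Static nuclide tables and mass/neutron arithmetic.

The isotopologue layer designates an isotope by a signed unit-mass offset
from the *rounded average atomic mass* of the element (so ``C+1`` is 13C,
``O+2`` is 18O), while neutron counts in nominal-mass specifications are
measured against the *most abundant stable isotope*.  The two baselines
coincide for most biologically relevant elements but differ for a few
(Cu, Zn, Se, Br in the vendored table); both are kept explicit.

Nuclide masses and abundances are vendored from the NIST/CODATA atomic
weight compilation as a plain TSV (``nuclides.tsv``) so all arithmetic is
reproducible offline; a user table in the same format may be substituted
via :func:`load_nuclide_table`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "IsotopeRecord",
    "ElementRecord",
    "NuclideTable",
    "UnknownNuclideWarning",
    "load_nuclide_table",
    "default_table",
    "designation_to_mass_number",
    "neutron_excess",
    "monoisotopic_mass",
]


class UnknownNuclideWarning(UserWarning):
    """An isotope designation resolved to a mass number with no tabulated nuclide."""


@dataclass(frozen=True)
class IsotopeRecord:
    """One nuclide: element symbol, nucleon count, exact mass, natural abundance."""

    element_symbol: str
    mass_number: int
    exact_mass: float
    abundance: float
    stable: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError(f"abundance out of [0,1] for {self.element_symbol}-{self.mass_number}")
        if self.mass_number < 1:
            raise ValueError("mass_number must be positive")


@dataclass(frozen=True)
class ElementRecord:
    """An element with its isotopes and the two integer-mass baselines.

    ``rounded_avg_mass`` is the nearest integer to the abundance-weighted
    mean of the stable-isotope masses (the designation baseline);
    ``most_abundant_mass_number`` is the mass number of the most abundant
    stable isotope (the neutron-count baseline).
    """

    symbol: str
    atomic_number: int
    isotopes: tuple[IsotopeRecord, ...]
    rounded_avg_mass: int = field(init=False)
    most_abundant_mass_number: int = field(init=False)

    def __post_init__(self) -> None:
        stable = [i for i in self.isotopes if i.stable]
        if not stable:
            raise ValueError(f"element {self.symbol} has no stable isotopes in table")
        total = sum(i.abundance for i in stable)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"stable abundances of {self.symbol} sum to {total:.4f}, not 1")
        mean = sum(i.exact_mass * i.abundance for i in stable) / total
        object.__setattr__(self, "rounded_avg_mass", int(round(mean)))
        best = max(stable, key=lambda i: i.abundance)
        object.__setattr__(self, "most_abundant_mass_number", best.mass_number)

    def isotope(self, mass_number: int) -> Optional[IsotopeRecord]:
        for iso in self.isotopes:
            if iso.mass_number == mass_number:
                return iso
        return None

    @property
    def stable_isotopes(self) -> tuple[IsotopeRecord, ...]:
        return tuple(i for i in self.isotopes if i.stable)


# Atomic numbers for the elements the vendored table covers; used only to
# populate ElementRecord.atomic_number and the mass_number sanity check.
_ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12,
    "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Fe": 26,
    "Cu": 29, "Zn": 30, "Se": 34, "Br": 35, "I": 53,
}


class NuclideTable:
    """Lookup of :class:`ElementRecord` by symbol."""

    def __init__(self, elements: Iterable[ElementRecord]):
        self._by_symbol = {e.symbol: e for e in elements}

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __iter__(self):
        return iter(self._by_symbol.values())

    def element(self, symbol: str) -> ElementRecord:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol: {symbol!r}") from None

    def baseline_discrepancies(self) -> dict[str, tuple[int, int]]:
        """Elements whose rounded-average and most-abundant baselines differ.

        Returns ``{symbol: (rounded_avg_mass, most_abundant_mass_number)}``.
        """
        return {
            e.symbol: (e.rounded_avg_mass, e.most_abundant_mass_number)
            for e in self
            if e.rounded_avg_mass != e.most_abundant_mass_number
        }


def load_nuclide_table(path: str | Path | None = None) -> NuclideTable:
    """Load a nuclide table from TSV (columns: symbol, mass_number, exact_mass,
    abundance, stable); defaults to the vendored table."""
    if path is None:
        text = resources.files("isoinchi").joinpath("nuclides.tsv").read_text()
        rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    by_element: dict[str, list[IsotopeRecord]] = {}
    for row in rows:
        rec = IsotopeRecord(
            element_symbol=row["symbol"],
            mass_number=int(row["mass_number"]),
            exact_mass=float(row["exact_mass"]),
            abundance=float(row["abundance"]),
            stable=row["stable"].strip() in ("1", "true", "True"),
        )
        z = _ATOMIC_NUMBERS.get(rec.element_symbol)
        if z is not None and rec.mass_number < z:
            raise ValueError(f"mass number {rec.mass_number} below atomic number for {rec.element_symbol}")
        by_element.setdefault(rec.element_symbol, []).append(rec)
    elements = [
        ElementRecord(
            symbol=sym,
            atomic_number=_ATOMIC_NUMBERS.get(sym, 0),
            isotopes=tuple(sorted(isos, key=lambda i: i.mass_number)),
        )
        for sym, isos in by_element.items()
    ]
    return NuclideTable(elements)


_DEFAULT_TABLE: NuclideTable | None = None


def default_table() -> NuclideTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_nuclide_table()
    return _DEFAULT_TABLE


def designation_to_mass_number(
    element: str, shift: int, table: NuclideTable | None = None
) -> int:
    """Resolve a signed designation (unit-mass offset from the rounded average
    atomic mass) to a mass number, e.g. ``("C", +1) -> 13``.

    A designation that lands on no tabulated nuclide is returned with an
    :class:`UnknownNuclideWarning` rather than rejected — the layer grammar
    permits arbitrary shifts.
    """
    table = table or default_table()
    rec = table.element(element)
    mass_number = rec.rounded_avg_mass + shift
    if rec.isotope(mass_number) is None:
        warnings.warn(
            f"designation {element}{shift:+d} -> mass number {mass_number} "
            "has no tabulated nuclide",
            UnknownNuclideWarning,
            stacklevel=2,
        )
    return mass_number


def neutron_excess(element: str, mass_number: int, table: NuclideTable | None = None) -> int:
    """Extra neutrons relative to the element's most abundant stable isotope
    (``("C", 13) -> 1``, ``("O", 18) -> 2``)."""
    table = table or default_table()
    return mass_number - table.element(element).most_abundant_mass_number


def monoisotopic_mass(
    formula: Mapping[str, int],
    assignment: Mapping[str, Mapping[int, int]] | None = None,
    table: NuclideTable | None = None,
) -> float:
    """Exact mass of a formula in Da; unassigned atoms default to each
    element's most abundant stable isotope.

    ``assignment`` maps element -> {mass_number: count} for atoms whose
    isotope is fixed; its per-element counts must not exceed the formula.
    """
    table = table or default_table()
    total = 0.0
    for symbol, count in formula.items():
        rec = table.element(symbol)
        assigned = dict(assignment.get(symbol, {})) if assignment else {}
        n_assigned = sum(assigned.values())
        if n_assigned > count:
            raise ValueError(
                f"assignment for {symbol} covers {n_assigned} atoms but formula has {count}"
            )
        for mass_number, k in assigned.items():
            iso = rec.isotope(mass_number)
            if iso is None:
                raise ValueError(f"no tabulated nuclide {symbol}-{mass_number}")
            total += iso.exact_mass * k
        default = rec.isotope(rec.most_abundant_mass_number)
        assert default is not None
        total += default.exact_mass * (count - n_assigned)
    return total
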