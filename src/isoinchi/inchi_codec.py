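"""Parser and canonical emitter for extended InChI strings.

The extension keeps the standard InChI skeleton (formula plus connection,
hydrogen, charge and stereo layers, which are retained opaquely and
re-emitted byte-identically) and adds semantics on two layers:

* ``/i`` — the isotopic layer: per-atom isotope designations and explicit
  hydrogen-isotope counts, read under the *partial isotopomer*
  interpretation (unspecified atoms are unknown, not defaulted).
* ``/a`` — the isotopologue layer: parenthesized groups expressing
  ambiguous isotope localization, either isotope-resolved
  (``(C2+1)`` = two 13C somewhere; ``(C1+1,1,2,3)`` = one 13C among atoms
  1–3) or nominal-mass (``(3n)`` = three extra neutrons;
  ``(4n,1,2,3,4,5,6)`` = four extra neutrons confined to listed atoms).

Atom numbers follow InChI canonical numbering: carbons occupy 1..n_C,
remaining heavy elements follow in alphabetical order; hydrogens are
unnumbered, so hydrogen-isotope groups list *bearer* heavy atoms.

Parsing is purely syntactic (it never consults nuclide data); semantic
rules live in :mod:`isoinchi.layer_semantics`.  ``emit`` produces a single
canonical text form: entries sorted by atom number, isotope groups before
neutron groups (carbon first, then alphabetical, then ascending shift),
candidate lists ascending, and a candidate list covering every atom of its
element omitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "InChIParseError",
    "InChIEmitError",
    "SkeletonInChI",
    "AtomIsotopeSpec",
    "IsotopologueGroup",
    "ExtendedInChI",
    "parse",
    "emit",
    "parse_formula",
    "atom_element_map",
]


class InChIParseError(ValueError):
    """Malformed extended InChI text; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class InChIEmitError(ValueError):
    """Model violates a type invariant; serialization refused."""


# All IUPAC element symbols — syntax-level check only, independent of the
# nuclide table (exotic elements parse; the validator flags what the
# arithmetic cannot handle).
ELEMENT_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_I_ENTRY = re.compile(r"^(\d+)([+-]\d+)?((?:[HDT]\d*)*)$")
_H_TOKEN = re.compile(r"([HDT])(\d*)")
_A_ISOTOPE_GROUP = re.compile(r"^([A-Z][a-z]?)(\d+)([+-]\d+)(?:,(\d+(?:,\d+)*))?$")
_A_NEUTRON_GROUP = re.compile(r"^(\d+)n(?:,(\d+(?:,\d+)*))?$")
_H_LAYER_MOBILE = re.compile(r"^\(H(\d*)(?:,(\d+(?:,\d+)*))\)$")

_H_LETTER_TO_ISO = {"H": 1, "D": 2, "T": 3}
_ISO_TO_H_LETTER = {1: "H", 2: "D", 3: "T"}


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts."""
    if not text:
        raise InChIParseError("empty molecular formula", 0)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m:
            raise InChIParseError(f"malformed formula near {text[pos:]!r}", pos)
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ELEMENT_SYMBOLS:
            raise InChIParseError(f"unknown element symbol {symbol!r}", pos)
        if symbol in counts:
            raise InChIParseError(f"duplicate element {symbol!r} in formula", pos)
        if digits == "0":
            raise InChIParseError("zero element count", pos + len(symbol))
        counts[symbol] = int(digits) if digits else 1
        pos = m.end()
    return counts


def _derive_atom_elements(element_counts: dict[str, int]) -> dict[int, str]:
    """InChI canonical numbering convention: carbons 1..n_C, remaining heavy
    elements alphabetical; hydrogens unnumbered."""
    out: dict[int, str] = {}
    n = 0
    heavy = {s: c for s, c in element_counts.items() if s != "H"}
    ordered: list[str] = []
    if "C" in heavy:
        ordered.append("C")
    ordered.extend(sorted(s for s in heavy if s != "C"))
    for symbol in ordered:
        for _ in range(heavy[symbol]):
            n += 1
            out[n] = symbol
    return out


def _parse_h_layer(content: str) -> tuple[dict[int, int], tuple[tuple[int, tuple[int, ...]], ...]]:
    """Extract per-atom fixed hydrogen counts and mobile-H groups from a
    standard ``/h`` layer (e.g. ``"2-11H,1H2"``, ``"1H3,(H,3,4)"``).

    Lenient: an unrecognized construct yields empty maps rather than a parse
    failure, since the layer is retained opaquely regardless and hydrogen
    capacities are only needed for semantic checks and counting.
    """
    fixed: dict[int, int] = {}
    mobile: list[tuple[int, tuple[int, ...]]] = []
    # split on commas outside parentheses
    items: list[str] = []
    depth = 0
    cur = ""
    for ch in content:
        if ch == "," and depth == 0:
            items.append(cur)
            cur = ""
        else:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            cur += ch
    items.append(cur)

    pending: list[int] = []

    def expand(token: str) -> Optional[list[int]]:
        m = re.match(r"^(\d+)(?:-(\d+))?$", token)
        if not m:
            return None
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            return None
        return list(range(lo, hi + 1))

    for item in items:
        pm = _H_LAYER_MOBILE.match(item)
        if pm:
            count = int(pm.group(1)) if pm.group(1) else 1
            atoms = tuple(int(a) for a in pm.group(2).split(","))
            mobile.append((count, atoms))
            continue
        m = re.match(r"^(\d+(?:-\d+)?)H(\d*)$", item)
        if m:
            atoms = expand(m.group(1))
            if atoms is None:
                return {}, ()
            count = int(m.group(2)) if m.group(2) else 1
            for a in pending + atoms:
                fixed[a] = fixed.get(a, 0) + count
            pending = []
            continue
        atoms = expand(item)
        if atoms is None:
            return {}, ()
        pending.extend(atoms)
    if pending:
        return {}, ()
    return fixed, tuple(mobile)


@dataclass
class SkeletonInChI:
    """The standard-InChI core: formula plus opaquely retained layers.

    ``formula_only`` marks truncated strings (formula + isotopologue layer
    with no structural layers), used when the constitutional isomer is
    unknown; such strings carry no atom numbering.
    """

    version_prefix: str
    formula_text: str
    retained_layers: tuple[str, ...] = ()
    formula_only: bool = False
    element_counts: dict[str, int] = field(default_factory=dict)
    atom_elements: dict[int, str] = field(default_factory=dict)
    fixed_h: dict[int, int] = field(default_factory=dict)
    mobile_h_groups: tuple[tuple[int, tuple[int, ...]], ...] = ()

    @classmethod
    def from_formula(cls, version: str, formula_text: str,
                     retained_layers: tuple[str, ...] = (),
                     formula_only: bool = False) -> "SkeletonInChI":
        counts = parse_formula(formula_text)
        atom_elements = {} if formula_only else _derive_atom_elements(counts)
        fixed_h: dict[int, int] = {}
        mobile: tuple[tuple[int, tuple[int, ...]], ...] = ()
        for layer in retained_layers:
            if layer.startswith("h"):
                fixed_h, mobile = _parse_h_layer(layer[1:])
                break
        return cls(
            version_prefix=version,
            formula_text=formula_text,
            retained_layers=retained_layers,
            formula_only=formula_only,
            element_counts=counts,
            atom_elements=atom_elements,
            fixed_h=fixed_h,
            mobile_h_groups=mobile,
        )

    @property
    def n_heavy_atoms(self) -> int:
        return sum(c for s, c in self.element_counts.items() if s != "H")

    @property
    def n_hydrogens(self) -> int:
        return self.element_counts.get("H", 0)

    def atoms_of(self, element: str) -> tuple[int, ...]:
        return tuple(a for a, e in self.atom_elements.items() if e == element)

    def h_bearers(self) -> tuple[int, ...]:
        """Heavy atoms carrying fixed hydrogens, ascending."""
        return tuple(sorted(a for a, c in self.fixed_h.items() if c > 0))


@dataclass
class AtomIsotopeSpec:
    """One ``/i`` entry: atom number with an optional mass-shift designation
    (0 is legal and means 'explicitly the default isotope') and/or explicit
    attached hydrogen-isotope counts keyed 1=protium, 2=deuterium, 3=tritium."""

    atom_number: int
    mass_shift: Optional[int] = None
    h_counts: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.atom_number < 1:
            raise InChIEmitError(f"atom number must be >= 1, got {self.atom_number}")
        if self.mass_shift is None and not self.h_counts:
            raise InChIEmitError(f"entry for atom {self.atom_number} specifies nothing")
        if any(c < 1 for c in self.h_counts.values()):
            raise InChIEmitError("hydrogen isotope counts must be >= 1")
        if any(k not in (1, 2, 3) for k in self.h_counts):
            raise InChIEmitError("hydrogen isotope keys must be 1, 2 or 3")


@dataclass
class IsotopologueGroup:
    """One parenthesized ``/a`` group.

    ``kind == "isotope"``: ``count`` atoms of ``element`` carry the isotope
    designated by ``shift``; ``kind == "neutron"``: ``count`` extra neutrons
    relative to the most abundant stable isotopes.  ``candidate_atoms``
    restricts the ambiguity to listed atoms (a fragment); for hydrogen
    groups the candidates name bearer heavy atoms.
    """

    kind: str  # "isotope" | "neutron"
    count: int
    element: Optional[str] = None
    shift: Optional[int] = None
    candidate_atoms: Optional[tuple[int, ...]] = None

    def check(self) -> None:
        if self.kind not in ("isotope", "neutron"):
            raise InChIEmitError(f"unknown group kind {self.kind!r}")
        if self.count < 1:
            raise InChIEmitError("group count must be >= 1")
        if self.kind == "isotope" and (self.element is None or self.shift is None):
            raise InChIEmitError("isotope group needs element and shift")
        if self.kind == "neutron" and (self.element is not None or self.shift is not None):
            raise InChIEmitError("neutron group carries no element/shift")
        if self.candidate_atoms is not None:
            atoms = self.candidate_atoms
            if not atoms:
                raise InChIEmitError("empty candidate atom list")
            if any(b <= a for a, b in zip(atoms, atoms[1:])):
                raise InChIEmitError("candidate atom list must be strictly increasing")
            if self.kind == "isotope" and self.element != "H" and self.count > len(atoms):
                raise InChIEmitError("isotope count exceeds candidate list size")


@dataclass
class ExtendedInChI:
    """Parsed model of an extended InChI string."""

    skeleton: SkeletonInChI
    isotopic_layer: tuple[AtomIsotopeSpec, ...] = ()
    exchangeable_h: dict[int, int] = field(default_factory=dict)
    isotopologue_layer: tuple[IsotopologueGroup, ...] = ()

    @property
    def has_isotopic(self) -> bool:
        return bool(self.isotopic_layer) or bool(self.exchangeable_h)

    @property
    def has_isotopologue(self) -> bool:
        return bool(self.isotopologue_layer)


def _parse_i_layer(content: str, offset: int) -> tuple[AtomIsotopeSpec, ...]:
    if not content:
        return ()
    entries = []
    pos = offset
    for token in content.split(","):
        m = _I_ENTRY.match(token)
        if not m or (m.group(2) is None and not m.group(3)):
            raise InChIParseError(f"malformed isotopic-layer entry {token!r}", pos)
        atom = int(m.group(1))
        shift = int(m.group(2)) if m.group(2) is not None else None
        h_counts: dict[int, int] = {}
        for letter, digits in _H_TOKEN.findall(m.group(3)):
            iso = _H_LETTER_TO_ISO[letter]
            n = int(digits) if digits else 1
            if n < 1:
                raise InChIParseError(f"zero hydrogen count in {token!r}", pos)
            h_counts[iso] = h_counts.get(iso, 0) + n
        entries.append(AtomIsotopeSpec(atom_number=atom, mass_shift=shift, h_counts=h_counts))
        pos += len(token) + 1
    return tuple(entries)


def _parse_exchangeable(content: str, offset: int) -> dict[int, int]:
    if not content or not re.fullmatch(r"(?:[HDT]\d*)+", content):
        raise InChIParseError(f"malformed exchangeable-hydrogen sublayer {content!r}", offset)
    out: dict[int, int] = {}
    for letter, digits in _H_TOKEN.findall(content):
        iso = _H_LETTER_TO_ISO[letter]
        out[iso] = out.get(iso, 0) + (int(digits) if digits else 1)
    return out


def _parse_candidates(text: Optional[str], offset: int) -> Optional[tuple[int, ...]]:
    if text is None:
        return None
    atoms = tuple(int(a) for a in text.split(","))
    if any(b <= a for a, b in zip(atoms, atoms[1:])):
        raise InChIParseError("candidate atom list must be strictly increasing", offset)
    return atoms


def _parse_a_layer(content: str, offset: int) -> tuple[IsotopologueGroup, ...]:
    if not content:
        raise InChIParseError("empty isotopologue layer", offset)
    if not re.fullmatch(r"(?:\([^()]*\))+", content):
        raise InChIParseError("isotopologue layer must be parenthesized groups", offset)
    groups = []
    pos = offset
    for inner in re.findall(r"\(([^()]*)\)", content):
        m = _A_NEUTRON_GROUP.match(inner)
        if m:
            groups.append(IsotopologueGroup(
                kind="neutron",
                count=int(m.group(1)),
                candidate_atoms=_parse_candidates(m.group(2), pos),
            ))
        else:
            m = _A_ISOTOPE_GROUP.match(inner)
            if not m:
                raise InChIParseError(f"malformed isotopologue group ({inner!r})", pos)
            element = m.group(1)
            if element not in ELEMENT_SYMBOLS:
                raise InChIParseError(f"unknown element symbol {element!r}", pos)
            groups.append(IsotopologueGroup(
                kind="isotope",
                element=element,
                count=int(m.group(2)),
                shift=int(m.group(3)),
                candidate_atoms=_parse_candidates(m.group(4), pos),
            ))
        g = groups[-1]
        if g.count < 1:
            raise InChIParseError("group count must be >= 1", pos)
        pos += len(inner) + 2
    return tuple(groups)


_MAIN_LAYER_PREFIXES = "chqpbtms"


def parse(text: str) -> ExtendedInChI:
    """Parse an extended (or standard) InChI string into the data model.

    Lossless and purely syntactic: unknown standard layers are retained
    opaquely in order, and all semantic checks are deferred to
    :func:`isoinchi.layer_semantics.validate`.
    """
    if not text.startswith("InChI="):
        raise InChIParseError("InChI string must begin with 'InChI='", 0)
    body = text[len("InChI="):]
    if not body or "/" not in body:
        raise InChIParseError("missing molecular formula layer", len("InChI="))
    segments = body.split("/")
    version = segments[0]
    if not version:
        raise InChIParseError("empty version prefix", len("InChI="))
    formula_text = segments[1]
    if "." in formula_text or "*" in formula_text:
        raise InChIParseError("multi-component formulas are not supported", len("InChI=") + len(version) + 1)
    parse_formula(formula_text)  # syntax check; counts derived in skeleton

    retained: list[str] = []
    isotopic: tuple[AtomIsotopeSpec, ...] = ()
    exchangeable: dict[int, int] = {}
    groups: tuple[IsotopologueGroup, ...] = ()
    seen_i = seen_a = False
    fixed_scope = False

    offset = len("InChI=") + len(version) + 1 + len(formula_text)
    idx = 2
    while idx < len(segments):
        seg = segments[idx]
        offset += 1  # the slash
        if not seg:
            raise InChIParseError("empty layer", offset)
        prefix = seg[0]
        if fixed_scope:
            retained.append(seg)
        elif prefix in "fr":
            # fixed-H / reconnected scope: everything from here on is opaque
            fixed_scope = True
            retained.append(seg)
        elif prefix == "i":
            if seen_i:
                raise InChIParseError("duplicate isotopic layer", offset)
            seen_i = True
            isotopic = _parse_i_layer(seg[1:], offset + 1)
            if idx + 1 < len(segments) and segments[idx + 1].startswith("h"):
                nxt = segments[idx + 1]
                exchangeable = _parse_exchangeable(nxt[1:], offset + len(seg) + 2)
                offset += len(seg) + 1
                idx += 1
                seg = nxt
        elif prefix == "a":
            if seen_a:
                raise InChIParseError("duplicate isotopologue layer", offset)
            seen_a = True
            groups = _parse_a_layer(seg[1:], offset + 1)
        else:
            retained.append(seg)
        offset += len(seg)
        idx += 1

    formula_only = not retained and not seen_i
    skeleton = SkeletonInChI.from_formula(
        version, formula_text, tuple(retained), formula_only=formula_only
    )
    return ExtendedInChI(
        skeleton=skeleton,
        isotopic_layer=isotopic,
        exchangeable_h=exchangeable,
        isotopologue_layer=groups,
    )


def _h_tokens(h_counts: dict[int, int]) -> str:
    parts = []
    for iso in (1, 2, 3):
        n = h_counts.get(iso, 0)
        if n:
            parts.append(_ISO_TO_H_LETTER[iso] + (str(n) if n > 1 else ""))
    return "".join(parts)


def _group_sort_key(g: IsotopologueGroup):
    if g.kind == "isotope":
        el_key = (0, "") if g.element == "C" else (1, g.element)
        return (0, el_key, g.shift, g.candidate_atoms or ())
    return (1, (0, ""), g.count, g.candidate_atoms or ())


def _full_candidate_set(skeleton: SkeletonInChI, g: IsotopologueGroup) -> Optional[frozenset[int]]:
    """The atom set a list-free group ranges over; None when unknown."""
    if skeleton.formula_only:
        return None
    if g.kind == "neutron":
        return frozenset(skeleton.atom_elements)
    if g.element == "H":
        bearers = set(skeleton.h_bearers())
        for _, atoms in skeleton.mobile_h_groups:
            bearers.update(atoms)
        return frozenset(bearers) if bearers else None
    return frozenset(skeleton.atoms_of(g.element))


def emit(model: ExtendedInChI) -> str:
    """Serialize a model to its canonical extended-InChI text.

    Refuses (raises :class:`InChIEmitError`) when a type invariant is
    violated.  A candidate list equal to the full atom set of its element is
    dropped; entries and groups are emitted in canonical order.
    """
    sk = model.skeleton
    n_heavy = sk.n_heavy_atoms

    def check_atoms(atoms: Iterable[int], what: str) -> None:
        for a in atoms:
            if not 1 <= a <= n_heavy:
                raise InChIEmitError(f"{what}: atom number {a} outside 1..{n_heavy}")

    for entry in model.isotopic_layer:
        entry.check()
        check_atoms([entry.atom_number], "isotopic layer")
    if sk.formula_only and (model.isotopic_layer or model.exchangeable_h):
        raise InChIEmitError("formula-only string cannot carry an isotopic layer")
    for g in model.isotopologue_layer:
        g.check()
        if g.candidate_atoms is not None:
            if sk.formula_only:
                raise InChIEmitError("formula-only string cannot reference atom numbers")
            check_atoms(g.candidate_atoms, "isotopologue layer")

    parts = ["InChI=", sk.version_prefix, "/", sk.formula_text]
    for layer in sk.retained_layers:
        parts.append("/" + layer)

    if model.isotopic_layer or model.exchangeable_h:
        entries = sorted(model.isotopic_layer, key=lambda e: e.atom_number)
        text = ",".join(
            str(e.atom_number)
            + (f"{e.mass_shift:+d}" if e.mass_shift is not None else "")
            + _h_tokens(e.h_counts)
            for e in entries
        )
        parts.append("/i" + text)
        if model.exchangeable_h:
            parts.append("/h" + _h_tokens(model.exchangeable_h))

    if model.isotopologue_layer:
        rendered = []
        for g in sorted(model.isotopologue_layer, key=_group_sort_key):
            candidates = g.candidate_atoms
            if candidates is not None:
                full = _full_candidate_set(sk, g)
                if full is not None and frozenset(candidates) == full:
                    candidates = None
            tail = "," + ",".join(str(a) for a in candidates) if candidates else ""
            if g.kind == "isotope":
                rendered.append(f"({g.element}{g.count}{g.shift:+d}{tail})")
            else:
                rendered.append(f"({g.count}n{tail})")
        parts.append("/a" + "".join(rendered))

    return "".join(parts)


def atom_element_map(skeleton: SkeletonInChI) -> dict[int, str]:
    """Atom-number -> element mapping (carbons first, heteroatoms
    alphabetical; hydrogens unnumbered).  Empty for formula-only inputs."""
    return dict(skeleton.atom_elements)
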