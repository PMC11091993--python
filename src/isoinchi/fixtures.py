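"""Seeded synthetic corpus generator for the extended-InChI toolchain.

Builds extended InChI strings over a pool of small metabolite skeletons
(ethane, propane, water, acetate, glycerol, alpha-D-glucopyranose,
glucosamine 6-phosphate) whose standard InChI strings are vendored
verbatim — canonical numbering is taken from the string, never computed.
Each fixture carries by-construction ground truth (taxonomy category,
expected isotopomer count where the construction determines one, expected
validation findings), so the generator doubles as the test oracle for the
classifier, validator and counter.  Identical specs give bit-identical
corpora.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from typing import IO, Optional

from .inchi_codec import (
    AtomIsotopeSpec,
    ExtendedInChI,
    IsotopologueGroup,
    SkeletonInChI,
    emit,
    parse,
)

__all__ = ["MOLECULE_POOL", "FixtureSpec", "Fixture", "generate_fixtures", "write_corpus"]

# Standard InChI strings, cross-checked once against the reference
# implementation and vendored as constants (canonicalization is out of
# scope for this package).
MOLECULE_POOL: dict[str, str] = {
    "ethane": "InChI=1S/C2H6/c1-2/h1-2H3",
    "propane": "InChI=1S/C3H8/c1-3-2/h3H2,1-2H3",
    "water": "InChI=1S/H2O/h1H2",
    "acetate": "InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)",
    "glycerol": "InChI=1S/C3H8O3/c4-1-3(6)2-5/h3-6H,1-2H2",
    "alpha_d_glucopyranose":
        "InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2/t2-,3-,4+,5-,6+/m1/s1",
    "glucosamine_6_phosphate":
        "InChI=1S/C6H14NO8P/c7-3-5(9)4(8)2(15-6(3)10)1-14-16(11,12)13"
        "/h2-6,8-10H,1,7H2,(H2,11,12,13)/t2-,3-,4-,5-,6+/m1/s1",
}

# designations with tabulated stable nuclides, per element
_SHIFT_CHOICES = {"C": (0, 1), "N": (0, 1), "O": (0, 1, 2), "P": (0,), "S": (0, 1, 2)}

_KINDS = (
    "unlabeled",
    "exact_isotopomer",
    "partial_isotopomer",
    "isotopologue",
    "isotopologue_fragment",
    "nominal_mass_isotopologue",
    "nominal_mass_fragment",
    "formula_only_isotopologue",
    "r3_boundary",
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n: int = 100
    molecule_pool: tuple[str, ...] = tuple(MOLECULE_POOL)
    category_weights: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in _KINDS})
    max_isotope_count: int = 3
    max_neutron_count: int = 4


@dataclass(frozen=True)
class Fixture:
    inchi: str
    molecule: str
    category: Optional[str]          # None for deliberately invalid strings
    expected_count: Optional[int]    # None when not determined by construction
    expected_findings: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _bounded_count(caps: list[int], k: int) -> int:
    """Ground-truth bounded-composition count, by direct recursion."""
    if k == 0:
        return 1
    if not caps:
        return 0
    return sum(_bounded_count(caps[1:], k - t) for t in range(min(caps[0], k) + 1))


def _h_capacities(sk: SkeletonInChI) -> list[int]:
    caps = [c for c in sk.fixed_h.values() if c > 0]
    mobile = sum(c for c, _ in sk.mobile_h_groups)
    if mobile:
        caps.append(mobile)
    return caps


class _Builder:
    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.skeletons = {name: parse(MOLECULE_POOL[name]) for name in spec.molecule_pool}

    def _choose_molecule(self) -> tuple[str, ExtendedInChI]:
        name = self.rng.choice(sorted(self.skeletons))
        return name, self.skeletons[name]

    def build(self, kind: str) -> Optional[Fixture]:
        maker = getattr(self, "_make_" + kind)
        for _ in range(20):
            fx = maker()
            if fx is not None:
                return fx
        return None

    # -- construction per kind ------------------------------------------------

    def _make_unlabeled(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        return Fixture(emit(x), name, "unlabeled", 1)

    def _make_exact_isotopomer(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        rng = self.rng
        entries = []
        for a in sorted(sk.atom_elements):
            el = sk.atom_elements[a]
            shift = rng.choice(_SHIFT_CHOICES.get(el, (0,)))
            h: dict[int, int] = {}
            cap = sk.fixed_h.get(a, 0)
            if cap:
                d = rng.randint(0, cap)
                if d:
                    h[2] = d
                if cap - d:
                    h[1] = cap - d
            entries.append(AtomIsotopeSpec(a, shift, h))
        exch: dict[int, int] = {}
        mobile = sum(c for c, _ in sk.mobile_h_groups)
        if mobile:
            d = rng.randint(0, mobile)
            if d:
                exch[2] = d
            if mobile - d:
                exch[1] = mobile - d
        model = ExtendedInChI(sk, tuple(entries), exch, ())
        return Fixture(emit(model), name, "exact_isotopomer", 1)

    def _make_partial_isotopomer(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        rng = self.rng
        atoms = sorted(sk.atom_elements)
        if len(atoms) < 2:
            # single heavy atom: a partial isotopomer needs unassigned content;
            # pin nothing heavy, mark one hydrogen instead
            cap = sk.fixed_h.get(atoms[0], 0)
            if cap < 2:
                return None
            d = rng.randint(1, cap - 1)
            model = ExtendedInChI(sk, (AtomIsotopeSpec(atoms[0], None, {2: d}),), {}, ())
            return Fixture(emit(model), name, "partial_isotopomer", 1)
        k = rng.randint(1, len(atoms) - 1)
        chosen = sorted(rng.sample(atoms, k))
        entries = []
        for a in chosen:
            el = sk.atom_elements[a]
            entries.append(AtomIsotopeSpec(a, rng.choice(_SHIFT_CHOICES.get(el, (0,))), {}))
        model = ExtendedInChI(sk, tuple(entries), {}, ())
        return Fixture(emit(model), name, "partial_isotopomer", 1)

    def _ambiguous_element(self, sk: SkeletonInChI, min_atoms: int) -> Optional[str]:
        ok = [el for el in sorted(set(sk.atom_elements.values()))
              if len(sk.atoms_of(el)) >= min_atoms and el in _SHIFT_CHOICES
              and any(s > 0 for s in _SHIFT_CHOICES[el])]
        return self.rng.choice(ok) if ok else None

    def _make_isotopologue(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        rng = self.rng
        if rng.random() < 0.3:
            # hydrogen group: k heavy hydrogens somewhere among the bearers
            caps = _h_capacities(sk)
            total = sum(caps)
            if total < 2:
                return None
            k = rng.randint(1, min(total - 1, self.spec.max_isotope_count))
            g = IsotopologueGroup("isotope", k, "H", 1)
            model = ExtendedInChI(sk, (), {}, (g,))
            return Fixture(emit(model), name, "isotopologue", _bounded_count(caps, k))
        el = self._ambiguous_element(sk, 2)
        if el is None:
            return None
        n_atoms = len(sk.atoms_of(el))
        shift = rng.choice([s for s in _SHIFT_CHOICES[el] if s > 0])
        k = rng.randint(1, min(n_atoms - 1, self.spec.max_isotope_count))
        g = IsotopologueGroup("isotope", k, el, shift)
        model = ExtendedInChI(sk, (), {}, (g,))
        return Fixture(emit(model), name, "isotopologue", math.comb(n_atoms, k))

    def _make_isotopologue_fragment(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        rng = self.rng
        el = self._ambiguous_element(sk, 3)
        if el is None:
            return None
        atoms = sorted(sk.atoms_of(el))
        size = rng.randint(2, len(atoms) - 1)
        subset = tuple(sorted(rng.sample(atoms, size)))
        shift = rng.choice([s for s in _SHIFT_CHOICES[el] if s > 0])
        k = rng.randint(1, min(size - 1, self.spec.max_isotope_count))
        g = IsotopologueGroup("isotope", k, el, shift, subset)
        model = ExtendedInChI(sk, (), {}, (g,))
        return Fixture(emit(model), name, "isotopologue_fragment", math.comb(size, k))

    def _make_nominal_mass_isotopologue(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        n = self.rng.randint(1, self.spec.max_neutron_count)
        model = ExtendedInChI(sk, (), {}, (IsotopologueGroup("neutron", n),))
        return Fixture(emit(model), name, "nominal_mass_isotopologue", None)

    def _make_nominal_mass_fragment(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        rng = self.rng
        atoms = sorted(sk.atom_elements)
        if len(atoms) < 3:
            return None
        size = rng.randint(2, len(atoms) - 1)
        subset = tuple(sorted(rng.sample(atoms, size)))
        # neutron budget achievable within the subset via 13C/15N/17O/18O/33S...
        budget = 0
        for a in subset:
            el = sk.atom_elements[a]
            budget += max(_SHIFT_CHOICES.get(el, (0,)))
        if budget < 1:
            return None
        n = rng.randint(1, min(budget, self.spec.max_neutron_count))
        model = ExtendedInChI(sk, (), {}, (IsotopologueGroup("neutron", n, None, None, subset),))
        return Fixture(emit(model), name, "nominal_mass_fragment", None)

    def _make_formula_only_isotopologue(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        rng = self.rng
        bare = SkeletonInChI.from_formula(sk.version_prefix, sk.formula_text,
                                          formula_only=True)
        if rng.random() < 0.5:
            el = self._ambiguous_element(sk, 1)
            if el is None:
                return None
            total = len(sk.atoms_of(el))
            shift = rng.choice([s for s in _SHIFT_CHOICES[el] if s > 0])
            k = rng.randint(1, min(total, self.spec.max_isotope_count))
            g = IsotopologueGroup("isotope", k, el, shift)
        else:
            g = IsotopologueGroup("neutron", rng.randint(1, self.spec.max_neutron_count))
        model = ExtendedInChI(bare, (), {}, (g,))
        return Fixture(emit(model), name, "formula_only_isotopologue", None)

    def _make_r3_boundary(self) -> Optional[Fixture]:
        name, x = self._choose_molecule()
        sk = x.skeleton
        rng = self.rng
        choices = [el for el in sorted(set(sk.atom_elements.values()))
                   if el in _SHIFT_CHOICES and any(s > 0 for s in _SHIFT_CHOICES[el])]
        if not choices:
            return None
        el = rng.choice(choices)
        atoms = sorted(sk.atoms_of(el))
        shift = rng.choice([s for s in _SHIFT_CHOICES[el] if s > 0])
        if len(atoms) >= 2 and rng.random() < 0.5:
            size = rng.randint(1, len(atoms) - 1)
            subset = tuple(sorted(rng.sample(atoms, size)))
            g = IsotopologueGroup("isotope", size, el, shift, subset)
        else:
            g = IsotopologueGroup("isotope", len(atoms), el, shift)
        model = ExtendedInChI(sk, (), {}, (g,))
        return Fixture(emit(model), name, None, None, ("R3",))


def generate_fixtures(spec: FixtureSpec) -> list[Fixture]:
    """Generate ``spec.n`` distinct fixtures; bit-reproducible per spec.

    Kinds are drawn by ``category_weights``; a kind infeasible for the
    drawn molecule is retried, and duplicate strings are rejected so the
    corpus is collision-free.
    """
    weights = {k: w for k, w in spec.category_weights.items() if w > 0}
    if not weights or any(w < 0 for w in spec.category_weights.values()):
        raise ValueError("category weights must be nonnegative and not all zero")
    builder = _Builder(spec)
    kinds = sorted(weights)
    wvals = [weights[k] for k in kinds]
    out: list[Fixture] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = max(200, 60 * spec.n)
    while len(out) < spec.n and attempts < max_attempts:
        attempts += 1
        kind = builder.rng.choices(kinds, weights=wvals, k=1)[0]
        fx = builder.build(kind)
        if fx is None or fx.inchi in seen:
            continue
        seen.add(fx.inchi)
        out.append(fx)
    if len(out) < spec.n:
        raise RuntimeError(
            f"could only generate {len(out)} distinct fixtures of {spec.n} requested"
        )
    return out


def write_corpus(fixtures: list[Fixture], stream: IO[str], seed: int) -> None:
    """Write a corpus as TSV with a seed header line."""
    stream.write(f"# seed={seed}\n")
    stream.write("inchi\tground_truth\n")
    for fx in fixtures:
        stream.write(f"{fx.inchi}\t{fx.to_json()}\n")
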