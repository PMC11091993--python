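"""Semantic rules over parsed extended InChI strings.

Three concerns live here:

* :func:`classify` — place a string in the isotopic taxonomy: unlabeled,
  exact/partial isotopomer (``/i`` under the interpretation that
  unspecified atoms are *unknown*), isotopologue vs isotopologue fragment
  (``/a`` with/without a restricting candidate list), the nominal-mass
  variants (neutron-count groups), and formula-only isotopologues.
* :func:`validate` — rule codes R1–R8 covering atom-number ranges,
  element/candidate agreement, the ambiguity boundary (an isotopologue
  group that actually pins every candidate atom belongs in ``/i``),
  formula-only restrictions, joint ``/i``+``/a`` consistency, and neutron
  feasibility.  Findings are data; boundary violations carry a suggested
  rewrite so pipelines can run strict or fix-up.
* :func:`normalize` / :func:`semantic_equal` — canonical semantic form:
  redundant candidate lists dropped, equal groups merged, boundary groups
  demoted into ``/i``; equality is normalize-then-compare, which matches
  isotopomer-set equality (checked against the enumeration machinery in
  the test-suite).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .inchi_codec import (
    AtomIsotopeSpec,
    ExtendedInChI,
    IsotopologueGroup,
    SkeletonInChI,
    emit,
)
from .isotope_data import NuclideTable, default_table

__all__ = [
    "Category",
    "IsotopicClassification",
    "Finding",
    "ValidationReport",
    "classify",
    "validate",
    "normalize",
    "semantic_equal",
    "MOBILE_SITE",
]

# Pseudo-site key for the pooled exchangeable/mobile hydrogens; real bearer
# atoms are numbered from 1.
MOBILE_SITE = 0


class Category(str, Enum):
    UNLABELED = "unlabeled"
    EXACT_ISOTOPOMER = "exact_isotopomer"
    PARTIAL_ISOTOPOMER = "partial_isotopomer"
    ISOTOPOLOGUE = "isotopologue"
    ISOTOPOLOGUE_FRAGMENT = "isotopologue_fragment"
    NOMINAL_MASS_ISOTOPOLOGUE = "nominal_mass_isotopologue"
    NOMINAL_MASS_FRAGMENT = "nominal_mass_fragment"
    FORMULA_ONLY_ISOTOPOLOGUE = "formula_only_isotopologue"


@dataclass(frozen=True)
class IsotopicClassification:
    category: Category
    # Set when deuterium/tritium entries coexist with an absent or incomplete
    # stereo description: the heavy hydrogen may then sit on either prochiral
    # position, so the string technically denotes an isotopologue(-fragment).
    stereo_ambiguity_flag: bool = False


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    rule_code: str  # "R1".."R8"
    message: str
    location: str  # layer + token index, e.g. "a[0]"


@dataclass
class ValidationReport:
    findings: tuple[Finding, ...] = ()
    suggested_rewrite: Optional[ExtendedInChI] = None

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def errors(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity == "error")

    def rule_codes(self) -> tuple[str, ...]:
        return tuple(f.rule_code for f in self.findings)

    def to_dict(self) -> dict:
        d = {
            "findings": [dataclasses.asdict(f) for f in self.findings],
        }
        if self.suggested_rewrite is not None:
            d["suggested_rewrite"] = emit(self.suggested_rewrite)
        return d


# ---------------------------------------------------------------------------
# shared helpers: pinned atoms, effective candidate sets, hydrogen capacities
# ---------------------------------------------------------------------------

def pinned_atoms(x: ExtendedInChI) -> frozenset[int]:
    """Heavy atoms whose isotope is fixed by an ``/i`` mass-shift entry."""
    return frozenset(e.atom_number for e in x.isotopic_layer if e.mass_shift is not None)


def h_site_capacities(x: ExtendedInChI) -> dict[int, int]:
    """Residual hydrogen capacity per site after explicit ``/i`` assignments.

    Sites are bearer heavy atoms (fixed hydrogens) plus :data:`MOBILE_SITE`,
    a single pooled site holding all mobile/exchangeable hydrogens — labile
    hydrogens interchange, so positions inside the pool are not distinct.
    """
    sk = x.skeleton
    explicit: dict[int, int] = {}
    for e in x.isotopic_layer:
        explicit[e.atom_number] = explicit.get(e.atom_number, 0) + sum(e.h_counts.values())
    caps: dict[int, int] = {}
    for atom, c in sk.fixed_h.items():
        caps[atom] = c - explicit.get(atom, 0)
    mobile_total = sum(c for c, _ in sk.mobile_h_groups)
    if mobile_total:
        caps[MOBILE_SITE] = mobile_total - sum(x.exchangeable_h.values())
    return caps


def effective_candidates(x: ExtendedInChI, g: IsotopologueGroup) -> tuple[int, ...]:
    """The atoms (or hydrogen sites) a group's ambiguity actually ranges over.

    Explicit candidate lists are taken as-is; a list-free group ranges over
    every atom of its element not pinned in ``/i`` (for hydrogen: every site
    with residual capacity; for neutron groups: every unpinned heavy atom,
    with hydrogen handled through site capacities by the callers).
    """
    sk = x.skeleton
    if g.candidate_atoms is not None:
        return tuple(g.candidate_atoms)
    pinned = pinned_atoms(x)
    if g.kind == "neutron":
        return tuple(a for a in sorted(sk.atom_elements) if a not in pinned)
    if g.element == "H":
        caps = h_site_capacities(x)
        return tuple(sorted(s for s, c in caps.items() if c > 0))
    return tuple(a for a in sorted(sk.atoms_of(g.element)) if a not in pinned)


def h_group_capacity(x: ExtendedInChI, g: IsotopologueGroup) -> int:
    """Total residual hydrogen capacity over a hydrogen group's candidates."""
    caps = h_site_capacities(x)
    if g.candidate_atoms is not None:
        return sum(max(caps.get(a, 0), 0) for a in g.candidate_atoms)
    return sum(c for c in caps.values() if c > 0)


def _max_neutron_excess(sk: SkeletonInChI, candidates: Optional[tuple[int, ...]],
                        h_capacity: int, table: NuclideTable) -> int:
    """Largest neutron excess achievable with stable isotopes."""
    total = 0
    atoms = candidates if candidates is not None else tuple(sk.atom_elements)
    for a in atoms:
        el = sk.atom_elements.get(a)
        if el is None or el not in table:
            continue
        rec = table.element(el)
        total += max(
            i.mass_number - rec.most_abundant_mass_number for i in rec.stable_isotopes
        )
    if candidates is None and "H" in table:
        rec = table.element("H")
        best = max(i.mass_number - rec.most_abundant_mass_number for i in rec.stable_isotopes)
        total += h_capacity * best
    return total


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _has_heavy_hydrogen(x: ExtendedInChI) -> bool:
    for e in x.isotopic_layer:
        if any(k in (2, 3) and v > 0 for k, v in e.h_counts.items()):
            return True
    return any(k in (2, 3) and v > 0 for k, v in x.exchangeable_h.items())


def _is_exact(x: ExtendedInChI) -> bool:
    sk = x.skeleton
    if sk.formula_only:
        return False
    shifted = pinned_atoms(x)
    if set(sk.atom_elements) - shifted:
        return False
    explicit_h = sum(sum(e.h_counts.values()) for e in x.isotopic_layer)
    explicit_h += sum(x.exchangeable_h.values())
    return explicit_h == sk.n_hydrogens


def _restricting_lists_present(x: ExtendedInChI) -> bool:
    """True when any group carries a candidate list that is a *proper*
    restriction — a list covering every atom the group would range over
    anyway is semantically absent."""
    for g in x.isotopologue_layer:
        if g.candidate_atoms is None:
            continue
        implicit = frozenset(effective_candidates(
            x, dataclasses.replace(g, candidate_atoms=None)))
        if frozenset(g.candidate_atoms) != implicit:
            return True
    return False


def classify(x: ExtendedInChI) -> IsotopicClassification:
    """Classify a *valid* string into the isotopic taxonomy.

    Raises ``ValueError`` when the string has error-severity validation
    findings — validate first.
    """
    report = validate(x, _with_rewrite=False)
    if report.errors:
        raise ValueError(
            "classification refused for invalid string: "
            + "; ".join(f"{f.rule_code}: {f.message}" for f in report.errors)
        )
    sk = x.skeleton
    stereo_flag = _has_heavy_hydrogen(x) and not any(
        layer.startswith("t") for layer in sk.retained_layers
    )
    if sk.formula_only:
        if x.has_isotopologue:
            return IsotopicClassification(Category.FORMULA_ONLY_ISOTOPOLOGUE, stereo_flag)
        return IsotopicClassification(Category.UNLABELED, stereo_flag)
    if x.has_isotopologue:
        fragment = _restricting_lists_present(x)
        if any(g.kind == "neutron" for g in x.isotopologue_layer):
            cat = Category.NOMINAL_MASS_FRAGMENT if fragment else Category.NOMINAL_MASS_ISOTOPOLOGUE
        else:
            cat = Category.ISOTOPOLOGUE_FRAGMENT if fragment else Category.ISOTOPOLOGUE
        return IsotopicClassification(cat, stereo_flag)
    if x.has_isotopic:
        if _is_exact(x):
            return IsotopicClassification(Category.EXACT_ISOTOPOMER, stereo_flag)
        return IsotopicClassification(Category.PARTIAL_ISOTOPOMER, stereo_flag)
    return IsotopicClassification(Category.UNLABELED, False)


# ---------------------------------------------------------------------------
# validation (rules R1-R8)
# ---------------------------------------------------------------------------

def validate(x: ExtendedInChI, table: NuclideTable | None = None,
             _with_rewrite: bool = True) -> ValidationReport:
    """Apply rules R1–R8; findings are data, never exceptions.

    R1 atom numbers in range; R2 candidate atoms match the group element
    (bearer atoms for hydrogen groups); R3 ambiguity boundary — a group
    whose isotope count equals its effective candidate count is not
    ambiguous and belongs in ``/i`` (error, with a suggested rewrite);
    R4 isotope count must not exceed the candidates/capacity; R5
    formula-only strings must not reference atoms; R6 joint ``/i``+``/a``
    consistency (per-element totals within the formula, pinned atoms
    excluded from candidate sets); R7 neutron counts feasible with stable
    isotopes; R8 no duplicate atom numbers within a layer.
    """
    table = table or default_table()
    sk = x.skeleton
    findings: list[Finding] = []
    n_heavy = sk.n_heavy_atoms
    pinned = pinned_atoms(x)
    caps = h_site_capacities(x)

    def err(code: str, msg: str, loc: str) -> None:
        findings.append(Finding("error", code, msg, loc))

    def warn(code: str, msg: str, loc: str) -> None:
        findings.append(Finding("warning", code, msg, loc))

    # R5 — formula-only strings carry no atom references
    if sk.formula_only:
        if x.isotopic_layer or x.exchangeable_h:
            err("R5", "formula-only string cannot carry an isotopic layer", "i")
        for gi, g in enumerate(x.isotopologue_layer):
            if g.candidate_atoms is not None:
                err("R5", "formula-only string cannot carry candidate atom lists "
                    "(no atom numbering without a constitution)", f"a[{gi}]")

    # R1 / R8 over the isotopic layer
    seen_atoms: set[int] = set()
    for ei, e in enumerate(x.isotopic_layer):
        loc = f"i[{ei}]"
        if not sk.formula_only and not 1 <= e.atom_number <= n_heavy:
            err("R1", f"atom number {e.atom_number} outside 1..{n_heavy}", loc)
        if e.atom_number in seen_atoms:
            err("R8", f"duplicate atom number {e.atom_number} in isotopic layer", loc)
        seen_atoms.add(e.atom_number)
        if e.h_counts and not sk.formula_only and sk.fixed_h:
            cap = sk.fixed_h.get(e.atom_number, 0)
            if sum(e.h_counts.values()) > cap and e.atom_number in sk.fixed_h:
                err("R6", f"atom {e.atom_number} assigned "
                    f"{sum(e.h_counts.values())} hydrogens but bears {cap}", loc)

    # per-group rules
    r3_present = False
    for gi, g in enumerate(x.isotopologue_layer):
        loc = f"a[{gi}]"
        if g.candidate_atoms is not None and not sk.formula_only:
            for a in g.candidate_atoms:
                if not 1 <= a <= n_heavy:
                    err("R1", f"candidate atom {a} outside 1..{n_heavy}", loc)
                    break
        if g.kind == "isotope" and not sk.formula_only:
            if g.element != "H" and g.element not in sk.element_counts:
                err("R2", f"group element {g.element} not in formula", loc)
                continue
            if g.candidate_atoms is not None:
                if g.element == "H":
                    for a in g.candidate_atoms:
                        bears = sk.fixed_h.get(a, 0) > 0 or any(
                            a in atoms for _, atoms in sk.mobile_h_groups)
                        if not bears:
                            err("R2", f"candidate atom {a} bears no hydrogen", loc)
                else:
                    for a in g.candidate_atoms:
                        if sk.atom_elements.get(a) != g.element:
                            err("R2", f"candidate atom {a} is "
                                f"{sk.atom_elements.get(a, '?')}, not {g.element}", loc)
                # R6: pinned atoms are excluded from candidate sets
                overlap = (set(g.candidate_atoms) & pinned) if g.element != "H" else set()
                if overlap:
                    err("R6", f"candidate atoms {sorted(overlap)} already pinned in /i", loc)
            # R3/R4 against effective candidates
            if g.element == "H":
                capacity = h_group_capacity(x, g)
                if g.count > capacity:
                    err("R4", f"hydrogen isotope count {g.count} exceeds capacity {capacity}", loc)
                elif g.count == capacity:
                    r3_present = True
                    err("R3", "hydrogen isotope count equals the full candidate capacity: "
                        "location is not ambiguous, use the /i layer", loc)
            else:
                cands = effective_candidates(x, g)
                if g.count > len(cands):
                    err("R4", f"isotope count {g.count} exceeds {len(cands)} candidate atoms", loc)
                elif g.count == len(cands):
                    r3_present = True
                    err("R3", f"isotope count {g.count} equals the candidate-atom count: "
                        "location is not ambiguous, use the /i layer", loc)
        elif g.kind == "isotope" and sk.formula_only:
            el_total = sk.element_counts.get(g.element, 0)
            if g.element not in sk.element_counts:
                err("R2", f"group element {g.element} not in formula", loc)
            elif g.count > el_total:
                err("R4", f"isotope count {g.count} exceeds formula count {el_total}", loc)
        elif g.kind == "neutron":
            # R7 — neutron counts achievable with stable isotopes
            if sk.formula_only:
                pseudo = SkeletonInChI.from_formula(sk.version_prefix, sk.formula_text)
                max_n = _max_neutron_excess(pseudo, None, pseudo.element_counts.get("H", 0), table)
            else:
                h_cap = sum(c for c in caps.values() if c > 0)
                max_n = _max_neutron_excess(sk, g.candidate_atoms, h_cap, table)
            if g.count > max_n:
                err("R7", f"neutron count {g.count} exceeds the maximum {max_n} "
                    "achievable with stable isotopes", loc)
            if g.candidate_atoms is not None and (set(g.candidate_atoms) & pinned):
                err("R6", "neutron-group candidate atoms already pinned in /i", loc)
        # R8 within a candidate list is enforced by the grammar (strictly
        # increasing); nothing further to check here.

    # R6 — per-element totals within the formula
    if not sk.formula_only or True:
        totals: dict[str, int] = {}
        for e in x.isotopic_layer:
            if e.mass_shift is not None:
                el = sk.atom_elements.get(e.atom_number)
                if el:
                    totals[el] = totals.get(el, 0) + 1
        h_total = sum(sum(e.h_counts.values()) for e in x.isotopic_layer)
        h_total += sum(x.exchangeable_h.values())
        for g in x.isotopologue_layer:
            if g.kind == "isotope":
                if g.element == "H":
                    h_total += g.count
                else:
                    totals[g.element] = totals.get(g.element, 0) + g.count
        for el, tot in totals.items():
            if tot > sk.element_counts.get(el, 0):
                err("R6", f"{tot} {el} atoms designated but formula has "
                    f"{sk.element_counts.get(el, 0)}", "a")
        if h_total > sk.n_hydrogens:
            err("R6", f"{h_total} hydrogens designated but formula has {sk.n_hydrogens}", "a")

    report = ValidationReport(findings=tuple(findings))
    if (
        _with_rewrite
        and r3_present
        and all(f.rule_code == "R3" for f in report.errors)
    ):
        try:
            report.suggested_rewrite = normalize(x)
        except ValueError:
            pass
    return report


# ---------------------------------------------------------------------------
# normalization and semantic equality
# ---------------------------------------------------------------------------

def _copy(x: ExtendedInChI) -> ExtendedInChI:
    return ExtendedInChI(
        skeleton=x.skeleton,
        isotopic_layer=tuple(
            AtomIsotopeSpec(e.atom_number, e.mass_shift, dict(e.h_counts))
            for e in x.isotopic_layer
        ),
        exchangeable_h=dict(x.exchangeable_h),
        isotopologue_layer=tuple(
            dataclasses.replace(g) for g in x.isotopologue_layer
        ),
    )


def _merge_i_entry(entries: list[AtomIsotopeSpec], atom: int,
                   shift: Optional[int] = None,
                   h_counts: Optional[dict[int, int]] = None) -> None:
    for e in entries:
        if e.atom_number == atom:
            if shift is not None:
                e.mass_shift = shift
            for k, v in (h_counts or {}).items():
                e.h_counts[k] = e.h_counts.get(k, 0) + v
            return
    entries.append(AtomIsotopeSpec(atom, shift, dict(h_counts or {})))


def normalize(x: ExtendedInChI) -> ExtendedInChI:
    """Canonical semantic form: redundant full candidate lists dropped,
    equal groups merged, unambiguous (R3) groups demoted into ``/i``;
    idempotent.  Refuses strings with errors other than R3."""
    report = validate(x, _with_rewrite=False)
    other = [f for f in report.errors if f.rule_code != "R3"]
    if other:
        raise ValueError(
            "normalize refused: " + "; ".join(f"{f.rule_code}: {f.message}" for f in other)
        )

    x = _copy(x)
    sk = x.skeleton

    changed = True
    while changed:
        changed = False
        entries = list(x.isotopic_layer)
        groups: list[IsotopologueGroup] = []

        # pass 1: drop redundant candidate lists
        for g in x.isotopologue_layer:
            if g.candidate_atoms is not None and not sk.formula_only:
                implicit = frozenset(effective_candidates(
                    x, dataclasses.replace(g, candidate_atoms=None)))
                if frozenset(g.candidate_atoms) == implicit:
                    g = dataclasses.replace(g, candidate_atoms=None)
                    changed = True
            groups.append(g)

        # pass 2: merge groups with identical kind/element/shift/candidates
        merged: dict[tuple, IsotopologueGroup] = {}
        for g in groups:
            key = (g.kind, g.element, g.shift, g.candidate_atoms)
            if key in merged:
                merged[key] = dataclasses.replace(
                    merged[key], count=merged[key].count + g.count)
                changed = True
            else:
                merged[key] = g
        groups = list(merged.values())

        # pass 3: demote unambiguous groups into /i
        kept: list[IsotopologueGroup] = []
        for g in groups:
            if g.kind != "isotope" or sk.formula_only:
                kept.append(g)
                continue
            if g.element == "H":
                shift = g.shift if g.shift is not None else 0
                iso = 1 + shift  # H designations: baseline mass number 1
                if iso not in (1, 2, 3):
                    kept.append(g)
                    continue
                probe = ExtendedInChI(sk, tuple(entries), dict(x.exchangeable_h), (g,))
                if g.count == h_group_capacity(probe, g):
                    caps = h_site_capacities(probe)
                    sites = (g.candidate_atoms if g.candidate_atoms is not None
                             else tuple(sorted(s for s, c in caps.items() if c > 0)))
                    for s in sites:
                        c = max(caps.get(s, 0), 0)
                        if c == 0:
                            continue
                        if s == MOBILE_SITE:
                            x.exchangeable_h[iso] = x.exchangeable_h.get(iso, 0) + c
                        else:
                            _merge_i_entry(entries, s, h_counts={iso: c})
                    changed = True
                    continue
                kept.append(g)
            else:
                probe = ExtendedInChI(sk, tuple(entries), dict(x.exchangeable_h), (g,))
                cands = effective_candidates(probe, g)
                if g.count == len(cands) and cands:
                    for a in cands:
                        _merge_i_entry(entries, a, shift=g.shift)
                    changed = True
                    continue
                kept.append(g)

        x.isotopic_layer = tuple(entries)
        x.isotopologue_layer = tuple(kept)

    from .inchi_codec import _group_sort_key  # canonical ordering

    x.isotopic_layer = tuple(sorted(x.isotopic_layer, key=lambda e: e.atom_number))
    x.isotopologue_layer = tuple(sorted(x.isotopologue_layer, key=_group_sort_key))
    return x


def _same_skeleton(a: SkeletonInChI, b: SkeletonInChI) -> bool:
    return (
        a.version_prefix == b.version_prefix
        and a.formula_text == b.formula_text
        and a.retained_layers == b.retained_layers
        and a.formula_only == b.formula_only
    )


def semantic_equal(a: ExtendedInChI, b: ExtendedInChI) -> bool:
    """True iff the two strings denote identical isotopomer sets
    (normalize, then compare the canonical emissions)."""
    if not _same_skeleton(a.skeleton, b.skeleton):
        raise ValueError("semantic_equal requires the same skeleton")
    return emit(normalize(a)) == emit(normalize(b))
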