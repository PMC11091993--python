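"""Isotopomer counting/enumeration and isotopologue-space expansion.

Counting convention: isotopomers are counted over labeled canonical atom
numbers *without* reduction by molecular symmetry — ethane's two
topologically equivalent carbons count separately, so one deuterium among
ethane's six hydrogens gives two isotopomers (one per bearer carbon), and
the fully default composition gives exactly one.  Hydrogens attached to a
single heavy atom are mutually interchangeable (they are unnumbered), as
are the pooled mobile/exchangeable hydrogens.  Chemists expecting
symmetry-reduced counts should note this loudly: counts here are per
*numbered-atom assignment*, the convention the layer grammar itself uses.

``count_isotopomers`` uses closed forms (binomials per heavy-element
group, bounded-composition counts for hydrogen groups, composition sums
for neutron groups) whenever groups are independent, and falls back to
exact deduplicated enumeration when candidate sets overlap or neutron and
isotope groups mix.  ``enumerate_isotopomers`` is always the explicit
product construction, so the two routes stay independent.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .inchi_codec import AtomIsotopeSpec, ExtendedInChI, emit
from .isotope_data import NuclideTable, default_table, neutron_excess
from .layer_semantics import (
    MOBILE_SITE,
    h_site_capacities,
    effective_candidates,
    normalize,
    pinned_atoms,
    validate,
)

__all__ = [
    "IsotopomerAssignment",
    "IsotopologueComposition",
    "count_isotopomers",
    "enumerate_isotopomers",
    "expand_nominal_mass",
    "enumerate_isotopologue_space",
    "neutron_count_of",
    "composition_of",
]


@dataclass(frozen=True)
class IsotopomerAssignment:
    """A fully located isotope assignment: every heavy atom carries exactly
    one mass number, and per-site hydrogen-isotope counts sum to the site's
    capacity (:data:`~isoinchi.layer_semantics.MOBILE_SITE` pools the
    exchangeable hydrogens)."""

    heavy_atom_isotopes: tuple[tuple[int, int], ...]  # (atom, mass_number)
    h_distribution: tuple[tuple[int, tuple[tuple[int, int], ...]], ...]  # (site, ((iso, n), ...))

    @classmethod
    def from_maps(cls, heavy: Mapping[int, int],
                  h_dist: Mapping[int, Mapping[int, int]]) -> "IsotopomerAssignment":
        return cls(
            heavy_atom_isotopes=tuple(sorted(heavy.items())),
            h_distribution=tuple(
                (site, tuple(sorted((k, v) for k, v in counts.items() if v)))
                for site, counts in sorted(h_dist.items())
            ),
        )


@dataclass(frozen=True)
class IsotopologueComposition:
    """Per-element isotope-count multiset; counts sum to the formula."""

    per_element: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[int, int]]) -> "IsotopologueComposition":
        return cls(tuple(
            (el, tuple(sorted((m, c) for m, c in by_mass.items() if c)))
            for el, by_mass in sorted(counts.items(), key=_element_order)
        ))

    def as_dict(self) -> dict[str, dict[int, int]]:
        return {el: dict(pairs) for el, pairs in self.per_element}

    def formula(self) -> dict[str, int]:
        return {el: sum(c for _, c in pairs) for el, pairs in self.per_element}


def _element_order(item) -> tuple:
    el = item[0]
    return (0, "") if el == "C" else (1, el)


def neutron_count_of(c: IsotopologueComposition, table: NuclideTable | None = None) -> int:
    """Total extra neutrons relative to the most abundant stable isotopes."""
    table = table or default_table()
    return sum(
        count * neutron_excess(el, mass, table)
        for el, pairs in c.per_element
        for mass, count in pairs
    )


# ---------------------------------------------------------------------------
# isotopologue space and nominal-mass expansion
# ---------------------------------------------------------------------------

def _allowed_masses(formula: Mapping[str, int],
                    allowed: Mapping[str, Iterable[int]] | None,
                    table: NuclideTable) -> dict[str, tuple[int, ...]]:
    out = {}
    for el in formula:
        if allowed is not None and el in allowed:
            masses = tuple(sorted(allowed[el]))
        else:
            masses = tuple(i.mass_number for i in table.element(el).stable_isotopes)
        if not masses:
            raise ValueError(f"no allowed nuclides for element {el}")
        out[el] = masses
    return out


def enumerate_isotopologue_space(
    formula: Mapping[str, int],
    allowed: Mapping[str, Iterable[int]] | None = None,
    table: NuclideTable | None = None,
) -> list[IsotopologueComposition]:
    """All per-element isotope multisets for a formula.

    With stable H and O isotopes, ``H2O`` yields the nine classical water
    isotopologues (1H/2H x 16O/17O/18O multisets).  The count is the
    product over elements of multiset coefficients C(n+k-1, k-1).
    """
    table = table or default_table()
    masses = _allowed_masses(formula, allowed, table)
    elements = sorted(formula, key=lambda e: _element_order((e,)))
    per_element_choices = []
    for el in elements:
        choices = []
        for combo in itertools.combinations_with_replacement(masses[el], formula[el]):
            by_mass: dict[int, int] = {}
            for m in combo:
                by_mass[m] = by_mass.get(m, 0) + 1
            choices.append(by_mass)
        per_element_choices.append(choices)
    out = []
    for picks in itertools.product(*per_element_choices):
        out.append(IsotopologueComposition.from_counts(dict(zip(elements, picks))))
    return out


def expand_nominal_mass(
    formula: Mapping[str, int],
    n: int,
    allowed: Mapping[str, Iterable[int]] | None = None,
    table: NuclideTable | None = None,
) -> list[IsotopologueComposition]:
    """All isotopologue compositions of a formula carrying exactly ``n``
    extra neutrons relative to the most abundant stable isotopes.

    An infeasible ``n`` yields an empty list; ``n < 1`` is refused.  The
    default nuclide universe is the stable isotopes.  Deterministic
    lexicographic order over (element, mass number) counts.
    """
    if n < 1:
        raise ValueError(f"neutron count must be >= 1, got {n}")
    table = table or default_table()
    masses = _allowed_masses(formula, allowed, table)
    elements = sorted(formula, key=lambda e: _element_order((e,)))

    # per element: the non-default nuclides with their neutron excess
    variants: list[tuple[str, list[tuple[int, int]]]] = []
    for el in elements:
        default = table.element(el).most_abundant_mass_number
        vs = [(m, neutron_excess(el, m, table)) for m in masses[el] if m != default]
        variants.append((el, sorted(vs)))

    # feasibility bounds for pruning (excesses may be negative, e.g. 74Se)
    lo_bound = []
    hi_bound = []
    for el, vs in variants:
        cap = formula[el]
        lo = min([0] + [e for _, e in vs if e < 0]) * cap
        hi = max([0] + [e for _, e in vs if e > 0]) * cap
        lo_bound.append(lo)
        hi_bound.append(hi)
    suffix_lo = [0] * (len(variants) + 1)
    suffix_hi = [0] * (len(variants) + 1)
    for i in range(len(variants) - 1, -1, -1):
        suffix_lo[i] = suffix_lo[i + 1] + lo_bound[i]
        suffix_hi[i] = suffix_hi[i + 1] + hi_bound[i]

    results: list[IsotopologueComposition] = []

    def rec(ei: int, remaining: int, chosen: dict[str, dict[int, int]]) -> None:
        if ei == len(variants):
            if remaining == 0:
                full = {}
                for el in elements:
                    default = table.element(el).most_abundant_mass_number
                    by_mass = dict(chosen.get(el, {}))
                    used = sum(by_mass.values())
                    by_mass[default] = by_mass.get(default, 0) + (formula[el] - used)
                    full[el] = by_mass
                results.append(IsotopologueComposition.from_counts(full))
            return
        if not (suffix_lo[ei] <= remaining <= suffix_hi[ei]):
            return
        el, vs = variants[ei]
        cap = formula[el]

        def pick(vi: int, left: int, rem: int, acc: dict[int, int]) -> None:
            if vi == len(vs):
                chosen[el] = dict(acc)
                rec(ei + 1, rem, chosen)
                chosen.pop(el, None)
                return
            m, exc = vs[vi]
            for k in range(0, left + 1):
                if k:
                    acc[m] = k
                pick(vi + 1, left - k, rem - k * exc, acc)
            acc.pop(m, None)

        pick(0, cap, remaining, {})

    rec(0, n, {})
    return results


# ---------------------------------------------------------------------------
# the labeling problem behind count/enumerate
# ---------------------------------------------------------------------------

@dataclass
class _Problem:
    x: ExtendedInChI
    table: NuclideTable
    pinned: dict[int, int]                       # atom -> shift
    heavy_groups: dict[str, list[tuple[int, int, tuple[int, ...]]]]  # el -> [(shift, count, candidates)]
    h_groups: list[tuple[int, int, tuple[int, ...]]]  # (iso 1..3, count, sites)
    neutron_groups: list[tuple[int, Optional[tuple[int, ...]]]]
    h_caps: dict[int, int]                       # residual site capacities


def _build_problem(x: ExtendedInChI, table: NuclideTable) -> _Problem:
    if x.skeleton.formula_only:
        raise ValueError("formula-only strings have no atom structure to count over")
    report = validate(x, table, _with_rewrite=False)
    if report.errors:
        raise ValueError(
            "counting refused for invalid string: "
            + "; ".join(f"{f.rule_code}: {f.message}" for f in report.errors)
        )
    x = normalize(x)  # merge equal groups, drop redundant lists
    pinned = {e.atom_number: e.mass_shift for e in x.isotopic_layer
              if e.mass_shift is not None}
    heavy_groups: dict[str, list[tuple[int, int, tuple[int, ...]]]] = {}
    h_groups: list[tuple[int, int, tuple[int, ...]]] = []
    neutron_groups: list[tuple[int, Optional[tuple[int, ...]]]] = []
    caps = h_site_capacities(x)
    for g in x.isotopologue_layer:
        if g.kind == "neutron":
            neutron_groups.append((g.count, g.candidate_atoms))
        elif g.element == "H":
            iso = 1 + (g.shift or 0)
            if iso not in (1, 2, 3):
                raise ValueError(f"unsupported hydrogen designation H{g.shift:+d}")
            sites = (g.candidate_atoms if g.candidate_atoms is not None
                     else tuple(sorted(s for s, c in caps.items() if c > 0)))
            h_groups.append((iso, g.count, sites))
        else:
            cands = effective_candidates(x, g)
            heavy_groups.setdefault(g.element, []).append((g.shift, g.count, cands))
    return _Problem(x, table, pinned, heavy_groups, h_groups, neutron_groups, caps)


def _pairwise_disjoint(sets: Sequence[frozenset]) -> bool:
    seen: set = set()
    for s in sets:
        if seen & s:
            return False
        seen |= s
    return True


def _element_selections(groups: list[tuple[int, int, tuple[int, ...]]]):
    """Yield atom->shift maps for one element's groups (joint, disjoint picks)."""
    def rec(gi: int, taken: frozenset[int], acc: dict[int, int]):
        if gi == len(groups):
            yield dict(acc)
            return
        shift, count, cands = groups[gi]
        avail = [a for a in cands if a not in taken]
        for combo in itertools.combinations(avail, count):
            for a in combo:
                acc[a] = shift
            yield from rec(gi + 1, taken | frozenset(combo), acc)
            for a in combo:
                acc.pop(a)
    yield from rec(0, frozenset(), {})


def _count_element(groups: list[tuple[int, int, tuple[int, ...]]]) -> int:
    sets = [frozenset(c) for _, _, c in groups]
    if _pairwise_disjoint(sets):
        return math.prod(math.comb(len(c), k) for _, k, c in groups)
    # overlapping candidate sets: count distinct joint assignments exactly
    distinct = {frozenset(sel.items()) for sel in _element_selections(groups)}
    return len(distinct)


def _bounded_composition_count(caps: Sequence[int], k: int) -> int:
    """Number of integer vectors 0 <= x_i <= caps[i] with sum k (DP)."""
    dp = [0] * (k + 1)
    dp[0] = 1
    for c in caps:
        new = [0] * (k + 1)
        run = 0
        # prefix-sum sliding window over min(c, j)
        for j in range(k + 1):
            run += dp[j]
            if j - c - 1 >= 0:
                run -= dp[j - c - 1]
            new[j] = run
        dp = new
    return dp[k]


def _h_distributions(caps: dict[int, int], groups: list[tuple[int, int, tuple[int, ...]]]):
    """Yield site -> {iso: count} maps for the hydrogen groups jointly."""
    def rec(gi: int, remaining: dict[int, int], acc: dict[int, dict[int, int]]):
        if gi == len(groups):
            yield {s: dict(cnt) for s, cnt in acc.items()}
            return
        iso, count, sites = groups[gi]
        usable = [s for s in sites if remaining.get(s, 0) > 0]

        def place(si: int, left: int):
            if left == 0:
                yield from rec(gi + 1, remaining, acc)
                return
            if si == len(usable):
                return
            s = usable[si]
            avail = remaining.get(s, 0)
            for take in range(min(avail, left), -1, -1):
                if take:
                    remaining[s] = avail - take
                    acc.setdefault(s, {})[iso] = acc.get(s, {}).get(iso, 0) + take
                yield from place(si + 1, left - take)
                if take:
                    remaining[s] = avail
                    acc[s][iso] -= take
                    if not acc[s][iso]:
                        del acc[s][iso]
                    if not acc[s]:
                        del acc[s]

        yield from place(0, count)

    yield from rec(0, dict(caps), {})


def _count_h(caps: dict[int, int], groups: list[tuple[int, int, tuple[int, ...]]]) -> int:
    if not groups:
        return 1
    if len(groups) == 1:
        iso, count, sites = groups[0]
        return _bounded_composition_count([max(caps.get(s, 0), 0) for s in sites], count)
    isos = [g[0] for g in groups]
    if len(set(isos)) == len(isos):
        # distinct isotopes still compete for capacity: joint enumeration,
        # but every joint distribution is distinct (no dedup needed)
        return sum(1 for _ in _h_distributions(caps, groups))
    distinct = set()
    for dist in _h_distributions(caps, groups):
        distinct.add(tuple(sorted((s, tuple(sorted(c.items()))) for s, c in dist.items())))
    return len(distinct)


def _neutron_selections(p: _Problem, n: int, candidates: Optional[tuple[int, ...]],
                        h_caps: dict[int, int]):
    """Yield (atom->shift map, site->{iso: n} map) placements for one
    neutron group; also used for counting via the closed-form path."""
    sk = p.x.skeleton
    if candidates is not None:
        atoms = [a for a in candidates if a not in p.pinned]
        include_h = False
    else:
        atoms = [a for a in sorted(sk.atom_elements) if a not in p.pinned]
        include_h = True
    by_el: dict[str, list[int]] = {}
    for a in atoms:
        by_el.setdefault(sk.atom_elements[a], []).append(a)

    formula = {el: len(atoms_) for el, atoms_ in by_el.items()}
    h_cap_total = sum(c for c in h_caps.values() if c > 0) if include_h else 0
    if include_h and h_cap_total:
        formula["H"] = h_cap_total
    if not formula:
        return
    for comp in expand_nominal_mass(formula, n, table=p.table):
        d = comp.as_dict()
        per_el_choices = []
        for el, by_mass in d.items():
            if el == "H":
                continue
            default = p.table.element(el).most_abundant_mass_number
            extras = sorted((m, c) for m, c in by_mass.items() if m != default and c > 0)
            if not extras:
                continue
            baseline = p.table.element(el).rounded_avg_mass

            def gen_el(extras=tuple(extras), avail=tuple(by_el[el]), baseline=baseline):
                def rec(vi: int, pool: tuple[int, ...], acc: dict[int, int]):
                    if vi == len(extras):
                        yield dict(acc)
                        return
                    m, c = extras[vi]
                    shift = m - baseline
                    for combo in itertools.combinations(pool, c):
                        for a in combo:
                            acc[a] = shift
                        rest = tuple(a for a in pool if a not in combo)
                        yield from rec(vi + 1, rest, acc)
                        for a in combo:
                            acc.pop(a)
                yield from rec(0, avail, {})

            per_el_choices.append(gen_el)

        h_extra = {}
        if "H" in d:
            default_h = p.table.element("H").most_abundant_mass_number
            h_extra = {m: c for m, c in d["H"].items() if m != default_h and c > 0}

        def h_choices():
            if not h_extra:
                yield {}
                return
            groups = [(m, c, tuple(sorted(s for s, cc in h_caps.items() if cc > 0)))
                      for m, c in sorted(h_extra.items())]
            yield from _h_distributions(h_caps, groups)

        for picks in itertools.product(*[g() for g in per_el_choices]):
            heavy: dict[int, int] = {}
            for m in picks:
                heavy.update(m)
            for hdist in h_choices():
                yield heavy, hdist


def _count_single_neutron_group(p: _Problem, n: int,
                                candidates: Optional[tuple[int, ...]]) -> int:
    """Closed-form count for a lone neutron group: sum over compositions of
    per-element placement multinomials times hydrogen distribution counts."""
    sk = p.x.skeleton
    if candidates is not None:
        atoms = [a for a in candidates if a not in p.pinned]
        include_h = False
    else:
        atoms = [a for a in sorted(sk.atom_elements) if a not in p.pinned]
        include_h = True
    by_el: dict[str, list[int]] = {}
    for a in atoms:
        by_el.setdefault(sk.atom_elements[a], []).append(a)
    formula = {el: len(atoms_) for el, atoms_ in by_el.items()}
    h_caps = [c for c in p.h_caps.values() if c > 0] if include_h else []
    if include_h and h_caps:
        formula["H"] = sum(h_caps)
    if not formula:
        return 0
    total = 0
    for comp in expand_nominal_mass(formula, n, table=p.table):
        ways = 1
        for el, by_mass in comp.as_dict().items():
            default = p.table.element(el).most_abundant_mass_number
            if el == "H":
                extras = {m: c for m, c in by_mass.items() if m != default and c > 0}
                if extras:
                    # distribute each heavy-H isotope jointly over the sites
                    groups = [(m, c, tuple(range(len(h_caps))))
                              for m, c in sorted(extras.items())]
                    caps = dict(enumerate(h_caps))
                    ways *= _count_h(caps, groups)
                continue
            avail = len(by_el[el])
            for m, c in sorted(by_mass.items()):
                if m == default or c == 0:
                    continue
                ways *= math.comb(avail, c)
                avail -= c
        total += ways
    return total


def count_isotopomers(x: ExtendedInChI, table: NuclideTable | None = None) -> int:
    """Number of distinct isotopomer assignments a specification denotes.

    The specified isotope content (``/i`` entries plus ``/a`` groups) is
    placed in all distinct ways; unspecified atoms sit at their default
    isotope.  Independent groups multiply (binomials over candidate sets,
    bounded compositions over hydrogen capacities); entangled cases fall
    back to exact deduplicated enumeration.
    """
    table = table or default_table()
    p = _build_problem(x, table)

    if p.neutron_groups:
        if p.heavy_groups or p.h_groups or len(p.neutron_groups) > 1:
            # entangled: count by explicit deduplicated enumeration
            return sum(1 for _ in _distinct_assignment_keys(p))
        n, cands = p.neutron_groups[0]
        return _count_single_neutron_group(p, n, cands)

    total = 1
    for el, groups in p.heavy_groups.items():
        total *= _count_element(groups)
    total *= _count_h(p.h_caps, p.h_groups)
    return total


def _specified_selections(p: _Problem):
    """Yield (heavy atom->shift, site->{iso: n}) joint selections."""
    per_element = [list(_element_selections(groups))
                   for groups in p.heavy_groups.values()]
    if p.neutron_groups:
        def neutron_stream(prior_heavy: dict[int, int]):
            # neutron groups placed after isotope groups, skipping taken atoms
            def rec(gi: int, heavy: dict[int, int], hdists: list[dict]):
                if gi == len(p.neutron_groups):
                    merged_h: dict[int, dict[int, int]] = {}
                    ok = True
                    rem = dict(p.h_caps)
                    for hd in hdists:
                        for s, cnt in hd.items():
                            for iso, c in cnt.items():
                                if rem.get(s, 0) < c:
                                    ok = False
                                merged_h.setdefault(s, {})[iso] = \
                                    merged_h.get(s, {}).get(iso, 0) + c
                                rem[s] = rem.get(s, 0) - c
                    if ok:
                        yield dict(heavy), merged_h
                    return
                n, cands = p.neutron_groups[gi]
                sub = dataclasses.replace(p, pinned={**p.pinned,
                                                     **{a: 0 for a in heavy}})
                for hsel, hdist in _neutron_selections(sub, n, cands, dict(p.h_caps)):
                    if set(hsel) & set(heavy):
                        continue
                    yield from rec(gi + 1, {**heavy, **hsel}, hdists + [hdist])
            yield from rec(0, dict(prior_heavy), [])
    for combo in itertools.product(*per_element) if per_element else [()]:
        heavy: dict[int, int] = {}
        clash = False
        for sel in combo:
            if set(sel) & set(heavy):
                clash = True
                break
            heavy.update(sel)
        if clash:
            continue
        if p.neutron_groups:
            for nheavy, nh in neutron_stream(heavy):
                if p.h_groups:
                    rem = dict(p.h_caps)
                    for s, cnt in nh.items():
                        rem[s] = rem.get(s, 0) - sum(cnt.values())
                    for hdist in _h_distributions(rem, p.h_groups):
                        merged = {s: dict(c) for s, c in nh.items()}
                        for s, cnt in hdist.items():
                            for iso, c in cnt.items():
                                merged.setdefault(s, {})[iso] = \
                                    merged.get(s, {}).get(iso, 0) + c
                        yield nheavy, merged
                else:
                    yield nheavy, nh
        elif p.h_groups:
            for hdist in _h_distributions(p.h_caps, p.h_groups):
                yield dict(heavy), hdist
        else:
            yield dict(heavy), {}


def _assignment_key(heavy: Mapping[int, int], hdist: Mapping[int, Mapping[int, int]]):
    h_items = []
    for s, c in hdist.items():
        cleaned = tuple(sorted((k, v) for k, v in c.items() if v))
        if cleaned:
            h_items.append((s, cleaned))
    return (tuple(sorted(heavy.items())), tuple(sorted(h_items)))


def _distinct_assignment_keys(p: _Problem):
    seen = set()
    for heavy, hdist in _specified_selections(p):
        key = _assignment_key(heavy, hdist)
        if key not in seen:
            seen.add(key)
            yield key, heavy, hdist


def enumerate_isotopomers(
    x: ExtendedInChI,
    limit: int = 10_000,
    mode: str = "pinned",
    table: NuclideTable | None = None,
) -> list[ExtendedInChI]:
    """Materialize the isotopomer set a specification denotes.

    ``pinned`` mode emits partial isotopomers fixing only the specified
    isotope content; ``exact`` mode additionally writes every remaining
    atom's default isotope and every hydrogen explicitly, so the outputs
    classify as exact isotopomers.  Refuses (with the count in the
    message) when the set exceeds ``limit``.
    """
    if mode not in ("pinned", "exact"):
        raise ValueError(f"mode must be 'pinned' or 'exact', got {mode!r}")
    table = table or default_table()
    count = count_isotopomers(x, table)
    if count > limit:
        raise ValueError(f"isotopomer set has {count} members, exceeding limit {limit}")
    p = _build_problem(x, table)
    xn = p.x  # normalized
    sk = xn.skeleton

    explicit_h: dict[int, dict[int, int]] = {}
    for e in xn.isotopic_layer:
        if e.h_counts:
            explicit_h.setdefault(e.atom_number, {})
            for k, v in e.h_counts.items():
                explicit_h[e.atom_number][k] = explicit_h[e.atom_number].get(k, 0) + v

    out: list[tuple[tuple, ExtendedInChI]] = []
    for key, heavy, hdist in _distinct_assignment_keys(p):
        shifts: dict[int, int] = dict(p.pinned)
        shifts.update(heavy)
        h_per_site: dict[int, dict[int, int]] = {s: dict(c) for s, c in explicit_h.items()}
        for s, cnt in hdist.items():
            for iso, c in cnt.items():
                h_per_site.setdefault(s, {})[iso] = h_per_site.get(s, {}).get(iso, 0) + c
        exch = dict(xn.exchangeable_h)
        if MOBILE_SITE in h_per_site:
            for iso, c in h_per_site.pop(MOBILE_SITE).items():
                exch[iso] = exch.get(iso, 0) + c

        if mode == "exact":
            for a, el in sk.atom_elements.items():
                if a not in shifts:
                    rec = table.element(el)
                    shifts[a] = rec.most_abundant_mass_number - rec.rounded_avg_mass
            for a, cap in sk.fixed_h.items():
                have = sum(h_per_site.get(a, {}).values())
                if cap - have > 0:
                    h_per_site.setdefault(a, {})[1] = \
                        h_per_site.get(a, {}).get(1, 0) + (cap - have)
            mobile_total = sum(c for c, _ in sk.mobile_h_groups)
            rem = mobile_total - sum(exch.values())
            if rem > 0:
                exch[1] = exch.get(1, 0) + rem

        entries = []
        for a in sorted(set(shifts) | set(h_per_site)):
            entries.append(AtomIsotopeSpec(
                atom_number=a,
                mass_shift=shifts.get(a),
                h_counts=dict(h_per_site.get(a, {})),
            ))
        model = ExtendedInChI(
            skeleton=sk,
            isotopic_layer=tuple(entries),
            exchangeable_h=exch,
            isotopologue_layer=(),
        )
        out.append((key, model))

    out.sort(key=lambda t: t[0])
    return [m for _, m in out]


def composition_of(x: ExtendedInChI, table: NuclideTable | None = None
                   ) -> Optional[IsotopologueComposition]:
    """The isotopologue composition a specification determines, or ``None``
    when the composition itself is ambiguous (nominal-mass groups).

    All isotopomers of one isotopologue share a composition, so this is
    well-defined for isotope-resolved strings even when positions are
    ambiguous.
    """
    table = table or default_table()
    if any(g.kind == "neutron" for g in x.isotopologue_layer):
        return None
    sk = x.skeleton
    counts: dict[str, dict[int, int]] = {}

    def add(el: str, mass: int, k: int = 1) -> None:
        counts.setdefault(el, {})
        counts[el][mass] = counts[el].get(mass, 0) + k

    for e in x.isotopic_layer:
        if e.mass_shift is not None:
            el = sk.atom_elements.get(e.atom_number)
            if el:
                add(el, table.element(el).rounded_avg_mass + e.mass_shift)
        for iso, c in e.h_counts.items():
            if c:
                add("H", iso, c)
    for iso, c in x.exchangeable_h.items():
        if c:
            add("H", iso, c)
    for g in x.isotopologue_layer:
        el = g.element
        assert el is not None and g.shift is not None
        baseline = table.element(el).rounded_avg_mass
        add(el, baseline + g.shift, g.count)

    formula = dict(sk.element_counts)
    full: dict[str, dict[int, int]] = {}
    for el, total in formula.items():
        default = table.element(el).most_abundant_mass_number
        by_mass = dict(counts.get(el, {}))
        specified = sum(by_mass.values())
        if specified > total:
            raise ValueError(f"composition over-assigns element {el}")
        by_mass[default] = by_mass.get(default, 0) + (total - specified)
        full[el] = by_mass
    return IsotopologueComposition.from_counts(full)
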