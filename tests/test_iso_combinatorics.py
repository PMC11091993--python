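"""Counting, enumeration and nominal-mass expansion."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from isoinchi import (
    Category,
    IsotopologueComposition,
    IsotopomerAssignment,
    classify,
    count_isotopomers,
    emit,
    enumerate_isotopologue_space,
    enumerate_isotopomers,
    expand_nominal_mass,
    neutron_count_of,
    parse,
)


class TestCountIsotopomers:
    def test_ethane_worked_example(self, ethane):
        """12C2-1H6 has one isotopomer; 12C2-1H5-2H has two (one per bearer
        carbon) — counting over labeled atoms, no symmetry reduction."""
        assert count_isotopomers(parse(ethane)) == 1
        assert count_isotopomers(parse(ethane + "/a(H1+1)")) == 2

    @pytest.mark.parametrize(
        "suffix, expected",
        [
            ("/a(C2+1)", 15),          # C(6,2) placements of two 13C
            ("/a(C1+1,1,2,3)", 3),     # one 13C among three listed atoms
            ("/i1+1", 1),              # pinned partial isotopomer
            ("/a(C1+1)(O1+2)", 36),    # independent groups multiply
            ("/i1+1/a(C2+1)", 10),     # pinned atom excluded: C(5,2)
        ],
    )
    def test_glucose_counts(self, glucose, suffix, expected):
        assert count_isotopomers(parse(glucose + suffix)) == expected

    def test_single_group_closed_form_is_binomial(self, glucose):
        for k in range(1, 6):
            assert count_isotopomers(parse(glucose + f"/a(C{k}+1)")) == math.comb(6, k)

    def test_monotone_in_candidate_list(self, glucose):
        """Enlarging a candidate list never decreases the count."""
        counts = [
            count_isotopomers(parse(glucose + "/a(C1+1," + ",".join(map(str, range(1, n + 1))) + ")"))
            for n in range(2, 6)
        ]
        assert counts == sorted(counts)

    def test_formula_only_refused(self):
        with pytest.raises(ValueError):
            count_isotopomers(parse("InChI=1S/C6H12O6/a(C1+1)"))

    def test_invalid_string_refused(self, glucose):
        with pytest.raises(ValueError):
            count_isotopomers(parse(glucose + "/a(C6+1)"))

    def test_hydrogen_count_is_bounded_composition(self, glucose):
        """k deuteriums over bearer capacities (2,1,...,1): oracle by direct
        enumeration of bounded integer vectors."""
        caps = [2] + [1] * 10
        for k in (1, 2, 3):
            oracle = sum(
                1
                for v in itertools.product(*[range(c + 1) for c in caps])
                if sum(v) == k
            )
            assert count_isotopomers(parse(glucose + f"/a(H{k}+1)")) == oracle

    def test_nominal_count_matches_enumeration(self, glucose):
        x = parse(glucose + "/a(2n)")
        members = enumerate_isotopomers(x, limit=100_000)
        assert count_isotopomers(x) == len(members)
        assert len({emit(m) for m in members}) == len(members)


class TestEnumerateIsotopomers:
    def test_pinned_mode_glucose_single_13c(self, glucose):
        members = enumerate_isotopomers(parse(glucose + "/a(C1+1)"))
        assert [emit(m) for m in members] == [
            glucose + f"/i{i}+1" for i in range(1, 7)
        ]
        assert all(classify(m).category is Category.PARTIAL_ISOTOPOMER for m in members)

    def test_ethane_single_deuterium(self, ethane):
        members = enumerate_isotopomers(parse(ethane + "/a(H1+1)"))
        assert [emit(m) for m in members] == [ethane + "/i1D", ethane + "/i2D"]

    def test_exact_mode_outputs_classify_exact(self, ethane):
        members = enumerate_isotopomers(parse(ethane + "/a(H1+1)"), mode="exact")
        assert all(classify(m).category is Category.EXACT_ISOTOPOMER for m in members)
        assert len(members) == 2

    def test_length_always_equals_count(self, glucose):
        for suffix in ("/a(C2+1)", "/a(O1+1)(O1+2)", "/i2+1/a(C1+1,1,3,5)"):
            x = parse(glucose + suffix)
            assert len(enumerate_isotopomers(x)) == count_isotopomers(x)

    def test_limit_refusal_reports_count(self, glucose):
        with pytest.raises(ValueError, match="15"):
            enumerate_isotopomers(parse(glucose + "/a(C2+1)"), limit=10)


def test_isotopomer_assignment_canonical_form():
    """from_maps sorts atoms/sites and drops zero hydrogen counts, so two
    maps describing the same assignment compare (and hash) equal."""
    a = IsotopomerAssignment.from_maps({2: 13, 1: 12}, {1: {2: 1, 1: 0}})
    b = IsotopomerAssignment.from_maps({1: 12, 2: 13}, {1: {2: 1}})
    assert a == b
    assert a.heavy_atom_isotopes == ((1, 12), (2, 13))
    assert a.h_distribution == ((1, ((2, 1),)),)


class TestIsotopologueSpace:
    def test_water_nine_compositions(self):
        """The classical water isotopologues over stable H and O."""
        space = enumerate_isotopologue_space({"H": 2, "O": 1})
        expected = [
            {"H": {1: 2}, "O": {16: 1}},
            {"H": {1: 1, 2: 1}, "O": {16: 1}},
            {"H": {2: 2}, "O": {16: 1}},
            {"H": {1: 2}, "O": {17: 1}},
            {"H": {1: 1, 2: 1}, "O": {17: 1}},
            {"H": {2: 2}, "O": {17: 1}},
            {"H": {1: 2}, "O": {18: 1}},
            {"H": {1: 1, 2: 1}, "O": {18: 1}},
            {"H": {2: 2}, "O": {18: 1}},
        ]
        assert {IsotopologueComposition.from_counts(e) for e in expected} == set(space)
        assert len(space) == 9

    def test_single_carbon(self):
        assert len(enumerate_isotopologue_space({"C": 1})) == 2

    def test_ethane_21_compositions(self):
        """3 carbon multisets x 7 hydrogen multisets; cross-checked against
        the multiset-coefficient product."""
        space = enumerate_isotopologue_space(
            {"C": 2, "H": 6}, allowed={"C": [12, 13], "H": [1, 2]}
        )
        assert len(space) == len(set(space)) == math.comb(2 + 1, 1) * math.comb(6 + 1, 1) == 21


class TestExpandNominalMass:
    def test_glucose_n3_contains_paper_compositions(self):
        comps = [c.as_dict() for c in expand_nominal_mass({"C": 6, "H": 12, "O": 6}, 3)]
        assert {"C": {12: 3, 13: 3}, "H": {1: 12}, "O": {16: 6}} in comps
        assert {"C": {12: 5, 13: 1}, "H": {1: 12}, "O": {16: 5, 18: 1}} in comps

    def test_count_by_brute_force(self):
        """Oracle: bounded integer solutions of a*1 + b*1 + c*1 + d*2 = n
        over (2H, 13C, 17O, 18O) within formula bounds."""
        f = {"C": 6, "H": 12, "O": 6}
        for n in (1, 2, 3, 4):
            oracle = sum(
                1
                for a in range(min(12, n) + 1)           # 2H
                for b in range(min(6, n) + 1)            # 13C
                for c in range(min(6, n) + 1)            # 17O
                for d in range(min(6, n // 2) + 1)       # 18O
                if a + b + c + 2 * d == n and c + d <= 6
            )
            assert len(expand_nominal_mass(f, n)) == oracle

    def test_conservation(self):
        for n in (1, 2, 3, 5):
            for comp in expand_nominal_mass({"C": 3, "H": 8, "O": 3}, n):
                assert neutron_count_of(comp) == n

    def test_partitions_isotopologue_space(self):
        """Nominal-mass classes partition the full isotopologue space."""
        formula = {"C": 2, "O": 1}
        space = enumerate_isotopologue_space(formula)
        by_n: dict[int, set] = {}
        for comp in space:
            by_n.setdefault(neutron_count_of(comp), set()).add(comp)
        for n, members in by_n.items():
            if n == 0:
                continue
            assert set(expand_nominal_mass(formula, n)) == members
        total = sum(len(v) for v in by_n.values())
        assert total == len(space)

    def test_infeasible_is_empty_negative_is_refused(self):
        assert expand_nominal_mass({"C": 1}, 5) == []
        with pytest.raises(ValueError):
            expand_nominal_mass({"C": 1}, -1)

    def test_allowed_set_restriction(self):
        comps = expand_nominal_mass({"C": 6, "H": 12, "O": 6}, 2,
                                    allowed={"H": [1], "O": [16]})
        assert [c.as_dict()["C"] for c in comps] == [{12: 4, 13: 2}]


@settings(deadline=None, max_examples=40)
@given(
    n_atoms=st.integers(min_value=2, max_value=8),
    k=st.integers(min_value=1, max_value=7),
)
def test_single_group_count_is_binomial_property(n_atoms, k):
    """For one heavy-element group the count is C(|candidates|, k), checked
    against explicit enumeration."""
    if k >= n_atoms:
        return
    s = f"InChI=1S/C{n_atoms}H{2 * n_atoms + 2}/c1-2/a(C{k}+1)"
    x = parse(s)
    assert count_isotopomers(x) == math.comb(n_atoms, k)
    assert len(enumerate_isotopomers(x, limit=10_000)) == math.comb(n_atoms, k)
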