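"""Taxonomy classification, validation rules R1-R8, normalization."""

import itertools

import pytest

from isoinchi import (
    Category,
    classify,
    count_isotopomers,
    emit,
    enumerate_isotopomers,
    normalize,
    parse,
    semantic_equal,
    validate,
)


class TestClassify:
    @pytest.mark.parametrize(
        "suffix, category",
        [
            ("", Category.UNLABELED),
            ("/i1+1", Category.PARTIAL_ISOTOPOMER),
            ("/a(C2+1)", Category.ISOTOPOLOGUE),
            ("/a(C1+1,1,2,3)", Category.ISOTOPOLOGUE_FRAGMENT),
            ("/a(3n)", Category.NOMINAL_MASS_ISOTOPOLOGUE),
            ("/a(4n,1,2,3,4,5,6)", Category.NOMINAL_MASS_FRAGMENT),
        ],
    )
    def test_glucose_taxonomy(self, glucose, suffix, category):
        assert classify(parse(glucose + suffix)).category is category

    def test_formula_only_isotopologue(self):
        for s in ("InChI=1S/C6H12O6/a(C1+1)", "InChI=1S/C6H12O6/a(3n)"):
            assert classify(parse(s)).category is Category.FORMULA_ONLY_ISOTOPOLOGUE

    def test_exact_requires_every_atom_and_hydrogen(self, ethane):
        exact = parse(ethane + "/i1+0H3,2+0H2D")
        assert classify(exact).category is Category.EXACT_ISOTOPOMER
        # one hydrogen left unspecified -> only partial
        partial = parse(ethane + "/i1+0H3,2+0H2")
        assert classify(partial).category is Category.PARTIAL_ISOTOPOMER
        # shifts missing on one heavy atom -> partial
        partial2 = parse(ethane + "/i1+0H3,2H3")
        assert classify(partial2).category is Category.PARTIAL_ISOTOPOMER

    def test_full_candidate_list_is_not_a_fragment(self, glucose):
        """A list naming every carbon restricts nothing, so the string is a
        plain isotopologue, matching its list-free normal form."""
        x = parse(glucose + "/a(C1+1,1,2,3,4,5,6)")
        assert classify(x).category is Category.ISOTOPOLOGUE

    def test_deuterium_with_incomplete_stereo_sets_flag(self, glucose, ethane):
        # glucose keeps its /t layer: stereo-complete, no flag
        assert not classify(parse(glucose + "/i1D")).stereo_ambiguity_flag
        # ethane has no stereo layer at all: a lone D is stereo-ambiguous
        assert classify(parse(ethane + "/i1D")).stereo_ambiguity_flag
        # 13C without hydrogen isotopes never flags
        assert not classify(parse(ethane + "/i1+1")).stereo_ambiguity_flag

    def test_classification_refused_for_invalid_strings(self, glucose):
        with pytest.raises(ValueError):
            classify(parse(glucose + "/a(C6+1)"))

    def test_classify_invariant_under_roundtrip_and_normalize(self, glucose):
        for suffix in ("/i1+1", "/a(C2+1)", "/a(C1+1,1,2,3)", "/a(3n)"):
            x = parse(glucose + suffix)
            c = classify(x).category
            assert classify(parse(emit(x))).category is c
            assert classify(normalize(x)).category is c


class TestValidate:
    def test_well_formed_has_no_findings(self, glucose):
        assert validate(parse(glucose + "/a(C2+1)")).ok

    def test_r1_atom_number_out_of_range(self, ethane):
        codes = validate(parse(ethane + "/i5+1")).rule_codes()
        assert "R1" in codes
        codes = validate(parse(ethane + "/a(C1+1,1,7)")).rule_codes()
        assert "R1" in codes

    def test_r2_candidate_element_mismatch(self, glucose):
        # atoms 7-12 are oxygens; a carbon group cannot name them
        codes = validate(parse(glucose + "/a(C1+1,7,8)")).rule_codes()
        assert "R2" in codes

    def test_r2_hydrogen_candidates_must_bear_hydrogen(self, glucose):
        # atom 12 is the ring oxygen: no attached hydrogen
        codes = validate(parse(glucose + "/a(H1+1,12)")).rule_codes()
        assert "R2" in codes

    def test_r3_single_nitrogen_boundary(self, g6p):
        """One 15N among one nitrogen is not ambiguous: the group must be
        rewritten as an /i entry pinning atom 7."""
        report = validate(parse(g6p + "/a(N1+1)"))
        assert report.rule_codes() == ("R3",)
        assert report.errors
        rewrite = report.suggested_rewrite
        assert rewrite is not None
        (entry,) = rewrite.isotopic_layer
        assert entry.atom_number == 7 and entry.mass_shift == 1
        assert not rewrite.isotopologue_layer

    def test_r3_count_equal_to_element_total(self, glucose):
        report = validate(parse(glucose + "/a(C6+1)"))
        assert "R3" in report.rule_codes()
        rewrite = report.suggested_rewrite
        assert emit(rewrite).endswith("/i1+1,2+1,3+1,4+1,5+1,6+1")

    def test_r3_count_equal_to_candidate_list(self, glucose):
        report = validate(parse(glucose + "/a(C2+1,2,5)"))
        assert "R3" in report.rule_codes()
        assert emit(report.suggested_rewrite).endswith("/i2+1,5+1")

    def test_r4_count_exceeds_candidates(self, glucose):
        assert "R4" in validate(parse(glucose + "/a(O7+2)")).rule_codes()
        assert "R4" in validate(parse(glucose + "/a(H13+1)")).rule_codes()

    def test_r5_formula_only_with_atom_references(self):
        codes = validate(parse("InChI=1S/C6H12O6/a(C1+1,1,2)")).rule_codes()
        assert "R5" in codes

    def test_r6_pinned_atoms_excluded_from_candidates(self, glucose):
        codes = validate(parse(glucose + "/i1+1/a(C1+1,1,2)")).rule_codes()
        assert "R6" in codes

    def test_r6_totals_bounded_by_formula(self, glucose):
        codes = validate(parse(glucose + "/i1+1,2+1/a(C5+1)")).rule_codes()
        assert "R6" in codes

    def test_r7_neutron_count_beyond_stable_reach(self, ethane):
        # ethane: 2 C (13C: +1 each) + 6 H (2H: +1 each) -> max 8
        assert validate(parse(ethane + "/a(8n)")).ok
        assert "R7" in validate(parse(ethane + "/a(9n)")).rule_codes()

    def test_r8_duplicate_atoms_in_isotopic_layer(self, ethane):
        codes = validate(parse(ethane + "/i1+1,1+1")).rule_codes()
        assert "R8" in codes

    def test_r3_rewrite_preserves_isotopomer_set(self, glucose, g6p):
        """Oracle: the suggested rewrite enumerates the same isotopomers."""
        for base, suffix in ((g6p, "/a(N1+1)"), (glucose, "/a(C2+1,2,5)")):
            x = parse(base + suffix)
            rewrite = validate(x).suggested_rewrite
            original_set = {
                tuple(sorted((e.atom_number, e.mass_shift) for e in m.isotopic_layer))
                for m in _brute_force(x)
            }
            rewritten_set = {
                tuple(sorted((e.atom_number, e.mass_shift) for e in m.isotopic_layer))
                for m in enumerate_isotopomers(rewrite)
            }
            assert original_set == rewritten_set


def _brute_force(x):
    """Independent enumeration for a single heavy-element isotope group:
    place the count over candidates by explicit combinations."""
    (g,) = x.isotopologue_layer
    sk = x.skeleton
    cands = g.candidate_atoms or sk.atoms_of(g.element)
    out = []
    for combo in itertools.combinations(cands, g.count):
        entries = tuple((a, g.shift) for a in combo)
        m = parse(emit(x).split("/a")[0] + "/i" + ",".join(
            f"{a}{s:+d}" for a, s in entries))
        out.append(m)
    return out


class TestNormalize:
    def test_boundary_group_demoted_to_isotopic_layer(self, g6p):
        n = normalize(parse(g6p + "/a(N1+1)"))
        assert emit(n).endswith("/i7+1")

    def test_equal_groups_merge(self, glucose):
        n = normalize(parse(glucose + "/a(C1+1)(C1+1)"))
        assert emit(n).endswith("/a(C2+1)")
        # set-semantics oracle: merged and unmerged enumerate identically
        merged = {emit(m) for m in enumerate_isotopomers(n)}
        raw = {emit(m) for m in enumerate_isotopomers(parse(glucose + "/a(C1+1)(C1+1)"))}
        assert merged == raw == {
            emit(m) for m in enumerate_isotopomers(parse(glucose + "/a(C2+1)"))
        }

    def test_redundant_full_list_dropped(self, glucose):
        n = normalize(parse(glucose + "/a(C1+1,1,2,3,4,5,6)"))
        assert emit(n).endswith("/a(C1+1)")

    def test_idempotent(self, glucose, g6p, ethane):
        for s in (
            glucose + "/a(C1+1)(C1+1)",
            g6p + "/a(N1+1)",
            ethane + "/i1D",
            glucose + "/a(3n)",
            glucose,
        ):
            once = normalize(parse(s))
            assert emit(normalize(once)) == emit(once)

    def test_refuses_non_boundary_errors(self, glucose):
        with pytest.raises(ValueError):
            normalize(parse(glucose + "/a(O7+2)"))

    def test_hydrogen_boundary_demotion(self):
        # water: both hydrogens deuterated is not ambiguous
        n = normalize(parse("InChI=1S/H2O/h1H2/a(H2+1)"))
        assert emit(n) == "InChI=1S/H2O/h1H2/i1D2"


class TestSemanticEqual:
    def test_normalize_fixpoint_is_equal(self, glucose):
        x = parse(glucose + "/a(C1+1)(C1+1)")
        assert semantic_equal(x, normalize(x))

    def test_isotopologue_differs_from_pinned_isotopomer(self, glucose):
        assert not semantic_equal(parse(glucose + "/a(C1+1)"), parse(glucose + "/i1+1"))

    def test_redundant_candidate_list_is_equal(self, glucose):
        assert semantic_equal(
            parse(glucose + "/a(C1+1,1,2,3,4,5,6)"), parse(glucose + "/a(C1+1)")
        )

    def test_different_skeletons_refused(self, glucose, ethane):
        with pytest.raises(ValueError):
            semantic_equal(parse(glucose), parse(ethane))
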