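# Methods

## The representation problem

Stable-isotope tracing experiments produce spectral features whose
isotopic interpretation ranges from fully located (an NMR feature showing
¹³C at carbon 1) to purely compositional (an MS feature resolving only
"three extra neutrons"). A faithful identifier therefore has to express a
*set of isotopomers* at a declared level of ambiguity. This package
models that as two layers over an immutable standard-InChI skeleton:

* `/i` entries pin isotopes to canonically numbered atoms. Crucially the
  layer is read non-minimalistically: an atom without an entry has
  **unknown** isotopic status. An explicit `+0` shift therefore carries
  information ("this atom is the default isotope"), and an *exact*
  isotopomer requires a shift on every heavy atom plus explicit
  protium/deuterium/tritium counts covering every hydrogen.
* `/a` groups describe ambiguous placement. Isotope-resolved groups
  denote "k atoms of element E carry isotope (rounded-average-mass +
  shift)"; neutron groups denote a total extra-neutron count; either may
  confine the ambiguity to a candidate atom list (a *fragment*).

## Conventions the grammar leaves open

The layer grammar was fixed here as: each group in its own parentheses,
concatenated without separators (`/a(C1+1)(O1+2)`); inside a group the
element code, the isotope count, a mandatorily signed shift, then an
optional comma-separated ascending candidate list; neutron groups are
`<count>n` plus an optional list. Canonical emission sorts `/i` entries
by atom number (shift before hydrogen tokens, H→D→T, counts omitted when
1), isotope groups before neutron groups (carbon first, then
alphabetical, then ascending shift), and drops a candidate list that
covers every atom the group would range over anyway. One canonical text
per model makes string equality usable as semantic equality after
normalization.

Hydrogens are unnumbered in InChI, so candidate atoms for hydrogen
groups name the **bearer** heavy atoms. Mobile (exchangeable) hydrogens
— the `(H,3,4)` constructs of the `/h` layer, plus the `/i .../h`
isotope sub-layer the reference implementation emits for them (e.g.
water-d1 `InChI=1S/H2O/h1H2/i/hD`) — are pooled into a single site:
labile hydrogens interchange, so positions inside the pool are not
distinct. Fixed-H (`/f`) and reconnected (`/r`) scopes are retained
opaquely; isotope entries inside them are out of scope, as are
multi-component formulas.

## Two integer-mass baselines

Isotope designations are offsets from the element's **rounded average
atomic mass** (C+1 → ¹³C, O+2 → ¹⁸O), while neutron counts are measured
against the **most abundant stable isotope**. The baselines coincide for
H/C/N/O/P/S but differ for Cu, Zn, Se and Br in the vendored table
(e.g. Br: 79.904 rounds to 80 while the most common isotope is ⁷⁹Br).
Both are kept explicit (`designation_to_mass_number` vs
`neutron_excess`); which baseline a future standard would prescribe for
the discrepant elements is genuinely open, so the discrepancy list is
exposed and tested rather than resolved. A designation landing on no
tabulated nuclide parses and carries through with a warning — the
grammar permits arbitrary shifts, and rejecting them would conflate
syntax with nuclide bookkeeping.

Nuclide masses/abundances are vendored from the NIST/CODATA compilation
as `nuclides.tsv` (20 elements, stable isotopes plus tritium and ¹⁴C);
the table is overridable by a user TSV of the same shape. Radioisotope
decay data and isotope-pattern intensities are non-goals.

## Validation and the ambiguity boundary

Rules R1–R8 (stable codes, machine-readable report): R1 atom numbers in
range; R2 candidates match the group element / bear hydrogen; R3 the
boundary rule; R4 counts within candidates/capacity; R5 formula-only
strings reference no atoms; R6 joint `/i`+`/a` consistency (totals
within the formula; pinned atoms excluded from candidate sets — the two
layers are complementary, never overlapping); R7 neutron counts
achievable with stable isotopes; R8 no duplicate atoms within a layer.

R3 encodes the rule that `/a` is only for genuinely ambiguous placement:
a group whose count equals its effective candidate count (candidate list
size, or the element's unpinned atom total, or the full hydrogen
capacity) pins every candidate and must be written in `/i`. R3 findings
are errors but carry a `suggested_rewrite`, so pipelines can run strict
or fix-up. Normalization merges identical groups, drops redundant
candidate lists, demotes R3 groups into `/i`, and iterates to a fixpoint
(merging can create new boundary cases); it is idempotent by
construction and tested as such.

`semantic_equal` is normalize-then-compare-canonical-text, verified in
the tests against explicit isotopomer-set enumeration.

## Counting convention and algorithms

Isotopomers are counted over labeled canonical atom numbers **without
molecular-symmetry reduction** — ethane's two topologically equivalent
carbons count separately, giving the two-isotopomer mono-deuteroethane
convention the layer semantics itself implies. Chemists expecting
automorphism-reduced counts should divide by the relevant orbit sizes
themselves; the package deliberately does not.

Closed forms are used where groups are independent: binomial
coefficients per heavy-element group over disjoint candidate sets,
a sliding-window dynamic program for bounded compositions of hydrogen
counts over site capacities, and composition sums (expansion ×
placement multinomials) for a lone neutron group. When same-element
candidate sets overlap, or neutron groups mix with isotope groups, the
count falls back to exact deduplicated enumeration of assignments; the
explicit enumerator (`enumerate_isotopomers`) is an independent
itertools-based construction, so count-vs-enumeration agreement is a
meaningful cross-check rather than a tautology, and is asserted corpus-
wide in the tests. Enumeration order is lexicographic over the sorted
(atom, shift) assignment, deterministic by construction; `pinned` mode
writes only the specified content, `exact` mode additionally writes
every default isotope explicitly (and thus classifies as exact
isotopomers).

Nominal-mass expansion solves the bounded integer equation
Σ countᵢ·excessᵢ = n over the stable non-default nuclides of the formula
(defaulting to stable isotopes only; overridable), with interval pruning
so that negative excesses (⁷⁴Se etc.) are handled correctly. Infeasible
n returns an empty set; n < 1 is refused. A neutron-group candidate
list may mix elements — a neutron is element-agnostic.

## Synthetic corpus

The fixture generator emulates an annotation workload over seven small
metabolite skeletons (ethane, propane, water, acetate — vendored in its
neutral acid form so formula and skeletal hydrogen counts agree —
glycerol, alpha-D-glucopyranose, glucosamine 6-phosphate) whose standard
InChI strings are vendored constants cross-checked once against the
reference implementation; canonical numbering is never computed here.
Kinds are drawn per configurable weights (all equal by default) across
the eight taxonomy categories plus deliberate R3 boundary cases; isotope
counts are bounded at 3 per group and neutron counts at 4 — the range
typical of ¹³C/¹⁵N/²H tracer studies, and small enough that every
fixture's isotopomer set is explicitly enumerable. Each fixture carries
by-construction ground truth (category; expected count where the
construction determines one — binomials for heavy-atom groups, direct
bounded-composition recursion for hydrogen groups; expected findings),
and one seeded stream makes corpora bit-reproducible.

What the corpus does **not** emulate: real repository data (multi-
component salts, charged/protonated skeletons with `/p`, isotopes inside
`/f`/`/r` scopes, radioisotopes, exotic elements). Passing corpus tests
therefore demonstrates the layer semantics and combinatorics on clean
single-component skeletons, not robustness to the full variety of
deposited InChI strings.

## Problem sizes and numerical choices

The shipped test-suite and acceptance script use corpora of 200–1000
fixtures and cap oracle cross-checks at 10⁵ isotopomers per fixture —
sizes chosen so the full double-route verification (closed form vs
explicit enumeration) stays exhaustive over every generated case.
Exact masses are plain float sums (≤ ~10⁻⁶ Da rounding, well below the
10⁻⁴ Da differences that matter here). Stereo layers are retained
opaquely; the only stereo-aware behaviour is a *flag* (not a category
change) when deuterium/tritium entries coexist with an absent `/t`
layer, since an incompletely specified stereocentre bearing D can hide
positional ambiguity. The flag is conservative: molecules whose standard
InChI has no stereo layer at all (ethane) also flag.

## Known limitations

* Atom numbering is taken from the input string by the carbons-first-
  then-alphabetical convention; it is asserted, not recomputed, and
  structures where the reference numbering deviates are out of scope.
* Formula-only strings support classification, validation and
  composition-level operations but refuse isotopomer counting (no atom
  structure exists to count over).
* `/h`-layer parsing is lenient: an unrecognized hydrogen-layer construct
  leaves capacities unknown rather than failing, which disables
  hydrogen-related semantic checks for that string.
* Tautomer-aware equivalence and interpretation of `/b`, `/t`, `/m`,
  `/s` beyond opaque retention are non-goals.
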