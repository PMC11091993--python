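# isoinchi

Parse, validate, classify and reason over **extended InChI strings** that
describe isotopically resolved chemical entities at varying levels of
positional ambiguity — the annotation problem at the heart of stable
isotope-resolved metabolomics (SIRM), where NMR features pin isotopes to
specific atoms while mass-spectrometry features usually only resolve an
isotopologue or its nominal mass.

The package implements two layer semantics on top of the standard InChI
skeleton (which is retained opaquely and never recomputed):

* **Isotopic layer `/i`** — per-atom isotope designations, read under the
  *partial isotopomer* interpretation: atoms without an entry are
  **unknown**, not defaulted. An entry gives the InChI canonical atom
  number, a signed unit-mass shift from the element's rounded average
  atomic mass (`1+1` = ¹³C at atom 1; `+0` is legal and means "explicitly
  the default isotope") and/or explicit hydrogen isotopes (`H`/`D`/`T`
  with counts). A string is an *exact isotopomer* only when every heavy
  atom carries a shift and every hydrogen is explicitly assigned.
* **Isotopologue layer `/a`** — parenthesized groups for *ambiguous*
  isotope location:
  * `(C2+1)` — two ¹³C somewhere among the carbons (an isotopologue);
  * `(C1+1,1,2,3)` — one ¹³C confined to atoms 1–3 (an isotopologue
    fragment, the tandem-MS case);
  * `(3n)` — three extra neutrons relative to the most abundant stable
    isotopes (a nominal-mass isotopologue); `(4n,1,2,3,4,5,6)` confines
    them to listed atoms;
  * `InChI=1S/C6H12O6/a(C1+1)` — formula-only form for an unknown
    constitutional isomer.

On top of the codec the library provides the taxonomy classifier
(unlabeled / exact / partial isotopomer / isotopologue (fragment) /
nominal-mass (fragment) / formula-only), a validator with stable rule
codes **R1–R8** — including the boundary rule that a group whose isotope
count equals its candidate count is *not* ambiguous and is rewritten into
`/i` — a canonical normalizer, isotopomer **counting and enumeration**
(binomial/bounded-composition closed forms, cross-checked against explicit
enumeration), nominal-mass **expansion** into isotopologue compositions,
exact-mass arithmetic over a vendored NIST nuclide table, and a seeded
synthetic-corpus generator.

Counting is over labeled canonical atom numbers without symmetry
reduction: ¹²C₂¹H₅²H (mono-deuteroethane) has **two** isotopomers — one
per bearer carbon — and ¹²C₂¹H₆ has one.

## Worked example

```python
>>> from isoinchi import parse, classify, validate, count_isotopomers, \
...     enumerate_isotopomers, emit
>>> glc = ("InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2"
...        "/h2-11H,1H2/t2-,3-,4+,5-,6+/m1/s1")     # alpha-D-glucopyranose
>>> x = parse(glc + "/a(C2+1)")                     # two 13C, location unknown
>>> classify(x).category.value
'isotopologue'
>>> count_isotopomers(x)                            # C(6,2) placements
15
>>> [emit(m) for m in enumerate_isotopomers(parse(glc + "/a(C1+1)"))][:2]
['InChI=1S/C6H12O6/.../i1+1', 'InChI=1S/C6H12O6/.../i2+1']
```

The boundary rule in action — glucosamine 6-phosphate has a single
nitrogen, so "one ¹⁵N somewhere" is not ambiguous:

```bash
$ echo 'InChI=1S/C6H14NO8P/.../a(N1+1)' | isoinchi validate
{"findings": [{"rule_code": "R3", "severity": "error", ...}],
 "suggested_rewrite": "InChI=1S/C6H14NO8P/.../i7+1"}
```

The CLI exposes the whole pipeline:
`isoinchi parse|validate|classify|normalize|count|enumerate|expand|mass|fixtures`,
reading one InChI per line (or a TSV with an `inchi` column) and writing
one JSON record per input; `--strict` exits 1 on any error finding,
distinct from the usage-error exit code 2.

```bash
$ isoinchi expand --formula H2O --n 2
{"composition": {"H": {"1": 2}, "O": {"18": 1}}, "monoisotopic_mass": 20.01481, "neutron_count": 2}
...
```

## Layout

- `src/isoinchi/isotope_data.py` — nuclide table, designation/neutron
  baselines, exact masses
- `src/isoinchi/inchi_codec.py` — layer grammar, parser, canonical emitter
- `src/isoinchi/layer_semantics.py` — taxonomy, rules R1–R8, normalizer
- `src/isoinchi/iso_combinatorics.py` — counting, enumeration, expansion
- `src/isoinchi/fixtures.py`, `cli.py` — corpus generator and `isoinchi` CLI
- `docs/methods.md` — model, conventions and design choices in detail
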