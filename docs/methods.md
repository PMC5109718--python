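# Methods

This note records the model behind each pipeline stage, the parameters
that matter, the synthetic-data design, and the numerical/design choices
made where the design was genuinely open.

## Text normalization and matching

Dictionary terms (class labels and synonyms, all scopes by default) and
sentence text pass through the same normalizer: lowercase, split on
non-word characters, drop stopwords, stem each token. English uses the
classic Porter algorithm; French uses a light in-package suffix stripper
(plural `-s/-x`, `-aux → -al`, final mute `-e`). Stemming is applied to a
fixpoint and the stopword filter re-applied afterwards, which makes
`normalize` idempotent (stemming can create a stopword: "ase" → "as").
A `--no-stem` switch disables stemming on both sides simultaneously.

Two deliberate omissions from the stopword lists: copulas
(*is/are/est/sont*) and the clause-linking prepositions (*with/avec*).
The attributive filter operates on the normalized token stream, so these
words must survive as tokens — dropping "with" would make "red with
yellow stamens" look like "red" premodifying "stamens".

Matching is exact on normalized token sequences, longest-match-first and
left-to-right within each dictionary, multi-token entries contiguous.
There is no edit-distance fallback: a text "truncated" does not match a
term "truncate" unless the stemmer conflates them, and a bare "ovule"
does not match a class labelled "plant ovule" that lacks the synonym.
These miss modes are real properties of exact lexical matching and the
fixtures reproduce them on purpose.

French support is dictionary-based: every English label/synonym with a
glossary translation contributes a French entry; the document text itself
is never translated. The glossary is a two-column TSV
(`foreign<TAB>english`, no header).

## Sentence segmentation and the attributive heuristic

Sentences split on `. ; ! ?` with protection for measurement and
botanical abbreviations (`cm.`, `var.`, `diam.`, single-letter initials)
and for decimal points. The rule list is small, fixed and shipped with
the package.

Whether a quality is attributive to an entity is decided by a three-rule
heuristic rather than a dependency parse:

1. a quality directly adjacent to an entity (pre- or post-modifier)
   binds to that entity, *exclusively* — adjacency elsewhere vetoes a
   non-adjacent candidate;
2. otherwise the quality attaches to the nearest preceding entity with
   no other entity match in between;
3. copula constructions ("The flowers are red") are covered by rule 2
   because copulas are ordinary non-entity tokens.

The exclusivity in rule 1 is what rejects (flower, yellow) in "The
flowers are red with yellow stamens": "yellow" premodifies "stamens".
Rule 2 is also this package's answer to the open question of pairs
spanning clause boundaries ("flowers red; leaves ovate" splits at the
semicolon and never interacts). The heuristic is a plain callable on
`(tokens, entity_span, quality_span, all_entity_spans)` and can be
swapped for a real parser.

Qualities under a configurable relational-quality root describe ternary
relations (connectivity between two structures); their records carry a
placeholder flag stating only that the structure is related to
*something*, and contribute grouping classes but no value/trait classes.

## Axiom patterns

For each mined pair (E, Q):

* grouping: `'E phenotype' ≡ ∃has-part.(∃part-of.E ⊓ ∃has-quality.quality)`
* character state: `'E Q' ≡ ∃has-part.(E ⊓ ∃has-quality.Q)`
* character: for each most-specific attribute-slim superclass T of a
  value-slim Q, `'E T' ≡ ∃has-part.(E ⊓ ∃has-quality.T)`

The `has-part` prefix makes classes describe whole organisms, so "flower
red" ⊓ "stamen yellow" stays satisfiable even though flower and stamen
are disjoint. The grouping pattern wraps E in `part-of` (reflexive,
transitive), so grouping classes organize themselves along anatomical
parthood; the EQ patterns bind E directly because the traits of the
parts are not traits of the whole.

Promotion uses entailed subsumption on the quality ontology alone and
returns the set of *minimal* attribute-slim superclasses: "most specific"
is singular in the common case but hierarchies permit ties, in which case
one character class per minimal attribute is generated. A quality already
in the attribute slim is its own promotion. EQ classes are tagged by the
quality's own level — attribute-slim quality ⇒ `trait`, anything else ⇒
`value` — so a directly mined attribute pair and a promoted one collapse
into a single class rather than duplicating "flower color".

The impossible-combination filter is a general concept inclusion:

```
structure_root ⊓ ∃has-quality.process_quality_root ⊑ ⊥
```

EL-expressible, and sufficient to make every generated class whose
quality is process-only unsatisfiable (Bottom propagates back through
the `has-part` existential). After classification such classes are
stripped of their definitions, marked `owl:deprecated`, listed in the
deprecation report, and their identifiers are never reused. An externally
supplied deprecation list (one CURIE per line) is honored the same way.

Identifiers are zero-padded 7-digit CURIEs in a configurable namespace
(default `FLOPO`), assigned in lexicographic order of (pattern, entity
label, quality label) starting at `id_start` (default 1); a persisted
id-map TSV keeps ids stable across re-runs, with new classes appended.
Original published numeric ids are not reproduced — they depend on an
unrecoverable build order — so label-level agreement is the contract.
The optional `inheres-in` transform rewrites every generated definition's
right side X to `∃inheres-in.X`, making the classes subclasses of
quality; it is off by default and verified (by test and acceptance run)
to leave the subsumption DAG among generated classes unchanged.

## The EL reasoner

Normalization introduces fresh names for nested expressions, defined by
equivalences in both directions (a conservative extension over the input
signature), binarizes conjunctions, splits equivalences, and encodes
transitivity as the self-chain `r∘r ⊑ r`. Saturation is a worklist
fixpoint over the standard completion rules (R1–R8 in
`reasoner.py`'s module docstring), with axioms indexed by left-hand
atoms. The reflexive-role rule runs for every initialized name,
*including fresh ones* — that is required for the value-class ⊑
grouping-class inference. Disjointness is encoded as pairwise
conjunction-to-Bottom inclusions. `part-of` and `has-part` are modeled as
independent roles (no inverse reasoning; the patterns never rely on
inverse entailment).

Classification derives equivalence groups as strongly connected
components of the entailed subsumption relation, a transitively reduced
DAG of direct edges between groups (via networkx), and the unsatisfiable
set {X : ⊥ ∈ S(X)}. DL queries insert a fresh name defined equivalent to
the expression into a copy of the ontology, re-saturate, and report
neighbors among the original named classes; the query name never leaks.
Unsatisfiable queries are flagged and report the Bottom-equivalent named
classes as their equivalents.

Correctness is checked two ways: targeted entailment tests, and a
dual-route comparison against a brute-force oracle
(`tests/oracle_el.py`) — an independent naive fixpoint with its own
normalizer — over seeded random EL ontologies (≤ 40 classes, ≤ 4 roles,
≤ 60 axioms, 100 seeds; runs in a few seconds).

## Synthetic fixtures: what they emulate and what they do not

The mini structure ontology (12 classes) models a parthood chain (petal,
androecium ⊑ ∃part-of.flower; stamen ⊑ ∃part-of.androecium; petiole ⊑
∃part-of.leaf), reflexive+transitive `part_of`, a flower/stamen
disjointness, and the "plant ovule" class without an "ovule" synonym.
The mini quality ontology (15 classes) models attribute/value slims, the
deep-pink ⊑ pink ⊑ color chain, a process-quality branch (acute) in no
slim, and a relational-quality branch (connected).

Corpora are realized from templates, one per syntactic construction
(premodifier, postmodifier, copula, and the interleaved two-pair form
"The flowers are red with yellow stamens."), so every sentence's truth
status is known by construction; interleaved sentences additionally
record their two cross-pairings as guaranteed negatives. French
sentences use glossary terms with postnominal adjectives. Entity plurals
use `label + "s"` only when the plural stems back to the label's own stem
(hence the synthetic "leafs" — Porter sends "leaves" elsewhere, and the
generator must not plant pairs the exact matcher provably cannot
recover). Distractor sentences contain no dictionary terms.

Default generation parameters: 20 taxa, 3 planted sentences per taxon
drawn from a 9-pair pool covering every construction and one
relational-quality pair, distractor rate 0.3, French fraction 0.25, 2
process-quality pairs, seed 42. These sizes keep every property
measurable (each construction, both languages, exclusions, placeholders
all occur) while a run stays instantaneous; the acceptance script scales
the same generator to 200 taxa.

What the fixtures do *not* emulate: OCR noise, telegraphic flora
ellipsis, vocabulary outside the mini-ontologies, French syntax beyond
the glossary path, and the sheer scale and ambiguity of real floras.
Passing tests therefore demonstrate the machinery (recall 1.0 on
unambiguous constructions, zero cross-attachments on guaranteed
negatives, exact class counts), not expected precision/recall on real
text, where the known miss modes above apply.

## Degenerate inputs and determinism

Empty corpora, empty record lists, all-stopword terms, unknown subset
tags and empty ontologies all yield empty-but-valid outputs; an unknown
document language or an unresolvable configured path is an error, as is
a persisted id map assigning one id to two keys. Every writer sorts its
output (prefixes, declarations, annotations, axioms, TSV rows), mining is
order-invariant (set semantics with a total sort), and the builder
iterates records in sorted order, so `run` twice on the same inputs is
byte-identical — the end-to-end determinism the test suite and acceptance
script both verify. The pipeline uses randomness only inside the fixture
generator, always behind an explicit seed.

## Known limitations

* The attributive heuristic has no notion of coordination ("flowers and
  leaves green") or long-range dependencies; a real dependency parser can
  be plugged in where higher precision is needed.
* The French stemmer is intentionally shallow; irregular plurals and
  derivational morphology are out of scope.
* The reasoner covers exactly the EL fragment the patterns need — no
  nominals, concrete domains, range restrictions or ABox.
* OBO output keeps only the OBO-expressible part of the logic (is_a,
  simple relationships, genus-differentia definitions, disjointness);
  the functional-syntax output is the full-fidelity serialization.
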