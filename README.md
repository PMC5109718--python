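# florapheno

Floras — the reference works describing every plant species of a region —
hold an enormous amount of morphological trait information, but only as
free text ("The flowers are red with yellow stamens."). **florapheno**
turns such taxon descriptions into a classified phenotype ontology. It is
aimed at biodiversity informaticians and ontology engineers who want to
standardize trait descriptions across floras, herbaria and trait
databases.

The pipeline has four stages:

1. **Mining.** Descriptions are split into sentences and matched against
   dictionaries built from a structure ontology (plant anatomy, with
   parthood relations — e.g. the Plant Ontology) and a quality ontology
   (attributes like *color* and values like *red*, distinguished by slim
   subset tags — e.g. PATO). Matching uses the same normalization on both
   sides (lowercasing, stopword removal, Porter stemming; French via a
   bilingual glossary). A co-occurring (entity, quality) pair is kept only
   if an adjacency/copula heuristic finds the quality *attributive* to the
   entity: from the sentence above, (flower, red) and (stamen, yellow)
   survive and the two cross-pairings are rejected.

2. **Generation.** Each mined entity–quality (EQ) pair (E, Q) is compiled
   into OWL 2 EL classes via three axiom patterns, each prefixed with
   `has-part some` so a class describes the whole organism bearing the
   phenotype:

   ```
   'E phenotype' EquivalentTo: has-part some ((part-of some E) and has-quality some quality)
   'E Q'         EquivalentTo: has-part some (E and has-quality some Q)
   'E T'         EquivalentTo: has-part some (E and has-quality some T)
   ```

   where T is the most specific attribute-slim superclass of a value-slim
   Q (red → color). One further axiom sends any structure bearing a
   process-only quality to `owl:Nothing`, so impossible combinations
   (e.g. *leaf* + the process sense of *acute*) classify as unsatisfiable
   and are deprecated instead of published.

3. **Classification.** A built-in EL completion-rule reasoner (conjunction,
   existentials, role hierarchies, role chains/transitivity, reflexive
   roles, Bottom) saturates the axioms. Because `part-of` is reflexive and
   transitive, *petal phenotype* and *stamen phenotype* become subclasses
   of *flower phenotype*, and *flower red* falls under *flower color*
   under *flower phenotype*: the primary axis of the hierarchy is plant
   anatomy.

4. **Annotation.** Each taxon is linked to its value, trait and grouping
   classes with sentence-level evidence.

Classified ontologies also answer DL queries: an expression such as
`has-part some (flower and has-quality some 'deep pink')` resolves to its
closest named classes even when no class for it exists.

## Worked example

Generate the bundled synthetic fixtures (mini plant-anatomy and quality
ontologies, a French/English glossary, and a 20-taxon template corpus
with known ground truth), then run the whole pipeline:

```bash
florapheno fixtures --out demo --seed 42
florapheno run -c demo/config.yaml
```

which prints

```json
{
  "annotation": {"dropped": 2, "rows": 172},
  "classification": {"direct_edges": 41, "groups": 48, "unsatisfiable": 0},
  "generation": {
    "by_pattern": {"phenotype": 6, "trait": 6, "value": 7},
    "excluded_unsatisfiable": 2,
    "externally_deprecated": 0,
    "generated_classes": 19
  },
  "mining": {
    "distinct_entities": 6, "distinct_pairs": 10, "distinct_qualities": 8,
    "n_candidates": 68, "n_documents": 20, "n_filtered_out": 4,
    "n_placeholder_records": 8, "n_records": 64, "n_sentences": 82,
    "n_taxa": 20
  }
}
```

Reading this: 82 sentences over 20 taxa yielded 68 co-occurrence
candidates, of which 4 failed the attributive filter; the 10 distinct EQ
pairs compiled into 19 classes (6 grouping, 7 character-state, 6
character classes). Two classes ("leaf acute", "stem acute") used a
process-only quality, classified as unsatisfiable, and were deprecated;
the 2 annotation rows pointing at them were dropped. The artifacts
(`built.ofn`, `built.obo`, `taxonomy.tsv`, `annotations.tsv`,
`eq_records.tsv`, `id_map.tsv`, `summary.json`) land in `demo/out/`.

Query the built ontology for a flower being deep pink — a class that was
never generated:

```bash
florapheno query --ontology demo/out/built.ofn --expression \
  "ObjectSomeValuesFrom(obo:has_part ObjectIntersectionOf(PO:0009046 \
   ObjectSomeValuesFrom(obo:has_quality PATO:0002710)))"
```

```json
{
  "direct_superclasses": ["FLOPO:0000013"],
  "labels": {"FLOPO:0000013": "flower pink"},
  "satisfiable": true, "equivalents": [], "direct_subclasses": []
}
```

*flower pink* is the closest matching class, because *deep pink* is a
subclass of *pink* in the quality ontology.

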