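"""Synthetic mini-ontologies, bilingual glossary and flora-style corpora.

Everything here is generated from templates so the truth status of every
sentence is known by construction: the corpus generator records exactly
which entity-quality pairs were planted (and in which syntactic
construction), which cross-pairings are guaranteed *not* to be
attributive, and which planted pairs use process-only qualities and must
therefore classify as unsatisfiable.  That bookkeeping is what mining
recall/precision and generation counts are measured against.

The structure ontology models a small plant-anatomy parthood hierarchy
(petal and androecium part of flower, stamen part of androecium, petiole
part of leaf; part-of reflexive and transitive; flower and stamen
disjoint).  The quality ontology models attribute/value slims (color,
shape, size vs. red, yellow, pink, deep pink, ovate, undulate, large), a
process-quality branch (acute — a quality of processes, the classic
text-mining artifact) and a relational-quality branch (connected).  The
class "plant ovule" deliberately has no synonym "ovule", reproducing a
known exact-matching miss.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .lexicon import Glossary
from .mining import TaxonDocument
from .model import Ontology, some
from .patterns import PatternConfig

# -- well-known fixture ids -------------------------------------------------

STRUCTURE_ROOT = "PO:0025131"
FLOWER = "PO:0009046"
PETAL = "PO:0009032"
STAMEN = "PO:0009029"
ANDROECIUM = "PO:0009061"
LEAF = "PO:0025034"
PETIOLE = "PO:0020038"
ROOT = "PO:0009005"
STEM = "PO:0009047"
SEED = "PO:0009010"
PLANT_OVULE = "PO:0020003"
FRUIT = "PO:0009001"

QUALITY_ROOT = "PATO:0000001"
COLOR = "PATO:0000014"
SHAPE = "PATO:0000052"
SIZE = "PATO:0000117"
RED = "PATO:0000322"
YELLOW = "PATO:0001323"
PINK = "PATO:0000954"
DEEP_PINK = "PATO:0002710"
OVATE = "PATO:0001324"
UNDULATE = "PATO:0000967"
LARGE = "PATO:0000586"
PROCESS_QUALITY = "PATO:0001236"
ACUTE = "PATO:0000389"
RELATIONAL_QUALITY = "PATO:0001452"
CONNECTED = "PATO:0001557"

ATTRIBUTE_SLIM = "attribute_slim"
VALUE_SLIM = "value_slim"

# value -> its attribute; the generator's own ground-truth promotion table,
# independent of the reasoner-based promotion it is later checked against
VALUE_ATTRIBUTE = {
    RED: COLOR, YELLOW: COLOR, PINK: COLOR, DEEP_PINK: COLOR,
    OVATE: SHAPE, UNDULATE: SHAPE, LARGE: SIZE,
}


def fixture_pattern_config() -> PatternConfig:
    return PatternConfig(
        has_part_role="has_part", part_of_role="part_of",
        has_quality_role="has_quality", inheres_in_role="inheres_in",
        structure_root=STRUCTURE_ROOT, quality_root=QUALITY_ROOT,
        process_quality_root=PROCESS_QUALITY,
        relational_quality_root=RELATIONAL_QUALITY,
        attribute_subset_tag=ATTRIBUTE_SLIM, value_subset_tag=VALUE_SLIM)


def make_mini_structure_ontology() -> Ontology:
    o = Ontology()
    o.add_role("part_of", transitive=True, reflexive=True).label = "part of"
    o.add_role("has_part").label = "has part"
    names = {
        STRUCTURE_ROOT: "plant anatomical entity",
        FLOWER: "flower", PETAL: "petal", STAMEN: "stamen",
        ANDROECIUM: "androecium", LEAF: "leaf", PETIOLE: "petiole",
        ROOT: "root", STEM: "stem", SEED: "seed",
        PLANT_OVULE: "plant ovule",  # deliberately no synonym "ovule"
        FRUIT: "fruit",
    }
    for cid, label in names.items():
        o.add_class(cid, label=label)
        if cid != STRUCTURE_ROOT:
            o.subclass_of(cid, STRUCTURE_ROOT)
    o.classes[FLOWER].synonyms.add(("blossom", "related"))
    for part, whole in ((PETAL, FLOWER), (ANDROECIUM, FLOWER),
                        (STAMEN, ANDROECIUM), (PETIOLE, LEAF)):
        o.subclass_of(part, some("part_of", whole))
    o.disjoint(FLOWER, STAMEN)
    return o


def make_mini_quality_ontology() -> Ontology:
    o = Ontology()
    o.add_role("has_quality").label = "has quality"
    entries = [
        # (id, label, parent, subset)
        (QUALITY_ROOT, "quality", None, None),
        (COLOR, "color", QUALITY_ROOT, ATTRIBUTE_SLIM),
        (SHAPE, "shape", QUALITY_ROOT, ATTRIBUTE_SLIM),
        (SIZE, "size", QUALITY_ROOT, ATTRIBUTE_SLIM),
        (RED, "red", COLOR, VALUE_SLIM),
        (YELLOW, "yellow", COLOR, VALUE_SLIM),
        (PINK, "pink", COLOR, VALUE_SLIM),
        (DEEP_PINK, "deep pink", PINK, VALUE_SLIM),
        (OVATE, "ovate", SHAPE, VALUE_SLIM),
        (UNDULATE, "undulate", SHAPE, VALUE_SLIM),
        (LARGE, "large", SIZE, VALUE_SLIM),
        (PROCESS_QUALITY, "process quality", QUALITY_ROOT, None),
        (ACUTE, "acute", PROCESS_QUALITY, None),
        (RELATIONAL_QUALITY, "relational quality", QUALITY_ROOT, None),
        (CONNECTED, "connected", RELATIONAL_QUALITY, None),
    ]
    for cid, label, parent, subset in entries:
        meta = o.add_class(cid, label=label)
        if parent:
            o.subclass_of(cid, parent)
        if subset:
            meta.subsets.add(subset)
    o.classes[RED].synonyms.add(("reddish", "broad"))
    return o


def make_glossary() -> Glossary:
    pairs = {
        ("fleur", "flower"), ("pétale", "petal"), ("étamine", "stamen"),
        ("androcée", "androecium"), ("feuille", "leaf"),
        ("pétiole", "petiole"), ("racine", "root"), ("tige", "stem"),
        ("graine", "seed"), ("fruit", "fruit"), ("ovule", "plant ovule"),
        ("rouge", "red"), ("jaune", "yellow"), ("rose", "pink"),
        ("rose foncé", "deep pink"), ("ovale", "ovate"),
        ("ondulé", "undulate"), ("grand", "large"), ("couleur", "color"),
        ("forme", "shape"), ("taille", "size"), ("aigu", "acute"),
        ("connecté", "connected"),
    }
    return Glossary(pairs=set(pairs))


# ---------------------------------------------------------------------------
# Corpus generation


CONSTRUCTIONS = ("premod", "postmod", "copula", "interleaved")

DEFAULT_PLANTED = [
    (FLOWER, RED, "copula"),
    (PETAL, RED, "premod"),
    (STAMEN, YELLOW, "premod"),
    (LEAF, OVATE, "postmod"),
    # "pink", not "deep pink": leaving the deep-pink value unmined keeps the
    # built ontology without a "flower deep pink" class, so the DL-query
    # example can resolve the expression to "flower pink" as closest match
    (FLOWER, PINK, "copula"),
    (STEM, LARGE, "copula"),
    (PETIOLE, UNDULATE, "postmod"),
    (FLOWER, RED, "interleaved"),
    (STEM, CONNECTED, "copula"),     # relational-quality placeholder
]

# partners for the interleaved construction; chosen so the partner never
# shares entity or quality with the primary pair
_INTERLEAVED_PARTNERS = [(STAMEN, YELLOW), (PETAL, UNDULATE), (SEED, LARGE)]

_PROCESS_ENTITIES = [LEAF, STEM, PETAL, FRUIT, SEED, ROOT]

_DISTRACTORS = {
    "en": ["Widespread in lowland forest.",
           "Occurs on rocky slopes near streams.",
           "Common throughout much of the region."],
    "fr": ["Répandu en forêt humide.",
           "Commun presque partout."],
}


@dataclass
class FixtureSpec:
    n_taxa: int = 20
    n_sentences_per_taxon: int = 3
    planted_pairs: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_PLANTED))
    distractor_rate: float = 0.3
    french_fraction: float = 0.25
    process_quality_pairs: int = 2
    seed: int = 42

    def __post_init__(self):
        if not 0 <= self.distractor_rate <= 1:
            raise ValueError("distractor_rate must be in [0, 1]")
        if not 0 <= self.french_fraction <= 1:
            raise ValueError("french_fraction must be in [0, 1]")
        if min(self.n_taxa, self.n_sentences_per_taxon,
               self.process_quality_pairs) < 0:
            raise ValueError("counts must be >= 0")
        for e, q, c in self.planted_pairs:
            if c not in CONSTRUCTIONS:
                raise ValueError(f"unknown construction {c!r}")


@dataclass
class GroundTruth:
    expected_eq: set[tuple[str, str, str]] = field(default_factory=set)
    guaranteed_negatives: set[tuple[str, str, str]] = field(default_factory=set)
    placeholder_pairs: set[tuple[str, str, str]] = field(default_factory=set)
    expected_generated_class_count_by_pattern: dict[str, int] = field(
        default_factory=dict)
    expected_unsat: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps({
            "expected_eq": sorted(map(list, self.expected_eq)),
            "guaranteed_negatives": sorted(map(list, self.guaranteed_negatives)),
            "placeholder_pairs": sorted(map(list, self.placeholder_pairs)),
            "expected_generated_class_count_by_pattern":
                self.expected_generated_class_count_by_pattern,
            "expected_unsat": sorted(self.expected_unsat),
        }, indent=2, sort_keys=True)


class _Realizer:
    """Turns (entity, quality, construction) into a sentence in one
    language, guaranteeing the planted pair is attributive and (for
    interleaved) that the cross pairings are not."""

    def __init__(self, structure_ont: Ontology, quality_ont: Ontology,
                 glossary: Glossary):
        from .lexicon import normalize
        self._normalize = normalize
        self.labels = {}
        for onto in (structure_ont, quality_ont):
            for cid, meta in onto.classes.items():
                self.labels[cid] = meta.label or cid
        self.french = {}
        for foreign, english in glossary.pairs:
            self.french.setdefault(english.lower(), foreign)

    def _en_plural(self, cid: str) -> str:
        label = self.labels[cid]
        plural = label + "s"
        if self._normalize(plural, "en") == self._normalize(label, "en"):
            return plural
        return label

    def _fr(self, cid: str) -> str:
        return self.french.get(self.labels[cid].lower(), self.labels[cid])

    def _fr_plural(self, cid: str) -> str:
        term = self._fr(cid)
        return " ".join(w + "s" if not w.endswith(("s", "x")) else w
                        for w in term.split())

    def sentence(self, entity: str, quality: str, construction: str,
                 language: str, partner: tuple[str, str] | None = None) -> str:
        if language == "fr":
            e, q = self._fr_plural(entity), self._fr_plural(quality)
            if construction == "interleaved":
                e2, q2 = (self._fr_plural(partner[0]),
                          self._fr_plural(partner[1]))
                return f"Les {e} sont {q} avec des {e2} {q2}."
            if construction == "copula":
                return f"Les {e} sont {q}."
            # French adjectives are postnominal; premod and postmod both
            # realize as adjacency after the noun
            return f"Les {e} {q}, glabres."
        e = self._en_plural(entity)
        q = self.labels[quality]
        if construction == "premod":
            return f"The {q} {e} are conspicuous."
        if construction == "postmod":
            return f"{e.capitalize()} {q}, glabrous."
        if construction == "copula":
            singular = e == self.labels[entity]
            return f"The {e} {'is' if singular else 'are'} {q}."
        e2 = self._en_plural(partner[0])
        q2 = self.labels[partner[1]]
        return f"The {e} are {q} with {q2} {e2}."


def make_corpus(spec: FixtureSpec,
                structure_ont: Ontology | None = None,
                quality_ont: Ontology | None = None,
                glossary: Glossary | None = None
                ) -> tuple[list[TaxonDocument], GroundTruth]:
    """Template-realized corpus plus its ground truth, reproducible from
    the seed."""
    structure_ont = structure_ont or make_mini_structure_ontology()
    quality_ont = quality_ont or make_mini_quality_ontology()
    glossary = glossary or make_glossary()
    realizer = _Realizer(structure_ont, quality_ont, glossary)
    rng = random.Random(spec.seed)
    truth = GroundTruth()
    documents: list[TaxonDocument] = []

    relational = {CONNECTED, RELATIONAL_QUALITY}
    process_plants = [(rng.randrange(spec.n_taxa) if spec.n_taxa else 0,
                       _PROCESS_ENTITIES[i % len(_PROCESS_ENTITIES)])
                      for i in range(spec.process_quality_pairs)]

    for i in range(spec.n_taxa):
        taxon_id = f"TX:{i:04d}"
        language = "fr" if rng.random() < spec.french_fraction else "en"
        k = min(spec.n_sentences_per_taxon, len(spec.planted_pairs))
        chosen = rng.sample(spec.planted_pairs, k) if k else []
        sentences: list[str] = []
        for entity, quality, construction in chosen:
            partner = None
            if construction == "interleaved":
                partner = next(p for p in _INTERLEAVED_PARTNERS
                               if p[0] != entity and p[1] != quality)
            sentences.append(realizer.sentence(entity, quality, construction,
                                               language, partner))
            truth.expected_eq.add((taxon_id, entity, quality))
            if quality in relational:
                truth.placeholder_pairs.add((taxon_id, entity, quality))
            if partner is not None:
                truth.expected_eq.add((taxon_id, partner[0], partner[1]))
                truth.guaranteed_negatives.add((taxon_id, entity, partner[1]))
                truth.guaranteed_negatives.add((taxon_id, partner[0], quality))
        for taxon_index, proc_entity in process_plants:
            if taxon_index == i:
                sentences.append(realizer.sentence(proc_entity, ACUTE,
                                                   "copula", language))
                truth.expected_eq.add((taxon_id, proc_entity, ACUTE))
        n_distractors = round(spec.distractor_rate * max(len(sentences), 1))
        pool = _DISTRACTORS[language]
        for j in range(n_distractors):
            sentences.append(pool[(i + j) % len(pool)])
        rng.shuffle(sentences)
        documents.append(TaxonDocument(
            taxon_id=taxon_id, taxon_name=f"Exemplarum species {i}",
            description=" ".join(sentences), language=language))

    # a pairing planted positively elsewhere can never be a guaranteed negative
    truth.guaranteed_negatives -= truth.expected_eq
    _fill_expected_counts(truth, quality_ont)
    return documents, truth


def _fill_expected_counts(truth: GroundTruth, quality_ont: Ontology) -> None:
    placeholder_q = {q for _t, _e, q in truth.placeholder_pairs}
    pairs = {(e, q) for _t, e, q in truth.expected_eq}
    entities = {e for e, _q in pairs}
    process_pairs = {(e, q) for e, q in pairs
                     if q in (ACUTE, PROCESS_QUALITY)}
    value_pairs = {(e, q) for e, q in pairs
                   if q not in placeholder_q and (e, q) not in process_pairs}
    trait_pairs = {(e, VALUE_ATTRIBUTE[q]) for e, q in value_pairs
                   if q in VALUE_ATTRIBUTE}
    truth.expected_generated_class_count_by_pattern = {
        "phenotype": len(entities),
        "value": len(value_pairs),
        "trait": len(trait_pairs),
    }
    truth.expected_unsat = {
        f"{_label(e)} {_label(q, quality_ont)}" for e, q in process_pairs}


_STRUCTURE_LABELS: dict[str, str] | None = None


def _label(cid: str, quality_ont: Ontology | None = None) -> str:
    global _STRUCTURE_LABELS
    if quality_ont is not None and cid in quality_ont.classes:
        return quality_ont.label_of(cid)
    if _STRUCTURE_LABELS is None:
        _STRUCTURE_LABELS = {c: m.label or c for c, m in
                             make_mini_structure_ontology().classes.items()}
    return _STRUCTURE_LABELS.get(cid, cid)
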