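"""Compile mined entity-quality pairs into a phenotype ontology.

Three axiom patterns, each an OWL EL equivalence whose right-hand side is
prefixed by ``has-part some`` so that every class describes the whole
organism bearing the phenotype:

* grouping ("phenotype") class for an entity E:
  ``'E phenotype' ≡ has-part some ((part-of some E) and has-quality some quality)``
* value class (character state) for a pair (E, Q):
  ``'E Q' ≡ has-part some (E and has-quality some Q)``
* trait class (character) for the most specific attribute T above a
  value-subset quality Q:
  ``'E T' ≡ has-part some (E and has-quality some T)``

Because part-of is reflexive and transitive, the grouping classes organize
themselves along the anatomical parthood hierarchy under classification,
and value classes fall under their trait and grouping classes.  One
further axiom sends any structure bearing a process-only quality to
Bottom, so impossible combinations classify as unsatisfiable and are
deprecated rather than published.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .mining import EQRecord
from .model import (
    Atomic,
    BOTTOM,
    EquivalentClasses,
    ClassExpression,
    Ontology,
    SubClassOf,
    conj,
    some,
)
from .reasoner import Reasoner, Taxonomy, classify

log = logging.getLogger(__name__)

PATTERNS = ("phenotype", "trait", "value")


@dataclass(frozen=True)
class PatternConfig:
    """Relational vocabulary and namespace policy for class generation."""

    has_part_role: str = "BFO:0000051"
    part_of_role: str = "BFO:0000050"
    has_quality_role: str = "RO:0000086"
    inheres_in_role: str = "RO:0000052"
    structure_root: str = "PO:0025131"       # plant anatomical entity
    quality_root: str = "PATO:0000001"       # quality
    process_quality_root: str | None = None
    relational_quality_root: str | None = None
    attribute_subset_tag: str = "attribute_slim"
    value_subset_tag: str = "value_slim"
    namespace_prefix: str = "FLOPO"
    id_start: int = 1

    def validate(self, structure_ont: Ontology, quality_ont: Ontology) -> None:
        if self.structure_root not in structure_ont.classes:
            raise ValueError(f"structure_root {self.structure_root!r} not in "
                             f"structure ontology")
        for cid, name in ((self.quality_root, "quality_root"),
                          (self.process_quality_root, "process_quality_root"),
                          (self.relational_quality_root, "relational_quality_root")):
            if cid is not None and cid not in quality_ont.classes:
                raise ValueError(f"{name} {cid!r} not in quality ontology")


@dataclass
class GeneratedClass:
    label: str
    pattern: str  # phenotype | trait | value
    entity_class: str
    quality_class: str | None  # None for pattern == "phenotype"
    definiens: ClassExpression
    flopo_id: str | None = None
    deprecated: bool = False

    def key(self) -> tuple[str, str, str]:
        return (self.pattern, self.entity_class, self.quality_class or "")

    @property
    def definition(self) -> EquivalentClasses:
        if self.flopo_id is None:
            raise ValueError("id not assigned yet")
        return EquivalentClasses(Atomic(self.flopo_id), self.definiens)


# ---------------------------------------------------------------------------
# The three patterns


def gen_phenotype_class(entity: str, structure_ont: Ontology,
                        cfg: PatternConfig) -> GeneratedClass:
    """Grouping class covering every phenotype of the entity or any of its
    parts."""
    if entity not in structure_ont.classes:
        raise KeyError(f"unknown structure class {entity!r}")
    definiens = some(cfg.has_part_role,
                     conj(some(cfg.part_of_role, entity),
                          some(cfg.has_quality_role, cfg.quality_root)))
    return GeneratedClass(
        label=f"{structure_ont.label_of(entity)} phenotype",
        pattern="phenotype", entity_class=entity, quality_class=None,
        definiens=definiens)


def _eq_class(entity: str, quality: str, pattern: str, structure_ont: Ontology,
              quality_ont: Ontology, cfg: PatternConfig) -> GeneratedClass:
    if entity not in structure_ont.classes:
        raise KeyError(f"unknown structure class {entity!r}")
    if quality not in quality_ont.classes:
        raise KeyError(f"unknown quality class {quality!r}")
    # the entity is bound directly (no part-of wrapper): the traits of the
    # parts differ from the traits of the whole
    definiens = some(cfg.has_part_role,
                     conj(Atomic(entity), some(cfg.has_quality_role, quality)))
    return GeneratedClass(
        label=f"{structure_ont.label_of(entity)} {quality_ont.label_of(quality)}",
        pattern=pattern, entity_class=entity, quality_class=quality,
        definiens=definiens)


def gen_value_class(entity: str, quality: str, structure_ont: Ontology,
                    quality_ont: Ontology, cfg: PatternConfig) -> GeneratedClass:
    """Character-state class for a mined (E, Q) pair."""
    return _eq_class(entity, quality, "value", structure_ont, quality_ont, cfg)


def gen_trait_class(entity: str, attribute: str, structure_ont: Ontology,
                    quality_ont: Ontology, cfg: PatternConfig) -> GeneratedClass:
    """Character class for an attribute T promoted from a mined value."""
    return _eq_class(entity, attribute, "trait", structure_ont, quality_ont, cfg)


def promote_to_attribute(quality: str, quality_ont: Ontology,
                         cfg: PatternConfig,
                         reasoner: Reasoner | None = None) -> set[str]:
    """Most specific attribute-subset superclasses of a quality.

    Subsumption is entailed on the quality ontology alone.  A quality that
    is itself in the attribute subset is its own promotion.  Hierarchies
    permit ties, so a set is returned; it is empty when no attribute
    subsumes the quality.
    """
    if quality not in quality_ont.classes:
        raise KeyError(f"unknown quality class {quality!r}")
    attributes = quality_ont.terms_in_subset(cfg.attribute_subset_tag)
    if quality in attributes:
        return {quality}
    if reasoner is None:
        reasoner = Reasoner(quality_ont)
    candidates = {a for a in attributes if reasoner.is_entailed(quality, a)}
    return {a for a in candidates
            if not any(b != a and reasoner.is_entailed(b, a)
                       and not reasoner.is_entailed(a, b)
                       for b in candidates)}


def exclusion_axiom(cfg: PatternConfig) -> SubClassOf:
    """No morphological structure bears a process-only quality: the
    combination is sent to Bottom, making the offending generated classes
    unsatisfiable."""
    if cfg.process_quality_root is None:
        raise ValueError("process_quality_root is not configured")
    return SubClassOf(
        conj(Atomic(cfg.structure_root),
             some(cfg.has_quality_role, cfg.process_quality_root)),
        Atomic(BOTTOM))


# ---------------------------------------------------------------------------
# Identifier assignment


class IdMapError(ValueError):
    pass


ID_MAP_HEADER = "pattern\tentity_id\tquality_id\tflopo_id"


def id_map_to_tsv(id_map: Mapping[tuple[str, str, str], str]) -> str:
    lines = [ID_MAP_HEADER]
    for key in sorted(id_map):
        lines.append("\t".join((*key, id_map[key])))
    return "\n".join(lines) + "\n"


def id_map_from_tsv(text: str) -> dict[tuple[str, str, str], str]:
    out: dict[tuple[str, str, str], str] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and lines[0] == ID_MAP_HEADER:
        lines = lines[1:]
    for ln in lines:
        pattern, eid, qid, fid = ln.split("\t")
        out[(pattern, eid, qid)] = fid
    return out


def assign_ids(classes: Sequence[GeneratedClass], cfg: PatternConfig,
               id_map: Mapping[tuple[str, str, str], str] | None = None,
               reserved_ids: Iterable[str] = ()) -> dict[tuple[str, str, str], str]:
    """Assign zero-padded 7-digit ids in the configured namespace.

    Ids are deterministic: new classes are numbered in lexicographic order
    of (pattern, entity label, quality label) starting at ``cfg.id_start``.
    A persisted id map keeps previously assigned ids stable across re-runs;
    reserved (e.g. deprecated) ids are never reused.
    """
    id_map = dict(id_map or {})
    used = set(id_map.values())
    if len(used) != len(id_map):
        seen: dict[str, tuple] = {}
        for key, fid in sorted(id_map.items()):
            if fid in seen:
                raise IdMapError(
                    f"persisted id {fid} assigned to both {seen[fid]} and {key}")
            seen[fid] = key
    used |= set(reserved_ids)
    counter = cfg.id_start
    order = sorted(classes, key=lambda c: (c.pattern, c.label))
    for gc in order:
        key = gc.key()
        if key in id_map:
            gc.flopo_id = id_map[key]
            continue
        while f"{cfg.namespace_prefix}:{counter:07d}" in used:
            counter += 1
        gc.flopo_id = f"{cfg.namespace_prefix}:{counter:07d}"
        used.add(gc.flopo_id)
        id_map[key] = gc.flopo_id
        counter += 1
    return id_map


# ---------------------------------------------------------------------------
# Ontology assembly


@dataclass
class BuildResult:
    ontology: Ontology
    generated: list[GeneratedClass]
    excluded: list[GeneratedClass]          # unsatisfiable, deprecated
    taxonomy: Taxonomy
    id_map: dict[tuple[str, str, str], str]

    @property
    def by_key(self) -> dict[tuple[str, str, str], GeneratedClass]:
        return {gc.key(): gc for gc in self.generated + self.excluded}

    def deprecation_report(self) -> str:
        return "".join(f"{gc.flopo_id}\n"
                       for gc in sorted(self.excluded, key=lambda g: g.flopo_id))


def eq_pattern(quality: str, quality_ont: Ontology, cfg: PatternConfig) -> str:
    """Pattern tag of an entity-quality class: attribute-subset qualities
    describe characters ("trait"), everything else a character state
    ("value").  Keying by the quality's own level means a directly mined
    attribute and a promoted one collapse to the same class."""
    if quality in quality_ont.terms_in_subset(cfg.attribute_subset_tag):
        return "trait"
    return "value"


def generate_classes(records: Sequence[EQRecord], structure_ont: Ontology,
                     quality_ont: Ontology, cfg: PatternConfig
                     ) -> list[GeneratedClass]:
    """One generated class per distinct (pattern, E, Q) triple across all
    records.  Placeholder (relational-quality) records contribute only the
    grouping class of their entity."""
    quality_reasoner = Reasoner(quality_ont)
    value_subset = quality_ont.terms_in_subset(cfg.value_subset_tag)
    out: dict[tuple[str, str, str], GeneratedClass] = {}

    def put(gc: GeneratedClass) -> None:
        out.setdefault(gc.key(), gc)

    for rec in sorted(records, key=lambda r: r.key()):
        put(gen_phenotype_class(rec.entity_class, structure_ont, cfg))
        if rec.relational_placeholder:
            continue
        if eq_pattern(rec.quality_class, quality_ont, cfg) == "trait":
            put(gen_trait_class(rec.entity_class, rec.quality_class,
                                structure_ont, quality_ont, cfg))
        else:
            put(gen_value_class(rec.entity_class, rec.quality_class,
                                structure_ont, quality_ont, cfg))
        if rec.quality_class in value_subset:
            for attr in sorted(promote_to_attribute(
                    rec.quality_class, quality_ont, cfg, quality_reasoner)):
                put(gen_trait_class(rec.entity_class, attr,
                                    structure_ont, quality_ont, cfg))
    return [out[k] for k in sorted(out)]


def build_ontology(records: Sequence[EQRecord], structure_ont: Ontology,
                   quality_ont: Ontology, cfg: PatternConfig,
                   id_map: Mapping[tuple[str, str, str], str] | None = None,
                   deprecated_ids: Iterable[str] = ()) -> BuildResult:
    """Assemble and classify the output ontology.

    The result contains all axioms of both input ontologies, every
    generated definition, and (when a process-quality root is configured)
    the exclusion axiom.  Generated classes that classify as unsatisfiable
    are stripped of their definitions, marked deprecated and reported in
    ``excluded``; externally supplied deprecated ids are likewise marked
    and their ids never reused.
    """
    cfg.validate(structure_ont, quality_ont)
    deprecated_ids = sorted(set(deprecated_ids))
    generated = generate_classes(records, structure_ont, quality_ont, cfg)
    id_map = assign_ids(generated, cfg, id_map=id_map,
                        reserved_ids=deprecated_ids)

    def assemble(classes: Sequence[GeneratedClass]) -> Ontology:
        onto = Ontology()
        onto.merge(structure_ont)
        onto.merge(quality_ont)
        for gc in classes:
            onto.add_class(gc.flopo_id, label=gc.label)
            if not gc.deprecated:
                onto.add_axiom(gc.definition)
            else:
                onto.classes[gc.flopo_id].deprecated = True
        for dep in deprecated_ids:
            onto.add_class(dep).deprecated = True
        if cfg.process_quality_root is not None:
            onto.add_axiom(exclusion_axiom(cfg))
        return onto

    draft = assemble(generated)
    reasoner = Reasoner(draft)
    excluded = [gc for gc in generated
                if not reasoner.is_satisfiable(gc.flopo_id)]
    for gc in excluded:
        gc.deprecated = True
        log.info("EXCLUDED_UNSATISFIABLE %s %r", gc.flopo_id, gc.label)
    kept = [gc for gc in generated if not gc.deprecated]
    if excluded:
        final = assemble(generated)
        taxonomy = classify(final)
    else:
        final, taxonomy = draft, reasoner.taxonomy()
    return BuildResult(ontology=final, generated=kept, excluded=excluded,
                       taxonomy=taxonomy, id_map=dict(id_map))


def apply_inheres_prefix(onto: Ontology, cfg: PatternConfig) -> Ontology:
    """Wrap every generated definition's right-hand side in
    ``inheres-in some``, turning the generated classes into subclasses of
    quality without changing any subsumption among them.  Off by default;
    returns a transformed copy."""
    out = onto.copy()
    prefix = f"{cfg.namespace_prefix}:"
    new_axioms = []
    for ax in out.axioms:
        if isinstance(ax, EquivalentClasses):
            named, rhs = None, None
            if isinstance(ax.a, Atomic) and ax.a.class_id.startswith(prefix):
                named, rhs = ax.a, ax.b
            elif isinstance(ax.b, Atomic) and ax.b.class_id.startswith(prefix):
                named, rhs = ax.b, ax.a
            if named is not None and not isinstance(rhs, Atomic):
                new_axioms.append(EquivalentClasses(
                    named, some(cfg.inheres_in_role, rhs)))
                continue
        new_axioms.append(ax)
    out.axioms = new_axioms
    out.add_role(cfg.inheres_in_role)
    return out
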