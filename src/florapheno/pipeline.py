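"""End-to-end orchestration: mine → generate → classify → annotate.

Stages communicate only through their declared file formats (corpus TSV,
EQ-record TSV, OFN/OBO ontologies, id-map TSV, taxonomy TSV, annotation
TSV), so any suffix of the pipeline can be re-run from intermediate files
and reproduce the final outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from . import obo, ofn
from .lexicon import Glossary, Lexicon, build_lexicon, normalize
from .mining import (EQRecord, Miner, TaxonDocument, corpus_from_tsv,
                     records_from_tsv, records_to_tsv)
from .model import Ontology
from .patterns import (BuildResult, PatternConfig, build_ontology,
                       apply_inheres_prefix, id_map_from_tsv, id_map_to_tsv,
                       promote_to_attribute)
from .reasoner import Reasoner

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    structure_ontology: str = ""
    quality_ontology: str = ""
    corpus: str = ""
    glossary: str | None = None
    eq_records: str | None = None        # precomputed records: skip mining
    id_map: str | None = None
    deprecation_list: str | None = None
    output_dir: str = "florapheno_out"
    source_tag: str = "corpus"
    stem: bool = True
    inheres_prefix: bool = False
    pattern: PatternConfig = field(default_factory=PatternConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except OSError as exc:
            raise ConfigError(str(exc)) from exc
        return cls.from_dict(data, base=Path(path).parent)

    @classmethod
    def from_dict(cls, data: Mapping, base: Path | None = None) -> "RunConfig":
        data = dict(data)
        pattern_keys = {f.name for f in dc_fields(PatternConfig)}
        run_keys = {f.name for f in dc_fields(cls)} - {"pattern"}
        pattern_kw = dict(data.pop("pattern", {}) or {})
        run_kw = {}
        for key, value in data.items():
            if key in pattern_keys:
                pattern_kw[key] = value
            elif key in run_keys:
                run_kw[key] = value
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        cfg = cls(**run_kw, pattern=PatternConfig(**pattern_kw))
        if base is not None:
            for name in ("structure_ontology", "quality_ontology", "corpus",
                         "glossary", "eq_records", "id_map",
                         "deprecation_list", "output_dir"):
                value = getattr(cfg, name)
                if value and not Path(value).is_absolute():
                    setattr(cfg, name, str(base / value))
        return cfg

    def validate(self) -> None:
        for name in ("structure_ontology", "quality_ontology"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise ConfigError(f"{name} path not resolvable: {path!r}")
        if self.eq_records is None and (not self.corpus
                                        or not Path(self.corpus).exists()):
            raise ConfigError(f"corpus path not resolvable: {self.corpus!r}")
        for name in ("glossary", "eq_records", "id_map", "deprecation_list"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path not resolvable: {path!r}")


def load_ontology(path: str | Path) -> Ontology:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".obo":
        return obo.parse_obo(text)
    return ofn.parse_ofn(text)


# ---------------------------------------------------------------------------
# Annotation


@dataclass(frozen=True)
class AnnotationRow:
    taxon_id: str
    flopo_class: str
    pattern: str
    evidence_sentence: str
    source_tag: str


ANNOTATION_HEADER = "taxon_id\tflopo_class\tpattern\tevidence_sentence\tsource_tag"


def annotations_to_tsv(rows: Sequence[AnnotationRow]) -> str:
    lines = [ANNOTATION_HEADER]
    for r in rows:
        lines.append("\t".join((r.taxon_id, r.flopo_class, r.pattern,
                                r.evidence_sentence.replace("\t", " "),
                                r.source_tag)))
    return "\n".join(lines) + "\n"


def annotate(records: Sequence[EQRecord], build: BuildResult,
             quality_ont: Ontology, cfg: PatternConfig,
             source_tag: str = "corpus") -> tuple[list[AnnotationRow], int]:
    """Taxon → generated-class annotation rows.

    Each record yields its value-class row plus the derived trait- and
    phenotype-class rows; placeholder records yield only the phenotype
    row.  Rows that would point at unsatisfiable or deprecated classes are
    dropped and counted.
    """
    by_key = build.by_key
    quality_reasoner = Reasoner(quality_ont)
    value_subset = quality_ont.terms_in_subset(cfg.value_subset_tag)
    rows: set[AnnotationRow] = set()
    dropped = 0

    def emit(rec: EQRecord, key: tuple[str, str, str]) -> None:
        nonlocal dropped
        gc = by_key.get(key)
        if gc is None:
            raise StageError("annotate",
                             f"record {rec.key()} has no generated class {key}")
        if gc.deprecated:
            dropped += 1
            log.info("DROPPED_DEPRECATED taxon=%s class=%s", rec.taxon_id,
                     gc.flopo_id)
            return
        rows.add(AnnotationRow(rec.taxon_id, gc.flopo_id, gc.pattern,
                               rec.sentence, source_tag))

    from .patterns import eq_pattern
    for rec in records:
        emit(rec, ("phenotype", rec.entity_class, ""))
        if rec.relational_placeholder:
            continue
        emit(rec, (eq_pattern(rec.quality_class, quality_ont, cfg),
                   rec.entity_class, rec.quality_class))
        if rec.quality_class in value_subset:
            for attr in sorted(promote_to_attribute(
                    rec.quality_class, quality_ont, cfg, quality_reasoner)):
                emit(rec, ("trait", rec.entity_class, attr))
    ordered = sorted(rows, key=lambda r: (r.taxon_id, r.flopo_class,
                                          r.evidence_sentence))
    return ordered, dropped


def match_external_traits(trait_labels: Iterable[str], build: BuildResult,
                          language: str = "en", stem: bool = True
                          ) -> tuple[dict[str, str], list[str]]:
    """Match free-text trait labels against generated-class labels.

    Labels are normalized exactly like mined text; unmatched labels are
    returned for curation.  Only satisfiable (non-deprecated) classes
    participate."""
    index: dict[tuple[str, ...], str] = {}
    for gc in sorted(build.generated, key=lambda g: g.flopo_id):
        key = tuple(normalize(gc.label, language, stem=stem))
        index.setdefault(key, gc.flopo_id)
    matched: dict[str, str] = {}
    unmatched: list[str] = []
    for label in trait_labels:
        key = tuple(normalize(label, language, stem=stem))
        if key in index:
            matched[label] = index[key]
        else:
            unmatched.append(label)
    return matched, unmatched


# ---------------------------------------------------------------------------
# The run


def relational_quality_ids(quality_ont: Ontology, cfg: PatternConfig) -> set[str]:
    """Quality classes entailed to lie under the relational-quality root."""
    if cfg.relational_quality_root is None:
        return set()
    reasoner = Reasoner(quality_ont)
    return {q for q in quality_ont.classes
            if reasoner.is_entailed(q, cfg.relational_quality_root)}


def build_lexicons(structure_ont: Ontology, quality_ont: Ontology,
                   glossary: Glossary | None, stem: bool = True
                   ) -> dict[str, tuple[Lexicon, Lexicon]]:
    lexicons = {"en": (build_lexicon(structure_ont, "en", stem=stem),
                       build_lexicon(quality_ont, "en", stem=stem))}
    if glossary is not None:
        lexicons["fr"] = (
            build_lexicon(structure_ont, "fr", glossary=glossary, stem=stem),
            build_lexicon(quality_ont, "fr", glossary=glossary, stem=stem))
    return lexicons


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write all artifacts under
    ``cfg.output_dir``; returns the run summary."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    structure_ont = stage("load", lambda: load_ontology(cfg.structure_ontology))
    quality_ont = stage("load", lambda: load_ontology(cfg.quality_ontology))
    glossary = None
    if cfg.glossary:
        glossary = stage("load", lambda: Glossary.from_tsv(
            Path(cfg.glossary).read_text()))

    summary: dict = {}
    if cfg.eq_records:
        records = stage("mine", lambda: records_from_tsv(
            Path(cfg.eq_records).read_text()))
        summary["mining"] = {"n_records": len(records), "precomputed": True}
    else:
        def mine():
            lexicons = build_lexicons(structure_ont, quality_ont, glossary,
                                      stem=cfg.stem)
            miner = Miner(lexicons,
                          relational_quality_ids(quality_ont, cfg.pattern),
                          stem=cfg.stem)
            docs = corpus_from_tsv(Path(cfg.corpus).read_text())
            return miner.mine_corpus(docs)
        records, mining_summary = stage("mine", mine)
        summary["mining"] = mining_summary.as_dict()
    (out / "eq_records.tsv").write_text(records_to_tsv(records))

    id_map = None
    if cfg.id_map and Path(cfg.id_map).exists():
        id_map = id_map_from_tsv(Path(cfg.id_map).read_text())
    deprecated_ids: list[str] = []
    if cfg.deprecation_list:
        deprecated_ids = [ln.strip() for ln in
                          Path(cfg.deprecation_list).read_text().splitlines()
                          if ln.strip()]

    build = stage("generate", lambda: build_ontology(
        records, structure_ont, quality_ont, cfg.pattern,
        id_map=id_map, deprecated_ids=deprecated_ids))
    built = build.ontology
    if cfg.inheres_prefix:
        built = apply_inheres_prefix(built, cfg.pattern)
    (out / "built.ofn").write_text(ofn.write_ofn(built))
    (out / "built.obo").write_text(obo.write_obo(built))
    (out / "id_map.tsv").write_text(id_map_to_tsv(build.id_map))
    (out / "deprecations.txt").write_text(build.deprecation_report())

    taxonomy = build.taxonomy
    (out / "taxonomy.tsv").write_text(taxonomy.edges_tsv())
    (out / "unsatisfiable.txt").write_text(
        "".join(f"{c}\n" for c in sorted(taxonomy.unsatisfiable)))

    rows, dropped = stage("annotate", lambda: annotate(
        records, build, quality_ont, cfg.pattern, source_tag=cfg.source_tag))
    (out / "annotations.tsv").write_text(annotations_to_tsv(rows))

    by_pattern: dict[str, int] = {}
    for gc in build.generated:
        by_pattern[gc.pattern] = by_pattern.get(gc.pattern, 0) + 1
    summary["generation"] = {
        "generated_classes": len(build.generated),
        "by_pattern": by_pattern,
        "excluded_unsatisfiable": len(build.excluded),
        "externally_deprecated": len(deprecated_ids),
    }
    summary["classification"] = {
        "groups": len(taxonomy.groups),
        "direct_edges": len(taxonomy.direct_edges),
        "unsatisfiable": len(taxonomy.unsatisfiable),
    }
    summary["annotation"] = {"rows": len(rows), "dropped": dropped}
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    return summary
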