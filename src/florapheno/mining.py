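"""Sentence segmentation, entity/quality co-occurrence and the attributive
filter that turns taxon descriptions into entity-quality records.

The attributive decision is a three-rule adjacency/copula heuristic rather
than a dependency parse: a quality immediately adjacent to an entity
modifies that entity (and only that one); otherwise it attaches to the
nearest preceding entity with no other entity in between, which also
covers copula constructions ("The flowers are red") because copulas
survive tokenization.  The heuristic is pluggable — any callable with the
same signature can replace it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .lexicon import Lexicon, normalize

log = logging.getLogger(__name__)

# Tokens before a '.' that mark measurement/botanical abbreviations, not
# sentence ends ("Stem 2 cm. in diam., glabrous." is one sentence).
ABBREVIATIONS = {
    "cm", "mm", "dm", "m", "ca", "diam", "var", "subsp", "ssp", "sp", "spp",
    "fl", "fr", "alt", "approx", "no", "syn", "cf", "agg", "al", "e.g", "i.e",
}

COPULA_TOKENS = {"is", "ar", "are", "sont", "est"}  # stemmed forms included

Span = tuple[int, int]  # 0-based, half-open token range


@dataclass(frozen=True)
class TaxonDocument:
    taxon_id: str
    taxon_name: str
    description: str
    language: str = "en"

    def __post_init__(self):
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")


@dataclass(frozen=True)
class EQRecord:
    taxon_id: str
    entity_class: str
    quality_class: str
    sentence: str
    entity_span: Span = (0, 0)
    quality_span: Span = (0, 0)
    relational_placeholder: bool = False

    def key(self) -> tuple[str, str, str, str]:
        return (self.taxon_id, self.entity_class, self.quality_class,
                self.sentence)


_WORD_BEFORE = re.compile(r"([\w.]+)$", re.UNICODE)


def split_sentences(text: str) -> list[str]:
    """Rule-based splitting on ``. ; ! ?`` with abbreviation protection.

    A period does not split when the word before it is a known
    abbreviation, a single letter (initials), or when it sits between two
    digits (decimal numbers).
    """
    sentences: list[str] = []
    start = 0
    for i, ch in enumerate(text):
        if ch not in ".;!?":
            continue
        if ch == ".":
            if i > 0 and i + 1 < len(text) and text[i - 1].isdigit() and text[i + 1].isdigit():
                continue
            m = _WORD_BEFORE.search(text[:i])
            if m:
                word = m.group(1).rstrip(".").lower()
                if word in ABBREVIATIONS or (len(word) == 1 and word.isalpha()):
                    continue
        piece = text[start:i].strip()
        if piece:
            sentences.append(piece)
        start = i + 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def extract_candidates(
    tokens: Sequence[str],
    entity_lexicon: Lexicon,
    quality_lexicon: Lexicon,
) -> list[tuple[tuple[Span, str], tuple[Span, str]]]:
    """Cross product of entity and quality matches within one normalized
    sentence, before attributive filtering."""
    entities = entity_lexicon.lookup(tokens)
    qualities = quality_lexicon.lookup(tokens)
    return [(e, q) for e in entities for q in qualities
            if not _overlaps(e[0], q[0])]


def _overlaps(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def attributive_filter(
    tokens: Sequence[str],
    entity_span: Span,
    quality_span: Span,
    all_entity_spans: Iterable[Span] | None = None,
) -> bool:
    """True iff the quality at ``quality_span`` attributively modifies the
    entity at ``entity_span``.

    Rules, in order: (a) direct adjacency (pre- or post-modifier) binds the
    quality to that entity exclusively; (b) otherwise the quality attaches
    to the nearest preceding entity with no other entity match in between;
    (c) copula constructions are covered by (b) since copulas are ordinary
    non-entity tokens.
    """
    if _overlaps(entity_span, quality_span):
        raise ValueError("entity and quality spans overlap")
    spans = set(all_entity_spans) if all_entity_spans is not None else {entity_span}
    spans.add(entity_span)
    qs, qe = quality_span
    es, ee = entity_span
    if qe == es or ee == qs:
        return True
    # adjacency to any *other* entity claims the quality exclusively
    for os_, oe in spans:
        if (os_, oe) != entity_span and (qe == os_ or oe == qs):
            return False
    preceding = [sp for sp in spans if sp[1] <= qs]
    if preceding:
        nearest = max(preceding, key=lambda sp: sp[1])
        return nearest == entity_span
    return False


AttributiveFilter = Callable[[Sequence[str], Span, Span, Iterable[Span]], bool]


@dataclass
class MiningSummary:
    n_documents: int = 0
    n_sentences: int = 0
    n_candidates: int = 0
    n_filtered_out: int = 0
    n_records: int = 0
    distinct_entities: int = 0
    distinct_qualities: int = 0
    distinct_pairs: int = 0
    n_taxa: int = 0
    n_placeholder_records: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class Miner:
    """Configured corpus miner.

    Parameters
    ----------
    lexicons:
        ``language -> (entity_lexicon, quality_lexicon)``.
    relational_quality_ids:
        Quality classes that are relational (ternary in the quality
        ontology); their records are marked as placeholders stating the
        structure is related to *something*, and skip value/trait
        generation downstream.
    """

    def __init__(
        self,
        lexicons: dict[str, tuple[Lexicon, Lexicon]],
        relational_quality_ids: Iterable[str] = (),
        stem: bool = True,
        attributive: AttributiveFilter | None = None,
    ):
        self.lexicons = lexicons
        self.relational_quality_ids = set(relational_quality_ids)
        self.stem = stem
        self.attributive = attributive or attributive_filter

    def mine_document(self, doc: TaxonDocument) -> list[EQRecord]:
        records, _, _, _ = self._mine(doc)
        return records

    def _mine(self, doc: TaxonDocument
              ) -> tuple[list[EQRecord], int, int, int]:
        """Returns (records, n_sentences, n_candidates, n_filtered_out)."""
        if doc.language not in self.lexicons:
            raise ValueError(
                f"document {doc.taxon_id!r} has language {doc.language!r} "
                f"with no built lexicon")
        entity_lex, quality_lex = self.lexicons[doc.language]
        records: list[EQRecord] = []
        sentences = split_sentences(doc.description)
        n_candidates = n_filtered = 0
        for sentence in sentences:
            tokens = normalize(sentence, doc.language, stem=self.stem)
            entities = entity_lex.lookup(tokens)
            qualities = quality_lex.lookup(tokens)
            if not entities or not qualities:
                continue
            entity_spans = [sp for sp, _ in entities]
            for espan, eclass in entities:
                for qspan, qclass in qualities:
                    if _overlaps(espan, qspan):
                        continue
                    n_candidates += 1
                    if not self.attributive(tokens, espan, qspan, entity_spans):
                        n_filtered += 1
                        log.debug("FILTERED_NON_ATTRIBUTIVE taxon=%s pair=(%s,%s) "
                                  "sentence=%r", doc.taxon_id, eclass, qclass,
                                  sentence)
                        continue
                    records.append(EQRecord(
                        taxon_id=doc.taxon_id,
                        entity_class=eclass,
                        quality_class=qclass,
                        sentence=sentence,
                        entity_span=espan,
                        quality_span=qspan,
                        relational_placeholder=qclass in self.relational_quality_ids,
                    ))
        return records, len(sentences), n_candidates, n_filtered

    def mine_corpus(
        self, documents: Iterable[TaxonDocument]
    ) -> tuple[list[EQRecord], MiningSummary]:
        """Mine every document; output is deduplicated on
        (taxon, entity, quality, sentence) and sorted, so it is invariant
        under document order."""
        summary = MiningSummary()
        seen: dict[tuple, EQRecord] = {}
        for doc in documents:
            summary.n_documents += 1
            recs, n_sent, n_cand, n_filt = self._mine(doc)
            summary.n_sentences += n_sent
            summary.n_candidates += n_cand
            summary.n_filtered_out += n_filt
            for rec in recs:
                seen.setdefault(rec.key(), rec)
        records = sorted(seen.values(), key=lambda r: r.key())
        summary.n_records = len(records)
        summary.distinct_entities = len({r.entity_class for r in records})
        summary.distinct_qualities = len({r.quality_class for r in records})
        summary.distinct_pairs = len({(r.entity_class, r.quality_class)
                                      for r in records})
        summary.n_taxa = len({r.taxon_id for r in records})
        summary.n_placeholder_records = sum(r.relational_placeholder
                                            for r in records)
        return records, summary


# ---------------------------------------------------------------------------
# TSV interchange formats

CORPUS_HEADER = "taxon_id\ttaxon_name\tlanguage\tdescription"
RECORDS_HEADER = "taxon_id\tentity_id\tquality_id\tplaceholder\tsentence"


def corpus_to_tsv(documents: Sequence[TaxonDocument]) -> str:
    lines = [CORPUS_HEADER]
    for d in documents:
        desc = d.description.replace("\t", " ").replace("\n", " ")
        lines.append(f"{d.taxon_id}\t{d.taxon_name}\t{d.language}\t{desc}")
    return "\n".join(lines) + "\n"


def corpus_from_tsv(text: str) -> list[TaxonDocument]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    if lines[0] == CORPUS_HEADER:
        lines = lines[1:]
    docs = []
    seen_ids = set()
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ValueError(f"corpus line has {len(parts)} fields, expected 4: {ln!r}")
        if parts[0] in seen_ids:
            raise ValueError(f"duplicate taxon_id {parts[0]!r} in corpus")
        seen_ids.add(parts[0])
        docs.append(TaxonDocument(taxon_id=parts[0], taxon_name=parts[1],
                                  language=parts[2], description=parts[3]))
    return docs


def records_to_tsv(records: Sequence[EQRecord]) -> str:
    lines = [RECORDS_HEADER]
    for r in records:
        sent = r.sentence.replace("\t", " ").replace("\n", " ")
        lines.append(f"{r.taxon_id}\t{r.entity_class}\t{r.quality_class}"
                     f"\t{int(r.relational_placeholder)}\t{sent}")
    return "\n".join(lines) + "\n"


def records_from_tsv(text: str) -> list[EQRecord]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    if lines[0] == RECORDS_HEADER:
        lines = lines[1:]
    out = []
    for ln in lines:
        taxon, eid, qid, placeholder, sentence = ln.split("\t")
        out.append(EQRecord(taxon_id=taxon, entity_class=eid, quality_class=qid,
                            sentence=sentence,
                            relational_placeholder=placeholder == "1"))
    return out
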