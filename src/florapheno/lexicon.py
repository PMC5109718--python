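"""Term dictionaries built from ontology labels and synonyms.

A lexicon maps normalized token sequences to ontology class ids.  The same
normalization (lowercase, punctuation stripping, stopword removal,
stemming) is applied to the dictionary terms and, later, to the text being
matched — that shared preprocessing is what makes exact token-sequence
matching behave like a full-text engine's analyzed matching.

French support is dictionary-based: every English label or synonym with a
translation in a bilingual glossary contributes a French entry; the French
document text itself is never machine-translated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import Ontology
from .stem import get_stemmer

# Small fixed stopword lists shipped with the package for determinism.
# Copulas (is/are/est/sont) and clause-linking prepositions (with/avec)
# are deliberately NOT stopwords: the attributive filter needs them as
# tokens — dropping "with" would make "red with yellow stamens" look like
# "red" premodifying "stamens".
STOPWORDS = {
    "en": {
        "the", "a", "an", "and", "or", "of", "in", "on", "at", "to",
        "by", "from", "for", "as", "that", "this", "these",
        "those", "it", "its", "they", "their", "but", "than", "then",
        "when", "while", "into", "about", "each", "per",
    },
    "fr": {
        "le", "la", "les", "un", "une", "des", "de", "du", "d", "l", "et",
        "ou", "en", "dans", "sur", "pour", "par", "plus",
        "que", "qui", "ce", "ces", "cette", "son", "sa", "ses", "leur",
        "il", "elle", "ne", "pas", "au", "aux",
    },
}

_TOKEN_SPLIT = re.compile(r"[^\w]+", re.UNICODE)


def _stem_fixpoint(stemmer, token: str) -> str:
    # stem to a fixpoint so normalize(normalize(t)) == normalize(t); the
    # suffix strippers converge in one or two applications
    seen = [token]
    while True:
        token = stemmer.stem(token)
        if token in seen:
            return min(seen[seen.index(token):] or [token])
        seen.append(token)


def normalize(term: str, language: str = "en", stem: bool = True) -> list[str]:
    """Lowercase, strip punctuation, drop stopwords, stem each token.

    Deterministic and idempotent; all-stopword input gives ``[]``.  The
    stopword filter also applies to stemmed forms (stemming can create a
    stopword, e.g. "ase" → "as").
    """
    stemmer = get_stemmer(language, stem=stem)
    stopwords = STOPWORDS.get(language, set())
    tokens = []
    for raw in _TOKEN_SPLIT.split(term.lower()):
        if not raw or raw in stopwords:
            continue
        stemmed = _stem_fixpoint(stemmer, raw)
        if stemmed and stemmed not in stopwords:
            tokens.append(stemmed)
    return tokens


@dataclass(frozen=True)
class LexiconEntry:
    normalized_term: tuple[str, ...]
    class_id: str
    source: str  # label | synonym | translation
    language: str

    def __post_init__(self):
        if not self.normalized_term:
            raise ValueError("empty normalized term")


@dataclass
class Glossary:
    """Bilingual term glossary: (foreign_term, english_term) pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def translations(self, english_term: str) -> set[str]:
        key = english_term.strip().lower()
        return {f for f, e in self.pairs if e.strip().lower() == key}

    @classmethod
    def from_tsv(cls, text: str) -> "Glossary":
        pairs = set()
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise ValueError(f"glossary line {lineno}: expected "
                                 f"foreign<TAB>english, got {line!r}")
            pairs.add((parts[0].strip(), parts[1].strip()))
        return cls(pairs)

    def to_tsv(self) -> str:
        return "".join(f"{f}\t{e}\n" for f, e in sorted(self.pairs))


class Lexicon:
    """A set of :class:`LexiconEntry` with longest-match lookup."""

    def __init__(self, entries: Iterable[LexiconEntry] = ()):
        self.entries: set[LexiconEntry] = set(entries)
        self._index: dict[str, list[LexiconEntry]] | None = None

    def add(self, entry: LexiconEntry) -> None:
        self.entries.add(entry)
        self._index = None

    def _build_index(self) -> dict[str, list[LexiconEntry]]:
        if self._index is None:
            idx: dict[str, list[LexiconEntry]] = {}
            for e in self.entries:
                idx.setdefault(e.normalized_term[0], []).append(e)
            for lst in idx.values():
                # longest first; deterministic tie-break on term then class
                lst.sort(key=lambda e: (-len(e.normalized_term),
                                        e.normalized_term, e.class_id))
            self._index = idx
        return self._index

    def lookup(self, tokens: Sequence[str]) -> list[tuple[tuple[int, int], str]]:
        """Maximal non-overlapping matches, longest-match-first and
        left-to-right.  Spans are 0-based half-open token ranges.  Two
        classes sharing the same normalized term are both reported."""
        idx = self._build_index()
        matches: list[tuple[tuple[int, int], str]] = []
        i = 0
        n = len(tokens)
        while i < n:
            candidates = idx.get(tokens[i], [])
            best_len = 0
            best_classes: list[str] = []
            for e in candidates:
                length = len(e.normalized_term)
                if best_len and length < best_len:
                    break  # sorted longest-first: nothing longer follows
                if i + length <= n and tuple(tokens[i:i + length]) == e.normalized_term:
                    best_len = length
                    if e.class_id not in best_classes:
                        best_classes.append(e.class_id)
            if best_len:
                for cid in sorted(best_classes):
                    matches.append(((i, i + best_len), cid))
                i += best_len
            else:
                i += 1
        return matches

    def to_tsv(self) -> str:
        rows = sorted((" ".join(e.normalized_term), e.class_id, e.source,
                       e.language) for e in self.entries)
        return "".join("\t".join(r) + "\n" for r in rows)

    @classmethod
    def from_tsv(cls, text: str) -> "Lexicon":
        entries = []
        for line in text.splitlines():
            if not line.strip():
                continue
            term, cid, source, lang = line.split("\t")
            entries.append(LexiconEntry(tuple(term.split()), cid, source, lang))
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(onto: Ontology, language: str = "en",
                  glossary: Glossary | None = None, stem: bool = True,
                  scopes: Iterable[str] | None = None) -> Lexicon:
    """One entry per label/synonym per non-deprecated class.

    For ``language="en"`` the ontology's own labels and synonyms are used.
    For other languages a glossary is required; each English label or
    synonym with a translation contributes an entry in the target language,
    alongside any language-tagged labels the ontology itself carries.
    All synonym scopes are included unless ``scopes`` restricts them.
    """
    if language != "en" and glossary is None:
        raise ValueError(f"a glossary is required to build a {language!r} lexicon")
    scope_filter = set(scopes) if scopes is not None else None
    lex = Lexicon()
    for meta in onto.active_classes():
        texts: list[tuple[str, str]] = []
        if meta.label:
            texts.append((meta.label, "label"))
        for text, scope in sorted(meta.synonyms):
            if scope_filter is None or scope in scope_filter:
                texts.append((text, "synonym"))
        if language == "en":
            for text, source in texts:
                tokens = tuple(normalize(text, "en", stem=stem))
                if tokens:
                    lex.add(LexiconEntry(tokens, meta.class_id, source, "en"))
        else:
            for text in sorted(meta.language_labels.get(language, ())):
                tokens = tuple(normalize(text, language, stem=stem))
                if tokens:
                    lex.add(LexiconEntry(tokens, meta.class_id, "label", language))
            for text, _source in texts:
                for translation in sorted(glossary.translations(text)):
                    tokens = tuple(normalize(translation, language, stem=stem))
                    if tokens:
                        lex.add(LexiconEntry(tokens, meta.class_id,
                                             "translation", language))
    return lex
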