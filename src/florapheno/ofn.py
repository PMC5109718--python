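"""OWL functional-style syntax reader/writer for the EL subset in use.

Supported axiom constructs: SubClassOf, EquivalentClasses, DisjointClasses,
ObjectSomeValuesFrom, ObjectIntersectionOf, TransitiveObjectProperty,
ReflexiveObjectProperty, SubObjectPropertyOf (with ObjectPropertyChain),
Declaration, and AnnotationAssertion for rdfs:label, the oboInOwl synonym
and subset properties, and owl:deprecated.  Anything else raises
:class:`OfnParseError` naming the construct.

The writer is byte-deterministic: prefixes, declarations, annotations and
axioms are each emitted in sorted order.
"""

from __future__ import annotations

import re

from .model import (
    Atomic,
    Axiom,
    BOTTOM,
    TOP,
    OBO_BASE,
    ClassExpression,
    Conjunction,
    EquivalentClasses,
    Existential,
    Ontology,
    SubClassOf,
    conj,
)

OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"

_STANDARD_PREFIXES = {
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "oboInOwl": OBOINOWL,
    "obo": OBO_BASE,
}

_SYN_PROPS = {
    "oboInOwl:hasExactSynonym": "exact",
    "oboInOwl:hasBroadSynonym": "broad",
    "oboInOwl:hasNarrowSynonym": "narrow",
    "oboInOwl:hasRelatedSynonym": "related",
}
_SYN_PROPS_OUT = {v: k for k, v in _SYN_PROPS.items()}


class OfnParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<iri><[^>]*>)
  | (?P<string>"(?:[^"\\]|\\.)*"(?:@[A-Za-z-]+|\^\^[A-Za-z:]+)?)
  | (?P<punct>[()=])
  | (?P<name>[^\s()=<>"]+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        between = text[pos:m.start()]
        if between.strip():
            raise OfnParseError(f"unexpected input: {between.strip()[:40]!r}")
        tokens.append(m.group(0))
        pos = m.end()
    if text[pos:].strip():
        raise OfnParseError(f"unexpected trailing input: {text[pos:].strip()[:40]!r}")
    return tokens


class _Stream:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        if self.i >= len(self.tokens):
            raise OfnParseError("unexpected end of input")
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise OfnParseError(f"expected {tok!r}, got {got!r}")


# ---------------------------------------------------------------------------
# Parsing


def parse_ofn(text: str) -> Ontology:
    stream = _Stream(_tokenize(text))
    onto = Ontology()
    prefixes: dict[str, str] = dict(_STANDARD_PREFIXES)
    while stream.peek() == "Prefix":
        stream.next()
        stream.expect("(")
        name = stream.next()
        if not name.endswith(":"):
            raise OfnParseError(f"bad prefix name {name!r}")
        stream.expect("=")
        iri = stream.next()
        stream.expect(")")
        prefix = name[:-1]
        base = iri.strip("<>")
        prefixes[prefix] = base
        if prefix not in _STANDARD_PREFIXES:
            onto.iri_prefixes[prefix] = base
    if stream.peek() != "Ontology":
        raise OfnParseError("expected Ontology(...)")
    stream.next()
    stream.expect("(")
    if stream.peek() and stream.peek().startswith("<"):
        stream.next()  # ontology IRI, ignored
    parser = _Parser(onto, prefixes)
    while stream.peek() != ")":
        parser.axiom(stream)
    stream.expect(")")
    if stream.peek() is not None:
        raise OfnParseError(f"trailing content after Ontology: {stream.peek()!r}")
    return onto


class _Parser:
    def __init__(self, onto: Ontology, prefixes: dict[str, str]):
        self.onto = onto
        self.prefixes = prefixes

    # -- entities -----------------------------------------------------------

    def entity(self, tok: str) -> str:
        """Token → internal id (CURIE, bare obo local name, or IRI)."""
        if tok.startswith("<"):
            iri = tok.strip("<>")
            return self._compress(iri)
        if ":" not in tok:
            raise OfnParseError(f"expected an entity, got {tok!r}")
        prefix, local = tok.split(":", 1)
        if prefix == "obo":
            return self._compress(OBO_BASE + local)
        if prefix == "owl" and local in ("Thing", "Nothing"):
            return f"owl:{local}"
        return tok

    def _compress(self, iri: str) -> str:
        for prefix, base in self.onto.iri_prefixes.items():
            if iri.startswith(base):
                return f"{prefix}:{iri[len(base):]}"
        if iri.startswith(OBO_BASE):
            local = iri[len(OBO_BASE):]
            m = re.fullmatch(r"([A-Za-z][A-Za-z0-9]*)_(\d+)", local)
            if m:
                return f"{m.group(1)}:{m.group(2)}"
            return local
        return iri

    # -- class expressions ---------------------------------------------------

    def class_expression(self, s: _Stream) -> ClassExpression:
        tok = s.next()
        if tok == "ObjectSomeValuesFrom":
            s.expect("(")
            role = self.entity(s.next())
            filler = self.class_expression(s)
            s.expect(")")
            return Existential(role, filler)
        if tok == "ObjectIntersectionOf":
            s.expect("(")
            ops = []
            while s.peek() != ")":
                ops.append(self.class_expression(s))
            s.expect(")")
            if len(ops) < 2:
                raise OfnParseError("ObjectIntersectionOf needs >= 2 operands")
            return conj(*ops)
        if tok in ("ObjectUnionOf", "ObjectComplementOf", "ObjectAllValuesFrom",
                   "ObjectOneOf", "ObjectHasValue", "DataSomeValuesFrom"):
            raise OfnParseError(f"construct outside the supported EL subset: {tok}")
        return Atomic(self.entity(tok))

    # -- axioms ---------------------------------------------------------------

    def axiom(self, s: _Stream) -> None:
        tok = s.next()
        handler = getattr(self, f"_ax_{tok}", None)
        if handler is None:
            raise OfnParseError(f"unsupported construct: {tok}")
        s.expect("(")
        handler(s)
        s.expect(")")

    def _ax_Declaration(self, s: _Stream) -> None:
        kind = s.next()
        s.expect("(")
        ent = self.entity(s.next())
        s.expect(")")
        if kind == "Class":
            if ent not in (TOP, BOTTOM):
                self.onto.add_class(ent)
        elif kind == "ObjectProperty":
            self.onto.add_role(ent)
        elif kind == "AnnotationProperty":
            pass
        else:
            raise OfnParseError(f"unsupported declaration kind: {kind}")

    def _ax_SubClassOf(self, s: _Stream) -> None:
        sub = self.class_expression(s)
        sup = self.class_expression(s)
        self.onto.add_axiom(SubClassOf(sub, sup))

    def _ax_EquivalentClasses(self, s: _Stream) -> None:
        exprs = []
        while s.peek() != ")":
            exprs.append(self.class_expression(s))
        if len(exprs) < 2:
            raise OfnParseError("EquivalentClasses needs >= 2 expressions")
        for other in exprs[1:]:
            self.onto.add_axiom(EquivalentClasses(exprs[0], other))

    def _ax_DisjointClasses(self, s: _Stream) -> None:
        exprs = []
        while s.peek() != ")":
            exprs.append(self.class_expression(s))
        for i, a in enumerate(exprs):
            for b in exprs[i + 1:]:
                self.onto.add_axiom(SubClassOf(conj(a, b), Atomic(BOTTOM)))

    def _ax_TransitiveObjectProperty(self, s: _Stream) -> None:
        self.onto.add_role(self.entity(s.next()), transitive=True)

    def _ax_ReflexiveObjectProperty(self, s: _Stream) -> None:
        self.onto.add_role(self.entity(s.next()), reflexive=True)

    def _ax_SubObjectPropertyOf(self, s: _Stream) -> None:
        tok = s.next()
        if tok == "ObjectPropertyChain":
            s.expect("(")
            chain = []
            while s.peek() != ")":
                chain.append(self.entity(s.next()))
            s.expect(")")
            sup = self.entity(s.next())
            if len(chain) != 2:
                raise OfnParseError("only length-2 property chains are supported")
            self.onto.add_role(sup).chains.add((chain[0], chain[1]))
        else:
            sub = self.entity(tok)
            sup = self.entity(s.next())
            self.onto.add_role(sup)
            self.onto.add_role(sub).super_roles.add(sup)

    def _ax_AnnotationAssertion(self, s: _Stream) -> None:
        prop_tok = s.next()
        prop = prop_tok if ":" in prop_tok and not prop_tok.startswith("<") \
            else self.entity(prop_tok)
        subject = self.entity(s.next())
        value_tok = s.next()
        lang = None
        literal = None
        if value_tok.startswith('"'):
            m = re.fullmatch(r'"((?:[^"\\]|\\.)*)"(?:@([A-Za-z-]+)|\^\^\S+)?',
                             value_tok)
            if not m:
                raise OfnParseError(f"bad literal {value_tok!r}")
            literal = m.group(1).replace('\\"', '"').replace("\\\\", "\\")
            lang = m.group(2)
        if subject in self.onto.roles:
            target_role = self.onto.roles[subject]
            if prop == "rdfs:label":
                target_role.label = literal
            return
        meta = self.onto.add_class(subject)
        if prop == "rdfs:label":
            if lang and lang != "en":
                meta.language_labels.setdefault(lang, set()).add(literal)
            else:
                meta.label = literal
        elif prop in _SYN_PROPS:
            meta.synonyms.add((literal, _SYN_PROPS[prop]))
        elif prop == "oboInOwl:inSubset":
            meta.subsets.add(literal)
        elif prop == "owl:deprecated":
            meta.deprecated = literal == "true"
        else:
            raise OfnParseError(f"unsupported annotation property: {prop}")


def parse_class_expression(text: str,
                           iri_prefixes: dict[str, str] | None = None
                           ) -> ClassExpression:
    """Parse a standalone functional-syntax class expression, e.g.
    ``ObjectSomeValuesFrom(obo:has_part ObjectIntersectionOf(PO:0009046
    ObjectSomeValuesFrom(obo:has_quality PATO:0002710)))``."""
    scratch = Ontology(iri_prefixes=dict(iri_prefixes or {}))
    stream = _Stream(_tokenize(text))
    expr = _Parser(scratch, dict(_STANDARD_PREFIXES)).class_expression(stream)
    if stream.peek() is not None:
        raise OfnParseError(f"trailing input after expression: {stream.peek()!r}")
    return expr


# ---------------------------------------------------------------------------
# Writing


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


class _Writer:
    def __init__(self, onto: Ontology):
        self.onto = onto
        self.extra_prefixes: dict[str, str] = dict(onto.iri_prefixes)

    def token(self, ent: str) -> str:
        if ent in (TOP, BOTTOM):
            return ent
        if ent.startswith("http://") or ent.startswith("https://"):
            return f"<{ent}>"
        if ":" not in ent:
            return f"obo:{ent}"
        prefix, local = ent.split(":", 1)
        if prefix not in self.extra_prefixes and prefix not in _STANDARD_PREFIXES:
            self.extra_prefixes[prefix] = f"{OBO_BASE}{prefix}_"
        return ent

    def expr(self, e: ClassExpression) -> str:
        if isinstance(e, Atomic):
            return self.token(e.class_id)
        if isinstance(e, Existential):
            return (f"ObjectSomeValuesFrom({self.token(e.role_id)} "
                    f"{self.expr(e.filler)})")
        if isinstance(e, Conjunction):
            return ("ObjectIntersectionOf(" +
                    " ".join(self.expr(op) for op in e.operands) + ")")
        raise TypeError(f"unknown expression {e!r}")  # pragma: no cover


def write_ofn(onto: Ontology, ontology_iri: str = "http://purl.obolibrary.org/obo/florapheno.owl") -> str:
    w = _Writer(onto)
    decls: list[str] = []
    for cid in sorted(onto.classes):
        decls.append(f"Declaration(Class({w.token(cid)}))")
    for rid in sorted(onto.roles):
        decls.append(f"Declaration(ObjectProperty({w.token(rid)}))")

    annotations: list[str] = []
    for cid in sorted(onto.classes):
        meta = onto.classes[cid]
        tok = w.token(cid)
        if meta.label:
            annotations.append(
                f'AnnotationAssertion(rdfs:label {tok} "{_escape(meta.label)}")')
        for lang in sorted(meta.language_labels):
            for text in sorted(meta.language_labels[lang]):
                annotations.append(
                    f'AnnotationAssertion(rdfs:label {tok} "{_escape(text)}"@{lang})')
        for text, scope in sorted(meta.synonyms):
            annotations.append(
                f'AnnotationAssertion({_SYN_PROPS_OUT[scope]} {tok} "{_escape(text)}")')
        for tag in sorted(meta.subsets):
            annotations.append(
                f'AnnotationAssertion(oboInOwl:inSubset {tok} "{_escape(tag)}")')
        if meta.deprecated:
            annotations.append(
                f'AnnotationAssertion(owl:deprecated {tok} "true"^^xsd:boolean)')
    for rid in sorted(onto.roles):
        role = onto.roles[rid]
        if role.label:
            annotations.append(
                f'AnnotationAssertion(rdfs:label {w.token(rid)} "{_escape(role.label)}")')

    logical: set[str] = set()
    for rid in sorted(onto.roles):
        role = onto.roles[rid]
        tok = w.token(rid)
        if role.transitive:
            logical.add(f"TransitiveObjectProperty({tok})")
        if role.reflexive:
            logical.add(f"ReflexiveObjectProperty({tok})")
        for sup in sorted(role.super_roles):
            logical.add(f"SubObjectPropertyOf({tok} {w.token(sup)})")
        for c1, c2 in sorted(role.chains):
            if (c1, c2) == (rid, rid) and role.transitive:
                continue  # already stated as transitivity
            logical.add(
                f"SubObjectPropertyOf(ObjectPropertyChain({w.token(c1)} "
                f"{w.token(c2)}) {tok})")
    for ax in onto.axioms:
        if isinstance(ax, SubClassOf):
            logical.add(f"SubClassOf({w.expr(ax.sub)} {w.expr(ax.sup)})")
        elif isinstance(ax, EquivalentClasses):
            logical.add(f"EquivalentClasses({w.expr(ax.a)} {w.expr(ax.b)})")
        else:  # pragma: no cover
            raise TypeError(f"unknown axiom {ax!r}")

    lines: list[str] = []
    all_prefixes = dict(_STANDARD_PREFIXES)
    all_prefixes.update(w.extra_prefixes)
    for prefix in sorted(all_prefixes):
        lines.append(f"Prefix({prefix}:=<{all_prefixes[prefix]}>)")
    lines.append("")
    lines.append(f"Ontology(<{ontology_iri}>")
    lines.extend(decls)
    lines.extend(annotations)
    lines.extend(sorted(logical))
    lines.append(")")
    lines.append("")
    return "\n".join(lines)
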