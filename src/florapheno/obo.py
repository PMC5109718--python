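"""Reader/writer for the OBO flat-file 1.4 subset the pipeline touches.

Supported stanza tags:

* ``[Term]``: id, name, synonym, subset, is_a, relationship,
  intersection_of, disjoint_from, is_obsolete
* ``[Typedef]``: id, name, is_a, is_transitive, is_reflexive,
  holds_over_chain

Anything else is ignored with a logged warning, never an error.  Logical
content maps onto the EL model: ``is_a`` becomes a SubClassOf between
atomic classes, ``relationship: part_of X`` becomes
``SubClassOf(term, part_of some X)``, an ``intersection_of`` block becomes
an EquivalentClasses with a conjunction, and ``disjoint_from`` becomes the
EL-encodable ``term and other SubClassOf owl:Nothing``.
"""

from __future__ import annotations

import logging
import re

from .model import (
    Atomic,
    Axiom,
    BOTTOM,
    ClassExpression,
    Conjunction,
    EquivalentClasses,
    Existential,
    Ontology,
    SubClassOf,
    conj,
    some,
)

log = logging.getLogger(__name__)


class OboParseError(ValueError):
    pass


_SYN_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]+)?')

_SCOPE_MAP = {
    "EXACT": "exact",
    "BROAD": "broad",
    "NARROW": "narrow",
    "RELATED": "related",
}

_SUPPORTED_TERM_TAGS = {
    "id", "name", "synonym", "subset", "is_a", "relationship",
    "intersection_of", "disjoint_from", "is_obsolete",
}
_SUPPORTED_TYPEDEF_TAGS = {
    "id", "name", "is_a", "is_transitive", "is_reflexive", "holds_over_chain",
}


def _strip_comment(value: str) -> str:
    # OBO trailing comments start with " ! "
    in_quote = False
    for i, ch in enumerate(value):
        if ch == '"' and (i == 0 or value[i - 1] != "\\"):
            in_quote = not in_quote
        elif ch == "!" and not in_quote:
            return value[:i].rstrip()
    return value.rstrip()


def parse_obo(text: str) -> Ontology:
    """Parse OBO flat-file content into an :class:`Ontology`."""
    onto = Ontology()
    stanza_type: str | None = None
    stanza_lines: list[tuple[int, str, str]] = []  # (lineno, tag, value)
    stanza_start = 0

    def flush():
        if stanza_type == "Term":
            _finish_term(onto, stanza_lines, stanza_start)
        elif stanza_type == "Typedef":
            _finish_typedef(onto, stanza_lines, stanza_start)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            stanza_lines = []
            stanza_start = lineno
            name = line.strip("[]")
            if name in ("Term", "Typedef"):
                stanza_type = name
            else:
                log.warning("ignoring unsupported stanza [%s] at line %d", name, lineno)
                stanza_type = None
            continue
        if ":" not in line:
            log.warning("ignoring malformed line %d: %r", lineno, line)
            continue
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = _strip_comment(value.strip())
        if stanza_type is None:
            continue  # header tags (format-version, subsetdef, ...) ignored
        stanza_lines.append((lineno, tag, value))
    flush()
    return onto


def _stanza_id(lines, start, supported, kind) -> str:
    term_id = None
    for lineno, tag, value in lines:
        if tag == "id":
            term_id = value
        elif tag not in supported:
            log.warning("ignoring unsupported %s tag %r at line %d", kind, tag, lineno)
    if not term_id:
        raise OboParseError(f"[{kind}] stanza starting at line {start} has no id")
    return term_id


def _finish_term(onto: Ontology, lines, start: int) -> None:
    term_id = _stanza_id(lines, start, _SUPPORTED_TERM_TAGS, "Term")
    meta = onto.add_class(term_id)
    intersection: list[ClassExpression] = []
    for lineno, tag, value in lines:
        if tag == "name":
            meta.label = value
        elif tag == "is_obsolete" and value.lower() == "true":
            meta.deprecated = True
        elif tag == "subset":
            meta.subsets.add(value)
        elif tag == "synonym":
            m = _SYN_RE.match(value)
            if not m:
                log.warning("unparseable synonym at line %d: %r", lineno, value)
                continue
            scope = _SCOPE_MAP.get(m.group("scope") or "RELATED", "related")
            meta.synonyms.add((m.group("text").replace('\\"', '"'), scope))
        elif tag == "is_a":
            onto.subclass_of(term_id, value)
        elif tag == "disjoint_from":
            onto.disjoint(term_id, value)
        elif tag == "relationship":
            parts = value.split()
            if len(parts) != 2:
                log.warning("unparseable relationship at line %d: %r", lineno, value)
                continue
            onto.subclass_of(term_id, some(parts[0], parts[1]))
        elif tag == "intersection_of":
            parts = value.split()
            if len(parts) == 1:
                intersection.append(Atomic(parts[0]))
            elif len(parts) == 2:
                intersection.append(some(parts[0], parts[1]))
            else:
                log.warning("unparseable intersection_of at line %d: %r", lineno, value)
    if len(intersection) >= 2:
        onto.equivalent(term_id, conj(*intersection))
    elif len(intersection) == 1:
        log.warning("single intersection_of clause for %s ignored", term_id)


def _finish_typedef(onto: Ontology, lines, start: int) -> None:
    role_id = _stanza_id(lines, start, _SUPPORTED_TYPEDEF_TAGS, "Typedef")
    role = onto.add_role(role_id)
    for lineno, tag, value in lines:
        if tag == "name":
            role.label = value
        elif tag == "is_transitive" and value.lower() == "true":
            role.transitive = True
        elif tag == "is_reflexive" and value.lower() == "true":
            role.reflexive = True
        elif tag == "is_a":
            role.super_roles.add(value)
        elif tag == "holds_over_chain":
            parts = value.split()
            if len(parts) != 2:
                log.warning("unparseable holds_over_chain at line %d: %r", lineno, value)
                continue
            role.chains.add((parts[0], parts[1]))


# ---------------------------------------------------------------------------
# Writing


_SCOPE_OUT = {v: k for k, v in _SCOPE_MAP.items()}


def write_obo(onto: Ontology, ontology_name: str = "florapheno") -> str:
    """Serialize the OBO-expressible part of an ontology, deterministically.

    Axioms outside the OBO tag vocabulary (e.g. equivalences whose definiens
    is a bare existential, or general concept inclusions) are skipped with a
    logged warning; use the functional-syntax writer for full fidelity.
    """
    is_a: dict[str, set[str]] = {}
    rels: dict[str, set[tuple[str, str]]] = {}
    disjoint: dict[str, set[str]] = {}
    inter: dict[str, list[str]] = {}
    for ax in onto.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic):
            if isinstance(ax.sup, Atomic):
                if ax.sup.class_id == BOTTOM:
                    log.warning("skipping unsatisfiability axiom for OBO output: %r", ax)
                else:
                    is_a.setdefault(ax.sub.class_id, set()).add(ax.sup.class_id)
                continue
            if isinstance(ax.sup, Existential) and isinstance(ax.sup.filler, Atomic):
                rels.setdefault(ax.sub.class_id, set()).add(
                    (ax.sup.role_id, ax.sup.filler.class_id))
                continue
        if (isinstance(ax, SubClassOf) and isinstance(ax.sub, Conjunction)
                and isinstance(ax.sup, Atomic) and ax.sup.class_id == BOTTOM
                and len(ax.sub.operands) == 2
                and all(isinstance(op, Atomic) for op in ax.sub.operands)):
            a, b = (op.class_id for op in ax.sub.operands)
            disjoint.setdefault(a, set()).add(b)
            continue
        if isinstance(ax, EquivalentClasses):
            named, expr = None, None
            for lhs, rhs in ((ax.a, ax.b), (ax.b, ax.a)):
                if isinstance(lhs, Atomic) and not isinstance(rhs, Atomic):
                    named, expr = lhs.class_id, rhs
            clauses = _intersection_clauses(expr) if named else None
            if named and clauses:
                inter.setdefault(named, []).extend(clauses)
                continue
        log.warning("axiom not expressible in OBO output, skipped: %r", ax)

    out: list[str] = ["format-version: 1.4", f"ontology: {ontology_name}", ""]
    for cid in sorted(onto.classes):
        meta = onto.classes[cid]
        out.append("[Term]")
        out.append(f"id: {cid}")
        if meta.label:
            out.append(f"name: {meta.label}")
        for text, scope in sorted(meta.synonyms):
            esc = text.replace('"', '\\"')
            out.append(f'synonym: "{esc}" {_SCOPE_OUT[scope]} []')
        for tag in sorted(meta.subsets):
            out.append(f"subset: {tag}")
        for sup in sorted(is_a.get(cid, ())):
            out.append(f"is_a: {sup}")
        for clause in sorted(inter.get(cid, [])):
            out.append(f"intersection_of: {clause}")
        for role, filler in sorted(rels.get(cid, ())):
            out.append(f"relationship: {role} {filler}")
        for other in sorted(disjoint.get(cid, ())):
            out.append(f"disjoint_from: {other}")
        if meta.deprecated:
            out.append("is_obsolete: true")
        out.append("")
    for rid in sorted(onto.roles):
        role = onto.roles[rid]
        out.append("[Typedef]")
        out.append(f"id: {rid}")
        if role.label:
            out.append(f"name: {role.label}")
        for sup in sorted(role.super_roles):
            out.append(f"is_a: {sup}")
        if role.transitive:
            out.append("is_transitive: true")
        if role.reflexive:
            out.append("is_reflexive: true")
        for c1, c2 in sorted(role.chains):
            out.append(f"holds_over_chain: {c1} {c2}")
        out.append("")
    return "\n".join(out)


def _intersection_clauses(expr: ClassExpression | None) -> list[str] | None:
    """OBO intersection_of clauses for a conjunction of atoms and simple
    existentials; None when not expressible."""
    if not isinstance(expr, Conjunction):
        return None
    clauses = []
    for op in expr.operands:
        if isinstance(op, Atomic):
            clauses.append(op.class_id)
        elif isinstance(op, Existential) and isinstance(op.filler, Atomic):
            clauses.append(f"{op.role_id} {op.filler.class_id}")
        else:
            return None
    return clauses
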