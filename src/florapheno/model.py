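"""In-memory model for the EL-profile ontology fragment used by the pipeline.

Class expressions are restricted to the OWL 2 EL constructs the phenotype
axiom patterns need: atomic classes, intersections, and existential
restrictions over object properties.  Expressions are immutable and
canonicalized on construction (conjunctions flattened, deduplicated and
order-normalized) so that structurally equal expressions compare and hash
equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

TOP = "owl:Thing"
BOTTOM = "owl:Nothing"

OBO_BASE = "http://purl.obolibrary.org/obo/"


# ---------------------------------------------------------------------------
# Class expressions


class ClassExpression:
    """Base class for EL class expressions. Instances are immutable."""

    __slots__ = ()

    def atoms(self) -> set[str]:
        """All atomic class ids occurring in the expression."""
        raise NotImplementedError

    def roles(self) -> set[str]:
        """All role ids occurring in the expression."""
        raise NotImplementedError

    def _key(self):
        raise NotImplementedError

    def __lt__(self, other: "ClassExpression"):
        return self._key() < other._key()


@dataclass(frozen=True, slots=True)
class Atomic(ClassExpression):
    class_id: str

    def atoms(self) -> set[str]:
        return {self.class_id}

    def roles(self) -> set[str]:
        return set()

    def _key(self):
        return (0, self.class_id)

    def __repr__(self) -> str:
        return self.class_id


@dataclass(frozen=True, slots=True)
class Existential(ClassExpression):
    role_id: str
    filler: ClassExpression

    def atoms(self) -> set[str]:
        return self.filler.atoms()

    def roles(self) -> set[str]:
        return {self.role_id} | self.filler.roles()

    def _key(self):
        return (1, self.role_id, self.filler._key())

    def __repr__(self) -> str:
        return f"some({self.role_id}, {self.filler!r})"


@dataclass(frozen=True, slots=True)
class Conjunction(ClassExpression):
    operands: tuple[ClassExpression, ...]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("Conjunction needs at least two operands")
        for op in self.operands:
            if isinstance(op, Conjunction):
                raise ValueError("Conjunctions must be flattened; use conj()")

    def atoms(self) -> set[str]:
        out: set[str] = set()
        for op in self.operands:
            out |= op.atoms()
        return out

    def roles(self) -> set[str]:
        out: set[str] = set()
        for op in self.operands:
            out |= op.roles()
        return out

    def _key(self):
        return (2, tuple(op._key() for op in self.operands))

    def __repr__(self) -> str:
        return "and(" + ", ".join(repr(op) for op in self.operands) + ")"


def conj(*exprs: ClassExpression) -> ClassExpression:
    """Canonical intersection: flattens nested conjunctions, removes
    duplicates and sorts operands.  Returns the single operand unchanged
    when only one distinct operand remains."""
    flat: list[ClassExpression] = []
    for e in exprs:
        if isinstance(e, Conjunction):
            flat.extend(e.operands)
        else:
            flat.append(e)
    uniq = sorted(set(flat), key=lambda e: e._key())
    if not uniq:
        raise ValueError("empty conjunction")
    if len(uniq) == 1:
        return uniq[0]
    return Conjunction(tuple(uniq))


def some(role_id: str, filler: ClassExpression | str) -> Existential:
    if isinstance(filler, str):
        filler = Atomic(filler)
    return Existential(role_id, filler)


# ---------------------------------------------------------------------------
# Axioms


class Axiom:
    __slots__ = ()


@dataclass(frozen=True, slots=True)
class SubClassOf(Axiom):
    sub: ClassExpression
    sup: ClassExpression

    def __repr__(self) -> str:
        return f"SubClassOf({self.sub!r}, {self.sup!r})"


@dataclass(frozen=True, slots=True)
class EquivalentClasses(Axiom):
    a: ClassExpression
    b: ClassExpression

    def as_inclusions(self) -> tuple[SubClassOf, SubClassOf]:
        return SubClassOf(self.a, self.b), SubClassOf(self.b, self.a)

    def __repr__(self) -> str:
        return f"EquivalentClasses({self.a!r}, {self.b!r})"


def axiom_signature(ax: Axiom) -> tuple[set[str], set[str]]:
    """(class ids, role ids) referenced by an axiom."""
    if isinstance(ax, SubClassOf):
        exprs = (ax.sub, ax.sup)
    elif isinstance(ax, EquivalentClasses):
        exprs = (ax.a, ax.b)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown axiom type {type(ax)!r}")
    cls: set[str] = set()
    rls: set[str] = set()
    for e in exprs:
        cls |= e.atoms()
        rls |= e.roles()
    return cls, rls


# ---------------------------------------------------------------------------
# Roles and class metadata


@dataclass
class Role:
    role_id: str
    label: str | None = None
    transitive: bool = False
    reflexive: bool = False
    super_roles: set[str] = field(default_factory=set)
    # role chains (r1, r2) such that r1 o r2 is a subproperty of this role
    chains: set[tuple[str, str]] = field(default_factory=set)


SYNONYM_SCOPES = ("exact", "broad", "narrow", "related")


@dataclass
class ClassMeta:
    class_id: str
    label: str | None = None
    synonyms: set[tuple[str, str]] = field(default_factory=set)  # (text, scope)
    subsets: set[str] = field(default_factory=set)
    deprecated: bool = False
    language_labels: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ontology


@dataclass
class Ontology:
    """A set of classes, roles and EL axioms with OBO-style annotations.

    Adding an axiom implicitly declares any class or role it references, so
    the signature-closure invariant holds by construction.
    """

    classes: dict[str, ClassMeta] = field(default_factory=dict)
    roles: dict[str, Role] = field(default_factory=dict)
    axioms: list[Axiom] = field(default_factory=list)
    iri_prefixes: dict[str, str] = field(default_factory=dict)

    def add_class(self, class_id: str, label: str | None = None, **kw) -> ClassMeta:
        meta = self.classes.get(class_id)
        if meta is None:
            meta = ClassMeta(class_id=class_id, label=label, **kw)
            self.classes[class_id] = meta
        else:
            if label is not None:
                meta.label = label
            for k, v in kw.items():
                setattr(meta, k, v)
        return meta

    def add_role(self, role_id: str, **kw) -> Role:
        role = self.roles.get(role_id)
        if role is None:
            role = Role(role_id=role_id, **kw)
            self.roles[role_id] = role
        else:
            for k, v in kw.items():
                if k in ("transitive", "reflexive"):
                    setattr(role, k, getattr(role, k) or v)
                else:
                    setattr(role, k, v)
        return role

    def add_axiom(self, ax: Axiom) -> None:
        cls, rls = axiom_signature(ax)
        for c in cls:
            if c not in (TOP, BOTTOM):
                self.add_class(c)
        for r in rls:
            self.add_role(r)
        self.axioms.append(ax)

    def subclass_of(self, sub: ClassExpression | str, sup: ClassExpression | str) -> None:
        if isinstance(sub, str):
            sub = Atomic(sub)
        if isinstance(sup, str):
            sup = Atomic(sup)
        self.add_axiom(SubClassOf(sub, sup))

    def equivalent(self, a: ClassExpression | str, b: ClassExpression | str) -> None:
        if isinstance(a, str):
            a = Atomic(a)
        if isinstance(b, str):
            b = Atomic(b)
        self.add_axiom(EquivalentClasses(a, b))

    def disjoint(self, a: str, b: str) -> None:
        """DisjointClasses over atomic classes, encoded as A ⊓ B ⊑ ⊥."""
        self.add_axiom(SubClassOf(conj(Atomic(a), Atomic(b)), Atomic(BOTTOM)))

    def merge(self, other: "Ontology") -> None:
        """Union the other ontology into this one (metadata merged, axioms
        appended; duplicate axioms are tolerated)."""
        for cid, meta in other.classes.items():
            mine = self.add_class(cid, label=meta.label if meta.label else None)
            mine.synonyms |= meta.synonyms
            mine.subsets |= meta.subsets
            mine.deprecated = mine.deprecated or meta.deprecated
            for lang, labels in meta.language_labels.items():
                mine.language_labels.setdefault(lang, set()).update(labels)
        for rid, role in other.roles.items():
            mine_r = self.add_role(rid, transitive=role.transitive, reflexive=role.reflexive)
            mine_r.super_roles |= role.super_roles
            mine_r.chains |= role.chains
        seen = set(map(repr, self.axioms))
        for ax in other.axioms:
            if repr(ax) not in seen:
                self.axioms.append(ax)
                seen.add(repr(ax))
        for p, base in other.iri_prefixes.items():
            self.iri_prefixes.setdefault(p, base)

    def copy(self) -> "Ontology":
        out = Ontology(iri_prefixes=dict(self.iri_prefixes))
        out.merge(self)
        return out

    # -- annotation helpers -------------------------------------------------

    def label_of(self, class_id: str) -> str:
        meta = self.classes.get(class_id)
        if meta is not None and meta.label:
            return meta.label
        return class_id

    def terms_in_subset(self, tag: str) -> set[str]:
        """All class ids tagged with the given subset name (e.g. PATO's
        attribute/value slims). Unknown tags give the empty set."""
        return {cid for cid, m in self.classes.items() if tag in m.subsets}

    def active_classes(self) -> Iterator[ClassMeta]:
        """Non-deprecated classes (the ones lexicon building may use)."""
        for meta in self.classes.values():
            if not meta.deprecated:
                yield meta

    # -- CURIE / IRI handling ----------------------------------------------

    def expand(self, curie: str) -> str:
        """CURIE → IRI using declared prefixes, falling back to the OBO
        Foundry underscore convention (PO:0009046 →
        http://purl.obolibrary.org/obo/PO_0009046)."""
        if curie.startswith("http://") or curie.startswith("https://"):
            return curie
        if ":" in curie:
            prefix, local = curie.split(":", 1)
            if prefix in self.iri_prefixes:
                return self.iri_prefixes[prefix] + local
            return f"{OBO_BASE}{prefix}_{local}"
        return OBO_BASE + curie

    def normalized_axioms(self) -> list[str]:
        """Sorted canonical reprs of the axiom set with equivalences split
        into inclusion pairs; used for logical-identity comparison."""
        out: set[str] = set()
        for ax in self.axioms:
            if isinstance(ax, EquivalentClasses):
                for inc in ax.as_inclusions():
                    out.add(repr(inc))
            else:
                out.add(repr(ax))
        return sorted(out)
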