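"""Completion-rule subsumption engine for the EL fragment used by the
phenotype axiom patterns: atomic classes, intersections, existential
restrictions, role hierarchies, role chains (hence transitivity),
reflexive roles and Bottom.

The engine normalizes the ontology into the usual EL normal forms (fresh
names standing for nested expressions), then saturates a worklist under
the completion rules:

    R1  A ∈ S(X), A ⊑ B               ⇒ B ∈ S(X)
    R2  A1,A2 ∈ S(X), A1 ⊓ A2 ⊑ B     ⇒ B ∈ S(X)
    R3  A ∈ S(X), A ⊑ ∃r.B            ⇒ (X,B) ∈ R(r)
    R4  (X,Y) ∈ R(r), A ∈ S(Y), ∃r.A ⊑ B ⇒ B ∈ S(X)
    R5  (X,Y) ∈ R(r), ⊥ ∈ S(Y)        ⇒ ⊥ ∈ S(X)
    R6  (X,Y) ∈ R(r), r ⊑ s           ⇒ (X,Y) ∈ R(s)
    R7  (X,Y) ∈ R(r1), (Y,Z) ∈ R(r2), r1∘r2 ⊑ s ⇒ (X,Z) ∈ R(s)
    R8  reflexive(r)                  ⇒ (X,X) ∈ R(r) for every context X

with S(X) initialized to {X, ⊤}.  The reflexive rule runs for fresh names
too; that is what makes a value class like "flower red" a subclass of
"flower phenotype" (the filler flower ⊓ ∃has-quality.red needs
∃part-of.flower via part-of's reflexivity).
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .model import (
    Atomic,
    Axiom,
    BOTTOM,
    TOP,
    ClassExpression,
    Conjunction,
    EquivalentClasses,
    Existential,
    Ontology,
    SubClassOf,
)

FRESH_PREFIX = "__el"


class UnsupportedConstructError(ValueError):
    pass


@dataclass
class NormalizedAxiomSet:
    gci1: list[tuple[str, str]] = field(default_factory=list)           # A ⊑ B
    gci2: list[tuple[str, str, str]] = field(default_factory=list)      # A1⊓A2 ⊑ B
    gci3: list[tuple[str, str, str]] = field(default_factory=list)      # A ⊑ ∃r.B
    gci4: list[tuple[str, str, str]] = field(default_factory=list)      # ∃r.B ⊑ A
    role_sub: list[tuple[str, str]] = field(default_factory=list)       # r ⊑ s
    chains: list[tuple[str, str, str]] = field(default_factory=list)    # r1∘r2 ⊑ s
    reflexive: set[str] = field(default_factory=set)
    names: set[str] = field(default_factory=set)  # every atomic name (incl. fresh)
    fresh_map: dict[str, ClassExpression] = field(default_factory=dict)


class _Normalizer:
    def __init__(self):
        self.n = NormalizedAxiomSet()
        self._memo: dict[ClassExpression, str] = {}
        self._counter = itertools.count()

    def fresh(self) -> str:
        name = f"{FRESH_PREFIX}{next(self._counter)}"
        self.n.names.add(name)
        return name

    def name_of(self, expr: ClassExpression) -> str:
        """Atomic name standing for the expression, introducing a fresh
        name defined (in both directions) for complex expressions."""
        if isinstance(expr, Atomic):
            self.n.names.add(expr.class_id)
            return expr.class_id
        if expr in self._memo:
            return self._memo[expr]
        if isinstance(expr, Existential):
            filler = self.name_of(expr.filler)
            name = self.fresh()
            self.n.gci3.append((name, expr.role_id, filler))
            self.n.gci4.append((expr.role_id, filler, name))
        elif isinstance(expr, Conjunction):
            ops = [self.name_of(op) for op in expr.operands]
            name = self.fresh()
            for op in ops:
                self.n.gci1.append((name, op))
            acc = ops[0]
            for op in ops[1:-1]:
                nxt = self.fresh()
                self.n.gci2.append((acc, op, nxt))
                acc = nxt
            self.n.gci2.append((acc, ops[-1], name))
        else:
            raise UnsupportedConstructError(f"unsupported expression: {expr!r}")
        self._memo[expr] = name
        self.fresh_record(name, expr)
        return name

    def fresh_record(self, name: str, expr: ClassExpression) -> None:
        self.n.fresh_map[name] = expr

    def axiom(self, ax: Axiom) -> None:
        if isinstance(ax, SubClassOf):
            self.n.gci1.append((self.name_of(ax.sub), self.name_of(ax.sup)))
        elif isinstance(ax, EquivalentClasses):
            a, b = self.name_of(ax.a), self.name_of(ax.b)
            self.n.gci1.append((a, b))
            self.n.gci1.append((b, a))
        else:
            raise UnsupportedConstructError(f"unsupported axiom: {ax!r}")


def normalize(onto: Ontology) -> NormalizedAxiomSet:
    """Normal-form translation; a conservative extension of the input over
    its original signature."""
    nz = _Normalizer()
    for cid in onto.classes:
        nz.n.names.add(cid)
    for ax in onto.axioms:
        nz.axiom(ax)
    for rid, role in onto.roles.items():
        if role.transitive:
            nz.n.chains.append((rid, rid, rid))
        if role.reflexive:
            nz.n.reflexive.add(rid)
        for sup in role.super_roles:
            nz.n.role_sub.append((rid, sup))
        for c1, c2 in role.chains:
            nz.n.chains.append((c1, c2, rid))
    return nz.n


# ---------------------------------------------------------------------------
# Saturation


def saturate(n: NormalizedAxiomSet) -> tuple[dict[str, set[str]],
                                             dict[str, set[tuple[str, str]]]]:
    """Least fixpoint of the completion rules.

    Returns ``S`` (context → entailed atomic superclasses) and ``R``
    (role → set of (X, Y) edges).
    """
    # indexes keyed by left-hand atoms
    by_sub: dict[str, list[str]] = {}
    for a, b in n.gci1:
        by_sub.setdefault(a, []).append(b)
    conj_index: dict[str, list[tuple[str, str]]] = {}
    for a1, a2, b in n.gci2:
        conj_index.setdefault(a1, []).append((a2, b))
        if a1 != a2:
            conj_index.setdefault(a2, []).append((a1, b))
    ex_rhs: dict[str, list[tuple[str, str]]] = {}     # A -> [(r, B)]   (gci3)
    for a, r, b in n.gci3:
        ex_rhs.setdefault(a, []).append((r, b))
    ex_lhs: dict[tuple[str, str], list[str]] = {}     # (r, A) -> [B]   (gci4)
    roles_with_lhs: dict[str, set[str]] = {}          # r -> fillers A used in gci4
    for r, a, b in n.gci4:
        ex_lhs.setdefault((r, a), []).append(b)
        roles_with_lhs.setdefault(r, set()).add(a)
    role_subs: dict[str, list[str]] = {}
    for r, s in n.role_sub:
        role_subs.setdefault(r, []).append(s)
    chains_by_first: dict[str, list[tuple[str, str]]] = {}
    chains_by_second: dict[str, list[tuple[str, str]]] = {}
    for r1, r2, s in n.chains:
        chains_by_first.setdefault(r1, []).append((r2, s))
        chains_by_second.setdefault(r2, []).append((r1, s))

    S: dict[str, set[str]] = {}
    R: dict[str, set[tuple[str, str]]] = {}
    out_edges: dict[str, set[tuple[str, str]]] = {}   # X -> {(r, Y)}
    in_edges: dict[str, set[tuple[str, str]]] = {}    # Y -> {(r, X)}

    queue: deque = deque()

    def add_sub(x: str, a: str) -> None:
        sx = S.setdefault(x, set())
        if a not in sx:
            sx.add(a)
            queue.append(("s", x, a))

    def add_edge(r: str, x: str, y: str) -> None:
        edges = R.setdefault(r, set())
        if (x, y) not in edges:
            edges.add((x, y))
            out_edges.setdefault(x, set()).add((r, y))
            in_edges.setdefault(y, set()).add((r, x))
            queue.append(("e", r, x, y))

    contexts = set(n.names) | {TOP, BOTTOM}
    for x in contexts:
        add_sub(x, x)
        add_sub(x, TOP)
        for r in n.reflexive:
            add_edge(r, x, x)

    while queue:
        item = queue.popleft()
        if item[0] == "s":
            _, x, a = item
            for b in by_sub.get(a, ()):                       # R1
                add_sub(x, b)
            for a2, b in conj_index.get(a, ()):               # R2
                if a2 in S[x]:
                    add_sub(x, b)
            for r, b in ex_rhs.get(a, ()):                    # R3
                add_edge(r, x, b)
            for r, x2 in tuple(in_edges.get(x, ())):          # R4 (A added to S(Y))
                for b in ex_lhs.get((r, a), ()):
                    add_sub(x2, b)
            if a == BOTTOM:                                   # R5 (⊥ added to S(Y))
                for _r, x2 in tuple(in_edges.get(x, ())):
                    add_sub(x2, BOTTOM)
        else:
            _, r, x, y = item
            for a in tuple(S.get(y, ())):                     # R4 (edge added)
                if a in roles_with_lhs.get(r, ()):
                    for b in ex_lhs.get((r, a), ()):
                        add_sub(x, b)
            if BOTTOM in S.get(y, ()):                        # R5
                add_sub(x, BOTTOM)
            for s in role_subs.get(r, ()):                    # R6
                add_edge(s, x, y)
            for r2, s in chains_by_first.get(r, ()):          # R7 left
                for r2b, z in tuple(out_edges.get(y, ())):
                    if r2b == r2:
                        add_edge(s, x, z)
            for r1, s in chains_by_second.get(r, ()):         # R7 right
                for r1b, w in tuple(in_edges.get(x, ())):
                    if r1b == r1:
                        add_edge(s, w, y)
    return S, R


# ---------------------------------------------------------------------------
# Classification


@dataclass
class Taxonomy:
    """Inferred hierarchy: equivalence groups over satisfiable named
    classes, a transitively reduced DAG of direct subclass edges between
    group representatives, and the unsatisfiable classes."""

    groups: dict[str, frozenset[str]]          # representative -> members
    direct_edges: set[tuple[str, str]]         # (child rep, parent rep)
    unsatisfiable: set[str]
    _member_to_rep: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._member_to_rep:
            for rep, members in self.groups.items():
                for m in members:
                    self._member_to_rep[m] = rep

    def representative(self, class_id: str) -> str:
        return self._member_to_rep[class_id]

    def equivalents(self, class_id: str) -> frozenset[str]:
        return self.groups[self.representative(class_id)]

    def direct_superclasses(self, class_id: str) -> set[str]:
        rep = self.representative(class_id)
        return {p for c, p in self.direct_edges if c == rep}

    def direct_subclasses(self, class_id: str) -> set[str]:
        rep = self.representative(class_id)
        return {c for c, p in self.direct_edges if p == rep}

    def ancestors(self, class_id: str) -> set[str]:
        out: set[str] = set()
        stack = [self.representative(class_id)]
        while stack:
            node = stack.pop()
            for child, parent in self.direct_edges:
                if child == node and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def is_subclass_of(self, sub: str, sup: str) -> bool:
        if sub in self.unsatisfiable:
            return True
        if sup in self.unsatisfiable:
            return False
        rsub, rsup = self.representative(sub), self.representative(sup)
        return rsub == rsup or rsup in self.ancestors(sub)

    def edges_tsv(self) -> str:
        lines = []
        for child, parent in sorted(self.direct_edges):
            for c in sorted(self.groups[child]):
                for p in sorted(self.groups[parent]):
                    lines.append(f"{c}\t{p}")
        return "\n".join(lines) + ("\n" if lines else "")


class Reasoner:
    """Saturated view over one ontology; answers subsumption, builds the
    taxonomy and evaluates DL queries."""

    def __init__(self, onto: Ontology):
        self.onto = onto
        self.normalized = normalize(onto)
        self.S, self.R = saturate(self.normalized)
        self.named = [c for c in onto.classes if c not in (TOP, BOTTOM)]

    def entailed_superclasses(self, class_id: str) -> set[str]:
        """Named classes Y with class_id ⊑ Y entailed (unsatisfiable
        classes are subclasses of everything)."""
        s = self.S.get(class_id, {class_id})
        if BOTTOM in s:
            return set(self.named)
        return {y for y in s if y in self.onto.classes and y not in (TOP, BOTTOM)}

    def is_entailed(self, sub: str, sup: str) -> bool:
        if sup == TOP or sub == BOTTOM:
            return True
        s = self.S.get(sub, {sub})
        return sup in s or BOTTOM in s

    def is_satisfiable(self, class_id: str) -> bool:
        return BOTTOM not in self.S.get(class_id, set())

    def subsumption_pairs(self) -> set[tuple[str, str]]:
        """All entailed (sub, super) pairs over the ontology's named
        classes; the shape the brute-force cross-check compares against."""
        out = set()
        for x in self.named:
            for y in self.entailed_superclasses(x):
                out.add((x, y))
        return out

    def taxonomy(self) -> Taxonomy:
        unsat = {x for x in self.named if not self.is_satisfiable(x)}
        sat = [x for x in self.named if x not in unsat]
        g = nx.DiGraph()
        g.add_nodes_from(sat)
        for x in sat:
            for y in self.S.get(x, ()):
                if y != x and y in self.onto.classes and y not in (TOP, BOTTOM) \
                        and y not in unsat:
                    g.add_edge(x, y)
        cond = nx.condensation(g)  # SCCs = equivalence groups
        groups: dict[str, frozenset[str]] = {}
        node_rep: dict[int, str] = {}
        for node, members in cond.nodes(data="members"):
            rep = min(members)
            node_rep[node] = rep
            groups[rep] = frozenset(members)
        reduced = nx.transitive_reduction(cond)
        edges = {(node_rep[u], node_rep[v]) for u, v in reduced.edges()}
        return Taxonomy(groups=groups, direct_edges=edges, unsatisfiable=unsat)


def classify(onto: Ontology) -> Taxonomy:
    return Reasoner(onto).taxonomy()


# ---------------------------------------------------------------------------
# DL queries


QUERY_NAME = "__query__"


@dataclass
class QueryResult:
    equivalents: list[str]
    direct_superclasses: list[str]
    direct_subclasses: list[str]
    satisfiable: bool


def query_expression(onto: Ontology, expr: ClassExpression) -> QueryResult:
    """Classify an anonymous class expression against the ontology.

    A fresh name defined equivalent to the expression is inserted, the
    ontology re-saturated, and the neighbors among the original named
    classes returned.  The fresh name never leaks into the input ontology.
    """
    work = onto.copy()
    work.equivalent(Atomic(QUERY_NAME), expr)
    r = Reasoner(work)
    named = [c for c in onto.classes if c not in (TOP, BOTTOM)]
    if not r.is_satisfiable(QUERY_NAME):
        bottoms = sorted(c for c in named if not r.is_satisfiable(c))
        return QueryResult(equivalents=bottoms, direct_superclasses=[],
                           direct_subclasses=[], satisfiable=False)
    supers = {y for y in named if r.is_entailed(QUERY_NAME, y)
              and r.is_satisfiable(y)}
    subs = {y for y in named if r.is_entailed(y, QUERY_NAME)
            and r.is_satisfiable(y)}
    equivalents = sorted(supers & subs)
    strict_supers = supers - set(equivalents)
    strict_subs = subs - set(equivalents)
    direct_supers = sorted(
        y for y in strict_supers
        if not any(z != y and r.is_entailed(z, y) and not r.is_entailed(y, z)
                   for z in strict_supers))
    direct_subs = sorted(
        y for y in strict_subs
        if not any(z != y and r.is_entailed(y, z) and not r.is_entailed(z, y)
                   for z in strict_subs))
    return QueryResult(equivalents=equivalents,
                       direct_superclasses=direct_supers,
                       direct_subclasses=direct_subs,
                       satisfiable=True)
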