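"""Independent brute-force EL subsumption oracle.

Deliberately shares no code with the package's reasoner: its own
normalizer (n-ary conjunction facts, its own fresh-name scheme) and a
naive apply-all-rules-until-no-change fixpoint with no worklist.  Also
provides the seeded random-ontology generator used to cross-check the two
engines.
"""

from __future__ import annotations

import random

from florapheno.model import (Atomic, BOTTOM, Conjunction, EquivalentClasses,
                              Existential, Ontology, SubClassOf, TOP, conj,
                              some)


def _flatten(onto: Ontology):
    """Own normalization: returns (subs, conjs, ex_rhs, ex_lhs, names).

    subs: (A, B) meaning A ⊑ B; conjs: (ops tuple, B) meaning ⊓ops ⊑ B;
    ex_rhs: (A, r, B) meaning A ⊑ ∃r.B; ex_lhs: (r, B, A) meaning ∃r.B ⊑ A.
    """
    subs, conjs, ex_rhs, ex_lhs = [], [], [], []
    names = set(onto.classes) | {TOP, BOTTOM}
    memo: dict[str, str] = {}
    counter = [0]

    def name(expr) -> str:
        if isinstance(expr, Atomic):
            names.add(expr.class_id)
            return expr.class_id
        key = repr(expr)
        if key in memo:
            return memo[key]
        n = f"@oracle{counter[0]}"
        counter[0] += 1
        names.add(n)
        memo[key] = n
        if isinstance(expr, Existential):
            f = name(expr.filler)
            ex_rhs.append((n, expr.role_id, f))
            ex_lhs.append((expr.role_id, f, n))
        elif isinstance(expr, Conjunction):
            ops = tuple(name(op) for op in expr.operands)
            for op in ops:
                subs.append((n, op))
            conjs.append((ops, n))
        else:
            raise TypeError(f"unsupported {expr!r}")
        return n

    for ax in onto.axioms:
        if isinstance(ax, SubClassOf):
            subs.append((name(ax.sub), name(ax.sup)))
        elif isinstance(ax, EquivalentClasses):
            a, b = name(ax.a), name(ax.b)
            subs.append((a, b))
            subs.append((b, a))
    return subs, conjs, ex_rhs, ex_lhs, names


def oracle_entailed_pairs(onto: Ontology) -> set[tuple[str, str]]:
    """All entailed (sub, super) pairs over the ontology's named classes,
    with unsatisfiable classes subsuming under everything."""
    subs, conjs, ex_rhs, ex_lhs, names = _flatten(onto)
    roles = set(onto.roles)
    for _a, r, _b in ex_rhs:
        roles.add(r)
    role_super: dict[str, set[str]] = {r: {r} for r in roles}
    # transitive closure of the role hierarchy, naively
    changed = True
    while changed:
        changed = False
        for r in roles:
            for s in list(role_super[r]):
                for t in onto.roles.get(s, None).super_roles if s in onto.roles else ():
                    if t not in role_super[r]:
                        role_super[r].add(t)
                        role_super.setdefault(t, {t})
                        changed = True
    chains = []
    reflexive = set()
    for rid, role in onto.roles.items():
        if role.transitive:
            chains.append((rid, rid, rid))
        if role.reflexive:
            reflexive.add(rid)
        for c1, c2 in role.chains:
            chains.append((c1, c2, rid))

    S: dict[str, set[str]] = {x: {x, TOP} for x in names}
    R: dict[str, set[tuple[str, str]]] = {r: set() for r in role_super}
    for r in reflexive:
        for s in role_super.get(r, {r}):
            R.setdefault(s, set()).update((x, x) for x in names)

    changed = True
    while changed:
        changed = False

        def put(x, a):
            nonlocal changed
            if a not in S[x]:
                S[x].add(a)
                changed = True

        def edge(r, x, y):
            nonlocal changed
            for s in role_super.get(r, {r}):
                es = R.setdefault(s, set())
                if (x, y) not in es:
                    es.add((x, y))
                    changed = True

        for x in names:
            sx = S[x]
            for a, b in subs:
                if a in sx:
                    put(x, b)
            for ops, b in conjs:
                if all(op in sx for op in ops):
                    put(x, b)
            for a, r, b in ex_rhs:
                if a in sx:
                    edge(r, x, b)
        for r, b, a in ex_lhs:
            for x, y in list(R.get(r, ())):
                if b in S[y]:
                    put(x, a)
        for r, edges in list(R.items()):
            for x, y in list(edges):
                if BOTTOM in S[y]:
                    put(x, BOTTOM)
        for r1, r2, s in chains:
            by_src = {}
            for y, z in R.get(r2, ()):
                by_src.setdefault(y, []).append(z)
            for x, y in list(R.get(r1, ())):
                for z in by_src.get(y, ()):
                    edge(s, x, z)

    named = [c for c in onto.classes if c not in (TOP, BOTTOM)]
    pairs = set()
    for x in named:
        if BOTTOM in S[x]:
            pairs.update((x, y) for y in named)
        else:
            pairs.update((x, y) for y in S[x] if y in onto.classes
                         and y not in (TOP, BOTTOM))
    return pairs


# ---------------------------------------------------------------------------
# Random EL ontologies


def random_el_ontology(seed: int, max_classes: int = 40, max_roles: int = 4,
                       max_axioms: int = 60) -> Ontology:
    rng = random.Random(seed)
    n_classes = rng.randint(3, max_classes)
    n_roles = rng.randint(1, max_roles)
    classes = [f"C:{i}" for i in range(n_classes)]
    roles = [f"r{i}" for i in range(n_roles)]
    onto = Ontology()
    for c in classes:
        onto.add_class(c)
    for r in roles:
        role = onto.add_role(r)
        role.transitive = rng.random() < 0.3
        role.reflexive = rng.random() < 0.2
        if rng.random() < 0.3:
            role.super_roles.add(rng.choice(roles))
        if rng.random() < 0.2:
            role.chains.add((rng.choice(roles), rng.choice(roles)))

    def rand_expr(depth: int):
        roll = rng.random()
        if depth == 0 or roll < 0.45:
            return Atomic(rng.choice(classes))
        if roll < 0.8:
            return some(rng.choice(roles), rand_expr(depth - 1))
        return conj(rand_expr(depth - 1), rand_expr(depth - 1))

    for _ in range(rng.randint(3, max_axioms)):
        roll = rng.random()
        if roll < 0.08:
            # occasional disjointness to exercise Bottom propagation
            onto.add_axiom(SubClassOf(
                conj(Atomic(rng.choice(classes)), Atomic(rng.choice(classes))),
                Atomic(BOTTOM)))
        elif roll < 0.25:
            onto.add_axiom(EquivalentClasses(Atomic(rng.choice(classes)),
                                             rand_expr(2)))
        else:
            onto.add_axiom(SubClassOf(rand_expr(2), rand_expr(2)))
    return onto
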