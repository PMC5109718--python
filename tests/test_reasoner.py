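"""EL completion-rule engine: saturation, classification, queries, and
agreement with an independent brute-force oracle."""

import pytest

from florapheno.model import (Atomic, BOTTOM, Ontology, SubClassOf, TOP, conj,
                              some)
from florapheno.reasoner import (Reasoner, UnsupportedConstructError, classify,
                                 normalize, query_expression, saturate)

from oracle_el import oracle_entailed_pairs, random_el_ontology


class TestNormalization:
    def test_atomic_inclusion_unchanged(self):
        o = Ontology()
        o.subclass_of("A", "B")
        n = normalize(o)
        assert ("A", "B") in n.gci1

    def test_transitivity_becomes_self_chain(self):
        o = Ontology()
        o.add_role("part_of", transitive=True)
        n = normalize(o)
        assert ("part_of", "part_of", "part_of") in n.chains

    def test_nested_equivalence_is_entailment_preserved(self):
        o = Ontology()
        o.equivalent("X", some("h", conj(Atomic("A"), some("q", "B"))))
        o.subclass_of("A", "A2")
        o.equivalent("Y", some("h", conj(Atomic("A2"), some("q", "B"))))
        assert Reasoner(o).subsumption_pairs() == oracle_entailed_pairs(o)
        assert Reasoner(o).is_entailed("X", "Y")


class TestSaturation:
    def test_initialization_invariant(self):
        o = Ontology()
        o.subclass_of("A", "B")
        S, _ = saturate(normalize(o))
        for x in ("A", "B"):
            assert x in S[x] and TOP in S[x]

    def test_reflexivity_consequence(self, structure_ont):
        """With reflexive part-of, flower ⊑ ∃part-of.flower holds, so the
        subclasses of ∃part-of.flower include flower itself."""
        o = structure_ont.copy()
        o.equivalent("Q:partof_flower", some("part_of", "PO:0009046"))
        r = Reasoner(o)
        for sub in ("PO:0009046", "PO:0009032", "PO:0009061"):
            assert r.is_entailed(sub, "Q:partof_flower")

    def test_chain_through_intermediate_structure(self, structure_ont):
        """stamen is part of androecium is part of flower; transitivity
        entails stamen ⊑ ∃part-of.flower."""
        o = structure_ont.copy()
        o.equivalent("Q:partof_flower", some("part_of", "PO:0009046"))
        assert Reasoner(o).is_entailed("PO:0009029", "Q:partof_flower")

    def test_bottom_propagates_through_existentials(self):
        o = Ontology()
        o.subclass_of("A", Atomic(BOTTOM))
        o.subclass_of("X", some("r", "A"))
        r = Reasoner(o)
        assert not r.is_satisfiable("X")


class TestClassify:
    def test_equivalent_pair_forms_one_group(self):
        o = Ontology()
        o.equivalent("A", "B")
        o.subclass_of("A", "C")
        tax = classify(o)
        assert tax.equivalents("A") == frozenset({"A", "B"})
        assert tax.direct_superclasses("B") == {"C"}

    def test_transitive_reduction_has_no_shortcut_edges(self):
        o = Ontology()
        o.subclass_of("A", "B")
        o.subclass_of("B", "C")
        o.subclass_of("A", "C")  # redundant
        tax = classify(o)
        assert tax.direct_edges == {("A", "B"), ("B", "C")}

    def test_reduction_closure_reproduces_entailment(self):
        onto = random_el_ontology(7)
        r = Reasoner(onto)
        tax = r.taxonomy()
        for x in r.named:
            if x in tax.unsatisfiable:
                continue
            entailed = {y for y in r.entailed_superclasses(x)
                        if y not in tax.unsatisfiable and y != x}
            via_dag = set()
            for rep in tax.ancestors(x) | {tax.representative(x)}:
                via_dag |= tax.groups[rep]
            via_dag -= {x}
            assert {y for y in entailed
                    if not r.is_entailed(y, x)} <= via_dag
            assert via_dag <= entailed | tax.equivalents(x)

    def test_classification_is_idempotent(self, default_build):
        tax1 = default_build.taxonomy
        tax2 = classify(default_build.ontology)
        assert tax1.groups == tax2.groups
        assert tax1.direct_edges == tax2.direct_edges
        assert tax1.unsatisfiable == tax2.unsatisfiable

    def test_unsupported_axiom_named_in_error(self):
        o = Ontology()
        o.axioms.append(object())  # type: ignore[arg-type]
        with pytest.raises((UnsupportedConstructError, TypeError)):
            classify(o)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(0, 20))
    def test_random_ontology_matches_brute_force(self, seed):
        onto = random_el_ontology(seed)
        assert Reasoner(onto).subsumption_pairs() == oracle_entailed_pairs(onto)

    def test_monotonicity_under_axiom_addition(self):
        onto = random_el_ontology(3)
        before = Reasoner(onto).subsumption_pairs()
        onto.subclass_of("C:0", some("r0", "C:1"))
        onto.subclass_of("C:1", "C:2")
        after = Reasoner(onto).subsumption_pairs()
        assert before <= after


class TestQueries:
    def test_query_equal_to_defined_class_is_equivalent(self, default_build,
                                                        label_to_id):
        gc = next(g for g in default_build.generated if g.label == "flower red")
        res = query_expression(default_build.ontology, gc.definiens)
        assert gc.flopo_id in res.equivalents

    def test_query_name_does_not_leak(self, default_build):
        onto = default_build.ontology
        n_axioms = len(onto.axioms)
        query_expression(onto, Atomic("PO:0009046"))
        assert len(onto.axioms) == n_axioms
        assert "__query__" not in onto.classes

    def test_unsatisfiable_query_flagged(self, default_build, pattern_cfg):
        from florapheno.fixtures import ACUTE, LEAF
        expr = some(pattern_cfg.has_part_role,
                    conj(Atomic(LEAF),
                         some(pattern_cfg.has_quality_role, ACUTE)))
        res = query_expression(default_build.ontology, expr)
        assert not res.satisfiable

    def test_unsatisfiable_query_reports_bottom_equivalents(self,
                                                            default_build):
        onto = default_build.ontology.copy()
        onto.subclass_of("X:doomed", Atomic(BOTTOM))
        res = query_expression(onto, conj(Atomic("X:doomed"),
                                          Atomic("PO:0009046")))
        assert not res.satisfiable
        assert res.equivalents == ["X:doomed"]
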