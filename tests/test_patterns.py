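"""The three axiom patterns, attribute promotion, the process-quality
exclusion, id assignment, and the assembled ontology's inferences."""

import pytest

from florapheno import fixtures as fx
from florapheno.mining import EQRecord
from florapheno.model import Atomic, Ontology, conj, some
from florapheno.patterns import (GeneratedClass, IdMapError, PatternConfig,
                                 apply_inheres_prefix, assign_ids,
                                 build_ontology, exclusion_axiom,
                                 gen_phenotype_class, gen_trait_class,
                                 gen_value_class, id_map_from_tsv,
                                 id_map_to_tsv, promote_to_attribute)
from florapheno.model import BOTTOM, SubClassOf
from florapheno.reasoner import Reasoner, classify, query_expression


def rec(entity, quality, taxon="TX:0001", placeholder=False):
    return EQRecord(taxon_id=taxon, entity_class=entity, quality_class=quality,
                    sentence="synthetic", relational_placeholder=placeholder)


class TestPatternShapes:
    def test_phenotype_grouping_class(self, structure_ont, pattern_cfg):
        gc = gen_phenotype_class(fx.FLOWER, structure_ont, pattern_cfg)
        assert gc.label == "flower phenotype"
        assert gc.definiens == some("has_part",
                                    conj(some("part_of", fx.FLOWER),
                                         some("has_quality", fx.QUALITY_ROOT)))

    def test_value_class_binds_entity_directly(self, structure_ont,
                                               quality_ont, pattern_cfg):
        gc = gen_value_class(fx.FLOWER, fx.RED, structure_ont, quality_ont,
                             pattern_cfg)
        assert gc.label == "flower red"
        assert gc.definiens == some("has_part",
                                    conj(Atomic(fx.FLOWER),
                                         some("has_quality", fx.RED)))

    def test_trait_class_same_shape_as_value(self, structure_ont, quality_ont,
                                             pattern_cfg):
        gc = gen_trait_class(fx.FLOWER, fx.COLOR, structure_ont, quality_ont,
                             pattern_cfg)
        assert gc.label == "flower color"
        assert gc.pattern == "trait"
        assert gc.definiens == some("has_part",
                                    conj(Atomic(fx.FLOWER),
                                         some("has_quality", fx.COLOR)))

    def test_unknown_entity_or_quality_rejected(self, structure_ont,
                                                quality_ont, pattern_cfg):
        with pytest.raises(KeyError):
            gen_phenotype_class("PO:9999999", structure_ont, pattern_cfg)
        with pytest.raises(KeyError):
            gen_value_class(fx.FLOWER, fx.FLOWER, structure_ont, quality_ont,
                            pattern_cfg)


class TestPromotion:
    def test_value_promotes_to_its_attribute(self, quality_ont, pattern_cfg):
        assert promote_to_attribute(fx.RED, quality_ont, pattern_cfg) == \
            {fx.COLOR}

    def test_attribute_promotes_to_itself(self, quality_ont, pattern_cfg):
        assert promote_to_attribute(fx.COLOR, quality_ont, pattern_cfg) == \
            {fx.COLOR}

    def test_promotion_skips_value_subset_ancestors(self, quality_ont,
                                                    pattern_cfg):
        # deep pink ⊑ pink ⊑ color: pink is a value, color the attribute
        assert promote_to_attribute(fx.DEEP_PINK, quality_ont, pattern_cfg) \
            == {fx.COLOR}

    def test_quality_under_two_incomparable_attributes(self, pattern_cfg):
        o = Ontology()
        for cid, tag in (("Q:a1", True), ("Q:a2", True), ("Q:v", False)):
            meta = o.add_class(cid, label=cid)
            if tag:
                meta.subsets.add(pattern_cfg.attribute_subset_tag)
        o.subclass_of("Q:v", "Q:a1")
        o.subclass_of("Q:v", "Q:a2")
        assert promote_to_attribute("Q:v", o, pattern_cfg) == {"Q:a1", "Q:a2"}

    def test_no_attribute_ancestor_gives_empty_set(self, quality_ont,
                                                   pattern_cfg):
        assert promote_to_attribute(fx.ACUTE, quality_ont, pattern_cfg) == set()


class TestExclusion:
    def test_axiom_shape(self, pattern_cfg):
        ax = exclusion_axiom(pattern_cfg)
        assert ax == SubClassOf(
            conj(Atomic(fx.STRUCTURE_ROOT),
                 some("has_quality", fx.PROCESS_QUALITY)),
            Atomic(BOTTOM))

    def test_unconfigured_root_is_error(self):
        with pytest.raises(ValueError):
            exclusion_axiom(PatternConfig(process_quality_root=None))

    def test_process_pairs_become_unsatisfiable_and_excluded(
            self, structure_ont, quality_ont, pattern_cfg):
        records = [rec(fx.LEAF, fx.ACUTE), rec(fx.STEM, fx.ACUTE),
                   rec(fx.PETAL, fx.ACUTE), rec(fx.FLOWER, fx.RED)]
        build = build_ontology(records, structure_ont, quality_ont,
                               pattern_cfg)
        assert sorted(gc.label for gc in build.excluded) == \
            ["leaf acute", "petal acute", "stem acute"]
        assert all(gc.deprecated for gc in build.excluded)
        kept = {gc.label for gc in build.generated}
        assert "flower red" in kept and "leaf acute" not in kept
        # the deprecated ids appear in the report and stay in the ontology
        report = build.deprecation_report().splitlines()
        assert len(report) == 3
        for cid in report:
            assert build.ontology.classes[cid].deprecated

    def test_no_process_pairs_no_exclusions(self, structure_ont, quality_ont,
                                            pattern_cfg):
        build = build_ontology([rec(fx.FLOWER, fx.RED)], structure_ont,
                               quality_ont, pattern_cfg)
        assert build.excluded == []
        assert any(ax == exclusion_axiom(pattern_cfg)
                   for ax in build.ontology.axioms)


class TestAssignIds:
    def _classes(self, structure_ont, quality_ont, pattern_cfg, pairs):
        out = []
        for e, q in pairs:
            out.append(gen_value_class(e, q, structure_ont, quality_ont,
                                       pattern_cfg))
        return out

    def test_ids_are_padded_ordered_and_deterministic(
            self, structure_ont, quality_ont, pattern_cfg):
        classes = self._classes(structure_ont, quality_ont, pattern_cfg,
                                [(fx.PETAL, fx.RED), (fx.FLOWER, fx.RED)])
        assign_ids(classes, pattern_cfg)
        by_label = {c.label: c.flopo_id for c in classes}
        assert by_label == {"flower red": "FLOPO:0000001",
                            "petal red": "FLOPO:0000002"}
        again = self._classes(structure_ont, quality_ont, pattern_cfg,
                              [(fx.PETAL, fx.RED), (fx.FLOWER, fx.RED)])
        assign_ids(again, pattern_cfg)
        assert {c.label: c.flopo_id for c in again} == by_label

    def test_persisted_map_keeps_old_ids_and_appends_new(
            self, structure_ont, quality_ont, pattern_cfg):
        first = self._classes(structure_ont, quality_ont, pattern_cfg,
                              [(fx.PETAL, fx.RED)])
        id_map = assign_ids(first, pattern_cfg)
        grown = self._classes(structure_ont, quality_ont, pattern_cfg,
                              [(fx.PETAL, fx.RED), (fx.FLOWER, fx.RED)])
        id_map2 = assign_ids(grown, pattern_cfg,
                             id_map=id_map_from_tsv(id_map_to_tsv(id_map)))
        assert id_map2[("value", fx.PETAL, fx.RED)] == \
            id_map[("value", fx.PETAL, fx.RED)]
        assert len(set(id_map2.values())) == 2

    def test_reserved_deprecated_ids_never_reused(self, structure_ont,
                                                  quality_ont, pattern_cfg):
        classes = self._classes(structure_ont, quality_ont, pattern_cfg,
                                [(fx.FLOWER, fx.RED)])
        assign_ids(classes, pattern_cfg, reserved_ids=["FLOPO:0000001"])
        assert classes[0].flopo_id == "FLOPO:0000002"

    def test_colliding_persisted_map_is_error(self, structure_ont,
                                              quality_ont, pattern_cfg):
        id_map = {("value", fx.FLOWER, fx.RED): "FLOPO:0000001",
                  ("value", fx.PETAL, fx.RED): "FLOPO:0000001"}
        with pytest.raises(IdMapError):
            assign_ids([], pattern_cfg, id_map=id_map)


class TestBuildOntology:
    def test_single_pair_generates_exactly_three_classes(
            self, structure_ont, quality_ont, pattern_cfg):
        build = build_ontology([rec(fx.FLOWER, fx.RED)], structure_ont,
                               quality_ont, pattern_cfg)
        assert sorted(gc.label for gc in build.generated) == \
            ["flower color", "flower phenotype", "flower red"]

    def test_two_pairs_share_nothing_but_patterns(self, structure_ont,
                                                  quality_ont, pattern_cfg):
        build = build_ontology([rec(fx.FLOWER, fx.RED), rec(fx.PETAL, fx.RED)],
                               structure_ont, quality_ont, pattern_cfg)
        assert sorted(gc.label for gc in build.generated) == \
            ["flower color", "flower phenotype", "flower red",
             "petal color", "petal phenotype", "petal red"]

    def test_attribute_mined_directly_yields_single_class(
            self, structure_ont, quality_ont, pattern_cfg):
        """A directly mined attribute is not in the value subset, so the
        promotion step is skipped and 'flower color' exists exactly once
        (as the value-pattern class)."""
        build = build_ontology([rec(fx.FLOWER, fx.COLOR),
                                rec(fx.FLOWER, fx.RED)],
                               structure_ont, quality_ont, pattern_cfg)
        color_classes = [gc for gc in build.generated
                         if gc.label == "flower color"]
        assert len(color_classes) == 1
        assert color_classes[0].pattern == "trait"

    def test_placeholder_record_contributes_only_phenotype_class(
            self, structure_ont, quality_ont, pattern_cfg):
        build = build_ontology([rec(fx.STEM, fx.CONNECTED, placeholder=True)],
                               structure_ont, quality_ont, pattern_cfg)
        assert [gc.label for gc in build.generated] == ["stem phenotype"]

    def test_empty_records_only_inputs_plus_exclusion(self, structure_ont,
                                                      quality_ont, pattern_cfg):
        build = build_ontology([], structure_ont, quality_ont, pattern_cfg)
        assert build.generated == []
        expected = set(structure_ont.normalized_axioms()) \
            | set(quality_ont.normalized_axioms()) \
            | {repr(exclusion_axiom(pattern_cfg))}
        assert set(build.ontology.normalized_axioms()) == expected

    def test_deduplication_across_taxa(self, structure_ont, quality_ont,
                                       pattern_cfg):
        records = [rec(fx.FLOWER, fx.RED, taxon=f"TX:{i:04d}")
                   for i in range(5)]
        build = build_ontology(records, structure_ont, quality_ont,
                               pattern_cfg)
        assert len(build.generated) == 3

    def test_determinism(self, default_records, structure_ont, quality_ont,
                         pattern_cfg):
        from florapheno.ofn import write_ofn
        b1 = build_ontology(default_records, structure_ont, quality_ont,
                            pattern_cfg)
        b2 = build_ontology(list(reversed(default_records)), structure_ont,
                            quality_ont, pattern_cfg)
        assert write_ofn(b1.ontology) == write_ofn(b2.ontology)


class TestInferences:
    def test_value_below_trait_below_phenotype(self, default_build,
                                               label_to_id):
        tax = default_build.taxonomy
        assert tax.is_subclass_of(label_to_id["flower red"],
                                  label_to_id["flower color"])
        assert tax.is_subclass_of(label_to_id["flower color"],
                                  label_to_id["flower phenotype"])

    def test_parthood_grouping(self, default_build, label_to_id):
        tax = default_build.taxonomy
        assert tax.is_subclass_of(label_to_id["petal phenotype"],
                                  label_to_id["flower phenotype"])
        assert tax.is_subclass_of(label_to_id["stamen phenotype"],
                                  label_to_id["flower phenotype"])

    def test_no_grouping_at_trait_level(self, default_build, label_to_id):
        """Traits of parts are not traits of the whole: petal red must not
        fall under flower red."""
        tax = default_build.taxonomy
        assert not tax.is_subclass_of(label_to_id["petal red"],
                                      label_to_id["flower red"])

    def test_composability_of_disjoint_part_phenotypes(
            self, default_build, label_to_id):
        """flower and stamen are disjoint, yet the conjunction of 'flower
        red' and 'stamen yellow' stays satisfiable thanks to the has-part
        prefix."""
        combined = conj(Atomic(label_to_id["flower red"]),
                        Atomic(label_to_id["stamen yellow"]))
        res = query_expression(default_build.ontology, combined)
        assert res.satisfiable

    def test_primary_axis_is_anatomy(self, default_build, structure_ont,
                                     pattern_cfg):
        """Among grouping classes, every ancestry step mirrors an entailed
        parthood between the underlying structures."""
        pheno = {gc.flopo_id: gc.entity_class
                 for gc in default_build.generated if gc.pattern == "phenotype"}
        sr = Reasoner(structure_ont)
        tax = default_build.taxonomy
        part_of = pattern_cfg.part_of_role
        probe = structure_ont.copy()
        for cid in set(pheno.values()):
            probe.equivalent(f"Q:in_{cid}", some(part_of, cid))
        pr = Reasoner(probe)
        for a, ea in pheno.items():
            for b, eb in pheno.items():
                if a != b and tax.is_subclass_of(a, b):
                    assert pr.is_entailed(ea, f"Q:in_{eb}")


class TestInheresPrefix:
    def test_definitions_wrapped(self, default_build, pattern_cfg):
        from florapheno.model import EquivalentClasses, Existential
        out = apply_inheres_prefix(default_build.ontology, pattern_cfg)
        wrapped = [ax for ax in out.axioms
                   if isinstance(ax, EquivalentClasses)
                   and isinstance(ax.a, Atomic)
                   and ax.a.class_id.startswith("FLOPO:")]
        assert wrapped
        for ax in wrapped:
            assert isinstance(ax.b, Existential)
            assert ax.b.role_id == pattern_cfg.inheres_in_role

    def test_subsumption_dag_among_generated_unchanged(self, default_build,
                                                       pattern_cfg):
        out = apply_inheres_prefix(default_build.ontology, pattern_cfg)
        tax2 = classify(out)
        ids = sorted(gc.flopo_id for gc in default_build.generated)
        tax1 = default_build.taxonomy

        def dag(t):
            return {(a, b) for a in ids for b in ids
                    if a != b and t.is_subclass_of(a, b)}
        assert dag(tax1) == dag(tax2)

    def test_empty_ontology_unchanged(self, pattern_cfg):
        o = Ontology()
        out = apply_inheres_prefix(o, pattern_cfg)
        assert out.axioms == []
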