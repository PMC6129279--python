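"""EQ decomposition, regulation indexing, and rule/pattern generation."""

import io

import pytest

from phenorules.fixtures import FixtureSpec, default_quality_config, make_toy_ontologies
from phenorules.ontology import parse_obo
from phenorules.rules import (
    ABN,
    ABNORMAL,
    DEC_INC,
    DECREASED,
    INC_DEC,
    INCREASED,
    NEGATIVE,
    POSITIVE,
    CorrespondenceRule,
    EQDecomposition,
    InconsistencyPattern,
    QualityConfig,
    RegulationRecord,
    build_correspondence_rules,
    build_inconsistency_patterns,
    decompose_all,
    decompose_phenotype_class,
    index_regulations,
    write_rules_tsv,
)

HEADER = "format-version: 1.2\n\n"


# -- oracles -----------------------------------------------------------------

def join_oracle(regs, decs):
    """Independent double-loop join producing the expected rule set."""
    rules = set()
    for dec in decs:
        if dec.direction == ABNORMAL:
            rules.add((dec.entity, dec.phenotype_class, ABN))
        for reg in regs:
            if reg.regulated != dec.entity:
                continue
            if reg.sign == POSITIVE and dec.direction == DECREASED:
                rules.add((reg.regulator, dec.phenotype_class, INC_DEC))
            if reg.sign == NEGATIVE and dec.direction == INCREASED:
                rules.add((reg.regulator, dec.phenotype_class, DEC_INC))
    return rules


def mirror_join_oracle(regs, decs):
    pats = set()
    for dec in decs:
        for reg in regs:
            if reg.regulated != dec.entity:
                continue
            if reg.sign == POSITIVE and dec.direction == INCREASED:
                pats.add((reg.regulator, dec.phenotype_class, INC_DEC))
            if reg.sign == NEGATIVE and dec.direction == DECREASED:
                pats.add((reg.regulator, dec.phenotype_class, DEC_INC))
    return pats


# -- decomposition -----------------------------------------------------------

def test_decompose_increased_thymocyte_apoptosis(worked_pheno, worked_quality_config):
    dec = decompose_phenotype_class(worked_pheno, "MP:0009541", worked_quality_config)
    assert dec == EQDecomposition("MP:0009541", "GO:0070242", INCREASED)


def test_abnormal_modifier_does_not_override_direction(worked_pheno, worked_quality_config):
    # MP:0006043 carries both PATO:0000911 and the abnormal modifier
    dec = decompose_phenotype_class(worked_pheno, "MP:0006043", worked_quality_config)
    assert dec.direction == DECREASED


def test_non_go_entity_yields_none():
    text = HEADER + (
        "[Term]\nid: UBERON:0000001\nname: anatomical thing\n\n"
        "[Term]\nid: MP:0000009\nname: abnormal anatomy\n"
        "intersection_of: phenotype_of UBERON:0000001\n"
        "intersection_of: has_quality PATO:0000460\n\n"
    )
    graph = parse_obo(text.splitlines())
    assert decompose_phenotype_class(graph, "MP:0000009") is None


def test_class_without_logical_definition_yields_none(worked_pheno, worked_quality_config):
    assert decompose_phenotype_class(worked_pheno, "MP:0008236", worked_quality_config) is None


def test_ambiguous_direction_yields_none():
    text = HEADER + (
        "[Term]\nid: GO:0000001\nname: p\n\n"
        "[Term]\nid: MP:0000002\nname: confusing\n"
        "intersection_of: phenotype_of GO:0000001\n"
        "intersection_of: has_quality PATO:0000912\n"
        "intersection_of: has_quality PATO:0000911\n\n"
    )
    graph = parse_obo(text.splitlines())
    assert decompose_phenotype_class(graph, "MP:0000002", default_quality_config()) is None


def test_planted_eq_classes_recovered_field_by_field():
    spec = FixtureSpec(n_processes=4, n_regulators_pos=0, n_regulators_neg=0,
                       eq_coverage=1.0, seed=3)
    _, pheno, plant_log = make_toy_ontologies(spec)
    decs = decompose_all(pheno, default_quality_config())
    assert len(plant_log["eq"]) == 12  # 4 processes x 3 directions
    assert {(d.phenotype_class, d.entity, d.direction) for d in decs} == {
        tuple(e) for e in plant_log["eq"]
    }


def test_quality_sets_must_be_disjoint():
    with pytest.raises(ValueError, match="disjoint"):
        QualityConfig(
            increased_qualities=frozenset({"PATO:0000912"}),
            decreased_qualities=frozenset({"PATO:0000912"}),
        )


# -- regulation index --------------------------------------------------------

def test_positive_regulation_record(worked_go):
    regs = index_regulations(worked_go)
    assert RegulationRecord("GO:0002904", "GO:0001783", POSITIVE) in regs
    assert RegulationRecord("GO:0043066", "GO:0006915", NEGATIVE) in regs


def test_no_regulation_definitions_gives_empty_list(worked_pheno):
    assert index_regulations(worked_pheno) == []


def test_planted_regulations_match_plant_log():
    spec = FixtureSpec(seed=11)
    go, _, plant_log = make_toy_ontologies(spec)
    regs = index_regulations(go)
    assert len(regs) == 40
    assert {(r.regulator, r.regulated, r.sign) for r in regs} == {
        tuple(r) for r in plant_log["regulations"]
    }


def test_genus_filter_restricts_to_regulation_subtree(worked_go):
    assert index_regulations(worked_go, genus="GO:0065007") == index_regulations(worked_go)
    assert index_regulations(worked_go, genus="GO:0001783") == []


def test_relationship_fallback_adds_records():
    text = HEADER + (
        "[Term]\nid: GO:0000001\nname: p\n\n"
        "[Term]\nid: GO:0000002\nname: reg of p\n"
        "relationship: positively_regulates GO:0000001\n\n"
    )
    graph = parse_obo(text.splitlines())
    assert index_regulations(graph) == []
    assert index_regulations(graph, use_relationship_fallback=True) == [
        RegulationRecord("GO:0000002", "GO:0000001", POSITIVE)
    ]


# -- rule and pattern generation ---------------------------------------------

def test_positive_regulation_joins_decreased_phenotype():
    regs = [RegulationRecord("GO:0002904", "GO:0001783", POSITIVE)]
    decs = [EQDecomposition("MP:0000100", "GO:0001783", DECREASED)]
    assert build_correspondence_rules(regs, decs) == [
        CorrespondenceRule("GO:0002904", "MP:0000100", INC_DEC)
    ]


def test_abnormal_rule_is_unconditional_on_regulation():
    decs = [EQDecomposition("MP:0000101", "GO:0001783", ABNORMAL)]
    assert build_correspondence_rules([], decs) == [
        CorrespondenceRule("GO:0001783", "MP:0000101", ABN)
    ]


def test_mirror_pair_becomes_inconsistency_pattern():
    regs = [RegulationRecord("GO:0002904", "GO:0001783", POSITIVE)]
    decs = [EQDecomposition("MP:0008782", "GO:0001783", INCREASED)]
    assert build_inconsistency_patterns(regs, decs) == [
        InconsistencyPattern("GO:0002904", "MP:0008782", INC_DEC)
    ]
    assert build_inconsistency_patterns(regs, []) == []


def test_generated_rules_equal_brute_force_join(toy):
    got = {(r.function_class, r.phenotype_class, r.rule_kind) for r in toy["rules"]}
    assert got == join_oracle(toy["regs"], toy["decs"])
    got_p = {(p.function_class, p.phenotype_class, p.violated_rule)
             for p in toy["patterns"]}
    assert got_p == mirror_join_oracle(toy["regs"], toy["decs"])


def test_rule_and_pattern_pairs_are_disjoint(toy):
    rule_pairs = {(r.function_class, r.phenotype_class) for r in toy["rules"]}
    pattern_pairs = {(p.function_class, p.phenotype_class) for p in toy["patterns"]}
    assert not rule_pairs & pattern_pairs


def test_sign_swap_exchanges_rules_and_patterns(toy):
    """Metamorphic: flipping every regulation sign turns each directional
    rule pair into the mirrored pattern pair and vice versa."""
    swapped = [
        RegulationRecord(r.regulator, r.regulated,
                         NEGATIVE if r.sign == POSITIVE else POSITIVE)
        for r in toy["regs"]
    ]
    swapped_rules = build_correspondence_rules(swapped, toy["decs"])
    directional_pairs = {
        (r.function_class, r.phenotype_class)
        for r in swapped_rules if r.rule_kind != ABN
    }
    original_pattern_pairs = {
        (p.function_class, p.phenotype_class) for p in toy["patterns"]
    }
    assert directional_pairs == original_pattern_pairs


def test_serialization_is_byte_identical(toy):
    buf1, buf2 = io.StringIO(), io.StringIO()
    write_rules_tsv(toy["rules"], buf1)
    write_rules_tsv(
        build_correspondence_rules(list(reversed(toy["regs"])), toy["decs"]), buf2)
    assert buf1.getvalue() == buf2.getvalue()
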