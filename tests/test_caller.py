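"""Haplotype matching and the call-resolution priority ladder."""

import random

import pytest

from starcall.caller import (
    CallStatus,
    call_sample_gene,
    candidate_matches,
    compatible_matches,
    resolve_call,
)
from starcall.definitions import (
    AlleleDefinitionTable,
    FunctionClass,
    StarAlleleDef,
    VariantDef,
)
from starcall.genotypes import SampleHaplotypes

from conftest import hap, oracle_candidate_matches, random_hap, random_table


class TestCandidateMatches:
    def test_all_ref_matches_reference(self, cyp2c19_table):
        assert candidate_matches(hap(cyp2c19_table), cyp2c19_table) == {"*1"}

    def test_single_defining_variant(self, cyp2c19_table):
        h = hap(cyp2c19_table, alt_labels=["*2"])
        assert candidate_matches(h, cyp2c19_table) == {"*2"}

    def test_missing_does_not_satisfy_requirement(self, cyp2c19_table):
        h = hap(cyp2c19_table, missing=["10:96541616:G:A"])
        assert "*2" not in candidate_matches(h, cyp2c19_table)
        assert "*2" in compatible_matches(h, cyp2c19_table)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        table = random_table(rng)
        for _ in range(30):
            h = random_hap(rng, table)
            assert candidate_matches(h, table) == oracle_candidate_matches(h, table)


class TestPriorityLadder:
    def test_nonfunctional_overrides_normal(self):
        """A haplotype matching both a no-function and a normal allele
        resolves to the no-function allele in the first pass."""
        v1 = VariantDef("22", 100, "A", "G")
        v2 = VariantDef("22", 200, "C", "T")
        table = AlleleDefinitionTable(
            "G",
            [v1, v2],
            [
                StarAlleleDef("G", "*1", {}, FunctionClass.NORMAL),
                StarAlleleDef("G", "*2", {v1: "alt"}, FunctionClass.NO_FUNCTION),
                StarAlleleDef(
                    "G", "*3", {v1: "alt", v2: "alt"}, FunctionClass.NORMAL
                ),
            ],
        ).validate()
        call = resolve_call({v1: "alt", v2: "alt"}, table)
        assert call.status is CallStatus.SINGLE
        assert call.resolved_label == "*2"
        assert call.resolved_function is FunctionClass.NO_FUNCTION
        assert call.unexplained_variants == {v2}

    def test_decreased_overrides_normal(self):
        v1 = VariantDef("22", 100, "A", "G")
        v2 = VariantDef("22", 200, "C", "T")
        table = AlleleDefinitionTable(
            "G",
            [v1, v2],
            [
                StarAlleleDef("G", "*1", {}, FunctionClass.NORMAL),
                StarAlleleDef("G", "*2", {v1: "alt"}, FunctionClass.NORMAL),
                StarAlleleDef(
                    "G", "*3", {v1: "alt", v2: "alt"}, FunctionClass.DECREASED
                ),
            ],
        ).validate()
        call = resolve_call({v1: "alt", v2: "alt"}, table)
        assert call.status is CallStatus.SINGLE
        assert call.resolved_label == "*3"
        assert call.candidates == {"*2", "*3"}

    def test_composite_call(self, cyp4f2_table):
        """Both single-variant alleles on one chromosome -> *2+*3."""
        h = hap(cyp4f2_table, alt_labels=["*2", "*3"])
        call = resolve_call(h, cyp4f2_table)
        assert call.status is CallStatus.COMPOSITE
        assert call.resolved_label == "*2+*3"
        # most severe member function propagates
        assert call.resolved_function is FunctionClass.DECREASED
        assert call.unexplained_variants == frozenset()

    def test_ambiguous_overlapping_definitions(self, dpyd_table):
        """A *9 haplotype also satisfies the nested *5 definition."""
        h = hap(dpyd_table, alt_labels=["*9"])
        call = resolve_call(h, dpyd_table)
        assert call.status is CallStatus.AMBIGUOUS
        assert call.candidates == {"*5", "*9"}
        assert call.resolved_label is None

    def test_no_match(self, cyp4f2_table):
        """An alt state explained by no allele (here: *3's variant plus an
        unexplained combination) with no candidate yields no_match."""
        v_extra = VariantDef("19", 16012345, "G", "A")
        table = AlleleDefinitionTable(
            cyp4f2_table.gene,
            cyp4f2_table.variants + [v_extra],
            cyp4f2_table.alleles
            + [
                StarAlleleDef(
                    "CYP4F2",
                    "*4",
                    {cyp4f2_table.variants[0]: "alt", v_extra: "alt"},
                    FunctionClass.NORMAL,
                )
            ],
        ).validate()
        h = {table.variants[0]: "ref", table.variants[1]: "ref", v_extra: "alt"}
        call = resolve_call(h, table)
        assert call.status is CallStatus.NO_MATCH
        assert call.candidates == frozenset()
        assert call.unexplained_variants == {v_extra}

    def test_reference_with_missing_carries_disclaimer(self, cyp2c19_table):
        h = hap(cyp2c19_table, missing=["10:96541616:G:A"])
        call = resolve_call(h, cyp2c19_table)
        assert call.status is CallStatus.SINGLE
        assert call.resolved_label == "*1"
        assert call.wildtype_disclaimer

    def test_fully_typed_reference_no_disclaimer(self, cyp2c19_table):
        call = resolve_call(hap(cyp2c19_table), cyp2c19_table)
        assert not call.wildtype_disclaimer

    def test_nonfunctional_tie_break_largest_definition(self):
        v1 = VariantDef("22", 100, "A", "G")
        v2 = VariantDef("22", 200, "C", "T")
        table = AlleleDefinitionTable(
            "G",
            [v1, v2],
            [
                StarAlleleDef("G", "*1", {}, FunctionClass.NORMAL),
                StarAlleleDef("G", "*2", {v1: "alt"}, FunctionClass.NO_FUNCTION),
                StarAlleleDef(
                    "G", "*3", {v1: "alt", v2: "alt"}, FunctionClass.NO_FUNCTION
                ),
            ],
        ).validate()
        call = resolve_call({v1: "alt", v2: "alt"}, table)
        assert call.resolved_label == "*3"  # larger definition wins the tie

    def test_compatible_pass_flag(self, cyp2c19_table):
        """With compatible semantics, a missing defining variant still lets
        the no-function allele resolve in pass 1."""
        h = hap(cyp2c19_table, missing=["10:96541616:G:A"])
        strict = resolve_call(h, cyp2c19_table, nonfunctional_semantics="full")
        loose = resolve_call(h, cyp2c19_table, nonfunctional_semantics="compatible")
        assert strict.resolved_label == "*1"
        assert loose.resolved_label == "*2"


class TestInvariantsAndProperties:
    def test_statuses_partition_outcomes(self):
        rng = random.Random(123)
        for _ in range(200):
            table = random_table(rng, max_variants=6, max_alleles=8)
            call = resolve_call(random_hap(rng, table), table)
            if call.status in (CallStatus.SINGLE, CallStatus.COMPOSITE):
                assert call.resolved_label is not None
            elif call.status is CallStatus.AMBIGUOUS:
                assert len(call.candidates) >= 2 and call.resolved_label is None
            else:
                assert call.candidates == frozenset()
                assert len(call.unexplained_variants) >= 1

    def test_masking_only_shrinks_candidates(self):
        """Adding missingness never creates a non-reference match: the masked
        candidate set is a subset of the original plus the reference."""
        rng = random.Random(7)
        for _ in range(300):
            table = random_table(rng, max_variants=8, max_alleles=10)
            h = random_hap(rng, table)
            before = candidate_matches(h, table)
            masked = {
                v: ("missing" if rng.random() < 0.4 else s) for v, s in h.items()
            }
            after = candidate_matches(masked, table)
            assert after <= before | {table.reference_label}
            call = resolve_call(masked, table)
            if (
                call.status is CallStatus.SINGLE
                and call.resolved_label != table.reference_label
            ):
                assert call.resolved_label in compatible_matches(h, table)

    def test_determinism(self, dpyd_table):
        h = hap(dpyd_table, alt_labels=["*9"])
        calls = [resolve_call(dict(h), dpyd_table) for _ in range(5)]
        assert len({(c.status, c.resolved_label, tuple(sorted(c.candidates))) for c in calls}) == 1

    def test_call_sample_gene_independent_haplotypes(self, cyp2c19_table):
        samp = SampleHaplotypes(
            "S",
            hap(cyp2c19_table, alt_labels=["*2"]),
            hap(cyp2c19_table),
        )
        call_a, call_b = call_sample_gene(samp, cyp2c19_table)
        assert call_a.resolved_label == "*2"
        assert call_b.resolved_label == "*1"

    def test_composite_function_at_least_as_severe_as_members(self):
        rng = random.Random(99)
        from starcall.util import severity_rank

        found = 0
        for _ in range(2000):
            table = random_table(rng, max_variants=6, max_alleles=8)
            call = resolve_call(random_hap(rng, table), table)
            if call.status is CallStatus.COMPOSITE:
                found += 1
                members = call.resolved_label.split("+")
                for m in members:
                    assert severity_rank(call.resolved_function.value) <= severity_rank(
                        table.allele(m).function_class.value
                    )
        assert found > 0  # the sweep actually exercised composite calls
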