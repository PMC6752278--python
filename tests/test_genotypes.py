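"""VCF reading, the imputation-probability filter, source merging, projection."""

import itertools
import random

import pytest

from starcall.definitions import parse_definition_table
from starcall.errors import AmbiguityError, DataError
from starcall.genotypes import (
    ALT,
    GENOTYPED,
    IMPUTED,
    MISSING,
    REF,
    SiteGenotype,
    apply_probability_filter,
    build_sample_haplotypes,
    merge_sources,
    read_phased_vcf,
)
from starcall.simulate import GeneSimSpec, SimulationSpec, simulate_cohort, simulate_table


VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Imputed site">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">
##contig=<ID=10>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2\tNA3
10\t96541616\trs4244285\tG\tA\t.\tPASS\t.\tGT\t0|1\t./.\t1|1
10\t96600000\t.\tC\tT,G\t.\tPASS\tIMPUTED\tGT:GP\t0|1:0.01,0.98,0.01\t0|2:0.1,0.85,0.05\t0|0:0.02,0.96,0.02
10\t96612495\trs12248560\tC\tT\t.\tPASS\t.\tGT\t0/1\t0|0\t0/0
"""


@pytest.fixture
def vcf_path(tmp_path):
    path = tmp_path / "cohort.vcf"
    path.write_text(VCF_TEXT)
    return path


class TestReadPhasedVcf:
    def test_phased_het_maps_to_ref_alt(self, vcf_path):
        gts = read_phased_vcf(vcf_path)
        g = next(
            g for g in gts if g.sample == "NA1" and g.variant.pos == 96541616
        )
        assert (g.allele_a, g.allele_b) == (REF, ALT)
        assert g.origin == GENOTYPED
        assert g.phased

    def test_missing_genotype(self, vcf_path):
        gts = read_phased_vcf(vcf_path)
        g = next(
            g for g in gts if g.sample == "NA2" and g.variant.pos == 96541616
        )
        assert (g.allele_a, g.allele_b) == (MISSING, MISSING)

    def test_multiallelic_decomposition(self, vcf_path):
        gts = read_phased_vcf(vcf_path)
        at_site = [g for g in gts if g.variant.pos == 96600000]
        # 2 alt alleles x 3 samples
        assert len(at_site) == 6
        alts = {g.variant.alt for g in at_site}
        assert alts == {"T", "G"}
        na2_t = next(g for g in at_site if g.sample == "NA2" and g.variant.alt == "T")
        na2_g = next(g for g in at_site if g.sample == "NA2" and g.variant.alt == "G")
        # NA2 is 0|2: the G sub-record sees the alt, the T sub-record does not
        assert (na2_t.allele_a, na2_t.allele_b) == (REF, REF)
        assert (na2_g.allele_a, na2_g.allele_b) == (REF, ALT)

    def test_imputed_flag_and_gp(self, vcf_path):
        gts = read_phased_vcf(vcf_path)
        g = next(g for g in gts if g.sample == "NA1" and g.variant.pos == 96600000)
        assert g.origin == IMPUTED
        assert g.gp == pytest.approx(0.98)
        direct = next(
            g for g in gts if g.sample == "NA1" and g.variant.pos == 96541616
        )
        assert direct.origin == GENOTYPED

    def test_region_filter(self, vcf_path):
        gts = read_phased_vcf(vcf_path, region=("10", 96541616, 96541616))
        assert {g.variant.pos for g in gts} == {96541616}

    def test_generator_round_trip_matches_truth(self, tmp_path):
        """States read back from a generated VCF equal the generator's truth."""
        table = simulate_table("CYP2C19", 3, seed=11)
        spec = SimulationSpec(
            seed=3,
            n_samples=3,
            genes={"CYP2C19": GeneSimSpec({"*1": 0.4, "*2": 0.3, "*3": 0.2, "*4": 0.1})},
            imputed_fraction=0.0,
        )
        cohort = simulate_cohort(spec, {"CYP2C19": table})
        paths = cohort.write(tmp_path)
        gts = read_phased_vcf(paths["vcf"])
        truth = {t.sample: t for t in cohort.truth}
        for g in gts:
            t = truth[g.sample]
            for hap_label, state in ((t.snv_labels[0], g.allele_a), (t.snv_labels[1], g.allele_b)):
                expected = (
                    ALT
                    if g.variant in table.allele(hap_label).alt_variants
                    else REF
                )
                assert state == expected


class TestProbabilityFilter:
    @pytest.mark.parametrize(
        "origin,gp,expect_missing",
        [
            (IMPUTED, 0.85, True),
            (IMPUTED, 0.8999, True),
            (IMPUTED, 0.90, False),  # boundary kept: "lower than" is strict
            (IMPUTED, 0.95, False),
            (GENOTYPED, 0.10, False),
            (GENOTYPED, None, False),
        ],
    )
    def test_filter_semantics(self, cyp2c19_table, origin, gp, expect_missing):
        v = cyp2c19_table.variants[0]
        g = SiteGenotype("S", v, REF, ALT, True, origin, gp)
        (out,) = apply_probability_filter([g])
        if expect_missing:
            assert (out.allele_a, out.allele_b) == (MISSING, MISSING)
        else:
            assert (out.allele_a, out.allele_b) == (REF, ALT)

    def test_imputed_without_gp_rejected(self, cyp2c19_table):
        g = SiteGenotype("S", cyp2c19_table.variants[0], REF, REF, True, IMPUTED, None)
        with pytest.raises(DataError, match="without GP"):
            apply_probability_filter([g])

    def test_threshold_validation(self, cyp2c19_table):
        with pytest.raises(ValueError):
            apply_probability_filter([], threshold=0.0)


class TestMergeSources:
    def _gt(self, table, sample, pos_idx, states, origin=GENOTYPED, gp=None):
        v = table.variants[pos_idx]
        return SiteGenotype(sample, v, states[0], states[1], True, origin, gp)

    def test_genotyped_wins_overlap(self, cyp2c19_table):
        direct = [self._gt(cyp2c19_table, "S", 0, (REF, ALT))]
        imputed = [self._gt(cyp2c19_table, "S", 0, (REF, REF), IMPUTED, 0.99)]
        (out,) = merge_sources(direct, imputed)
        assert (out.allele_a, out.allele_b) == (REF, ALT)
        assert out.origin == GENOTYPED

    def test_imputed_only_key_retained(self, cyp2c19_table):
        imputed = [self._gt(cyp2c19_table, "S", 1, (ALT, ALT), IMPUTED, 0.97)]
        (out,) = merge_sources([], imputed)
        assert out.origin == IMPUTED

    def test_conflicting_duplicates_rejected(self, cyp2c19_table):
        a = self._gt(cyp2c19_table, "S", 0, (REF, ALT))
        b = self._gt(cyp2c19_table, "S", 0, (ALT, ALT))
        with pytest.raises(DataError, match="conflicting duplicate"):
            merge_sources([a, b], [])

    @pytest.mark.parametrize("seed", range(10))
    def test_union_key_algebra(self, cyp2c19_table, seed):
        """Merged key set = union; overlaps all resolve to the direct source."""
        rng = random.Random(seed)
        samples = [f"S{i}" for i in range(6)]
        keys = list(itertools.product(samples, range(len(cyp2c19_table.variants))))
        direct_keys = set(rng.sample(keys, rng.randint(0, len(keys))))
        imputed_keys = set(rng.sample(keys, rng.randint(0, len(keys))))
        direct = [self._gt(cyp2c19_table, s, i, (REF, ALT)) for s, i in direct_keys]
        imputed = [
            self._gt(cyp2c19_table, s, i, (ALT, ALT), IMPUTED, 0.99)
            for s, i in imputed_keys
        ]
        out = merge_sources(direct, imputed)
        out_keys = {(g.sample, cyp2c19_table.variants.index(g.variant)) for g in out}
        assert out_keys == direct_keys | imputed_keys
        n_direct = sum(1 for g in out if g.origin == GENOTYPED)
        assert n_direct == len(direct_keys)

    def test_filter_and_merge_commute(self, cyp2c19_table):
        direct = [self._gt(cyp2c19_table, "S", 0, (REF, ALT), GENOTYPED, 0.5)]
        imputed = [
            self._gt(cyp2c19_table, "S", 0, (ALT, ALT), IMPUTED, 0.7),
            self._gt(cyp2c19_table, "S", 1, (REF, ALT), IMPUTED, 0.7),
            self._gt(cyp2c19_table, "S", 1, (ALT, ALT), IMPUTED, 0.99),
        ]
        del imputed[2]  # keep one record per key within the source
        a = apply_probability_filter(merge_sources(direct, imputed))
        b = merge_sources(
            apply_probability_filter(direct), apply_probability_filter(imputed)
        )
        assert {
            (g.key, g.allele_a, g.allele_b) for g in a
        } == {(g.key, g.allele_a, g.allele_b) for g in b}


class TestBuildHaplotypes:
    def test_projection_fills_missing(self, cyp2c19_table):
        v0 = cyp2c19_table.variants[0]
        gts = [SiteGenotype("S", v0, REF, ALT)]
        hap = build_sample_haplotypes(gts, cyp2c19_table, "S")
        v1 = cyp2c19_table.variants[1]
        assert hap.hap_a[v0] == REF and hap.hap_b[v0] == ALT
        assert hap.hap_a[v1] == MISSING and hap.hap_b[v1] == MISSING
        assert len(hap.hap_a) == len(cyp2c19_table.variants)

    def test_single_unphased_het_tolerated(self, cyp2c19_table):
        v0, v1 = cyp2c19_table.variants
        gts = [
            SiteGenotype("S", v0, REF, ALT, phased=False),
            SiteGenotype("S", v1, REF, REF, phased=False),
        ]
        hap = build_sample_haplotypes(gts, cyp2c19_table, "S")
        assert {hap.hap_a[v0], hap.hap_b[v0]} == {REF, ALT}

    def test_two_unphased_hets_rejected(self, cyp2c19_table):
        v0, v1 = cyp2c19_table.variants
        gts = [
            SiteGenotype("S", v0, REF, ALT, phased=False),
            SiteGenotype("S", v1, ALT, REF, phased=True),
        ]
        with pytest.raises(AmbiguityError):
            build_sample_haplotypes(gts, cyp2c19_table, "S")

    def test_no_missing_to_called_conversion(self, cyp2c19_table):
        """Filtering, merging and projection never invent a call."""
        v0 = cyp2c19_table.variants[0]
        g = SiteGenotype("S", v0, MISSING, MISSING, True, IMPUTED, 0.99)
        merged = merge_sources([], apply_probability_filter([g]))
        hap = build_sample_haplotypes(merged, cyp2c19_table, "S")
        assert hap.hap_a[v0] == MISSING and hap.hap_b[v0] == MISSING
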