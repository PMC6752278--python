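"""Shared fixtures: small hand-built definition tables and random-table helpers."""

import random

import pytest

from starcall.definitions import (
    AlleleDefinitionTable,
    FunctionClass,
    StarAlleleDef,
    Structural,
    VariantDef,
    parse_definition_table,
)

# CYP2C19-style: *2 is a no-function allele detectable from the single
# rs4244285 variant after curation; *17 is an increased-function promoter allele.
CYP2C19_TSV = """\
gene\tlabel\tfunction\tstructural\t10:96541616:G:A:rs4244285\t10:96612495:C:T:rs12248560
CYP2C19\t*1\tnormal\tnone\t\t
CYP2C19\t*2\tno_function\tnone\talt\t
CYP2C19\t*17\tincreased\tnone\t\talt
"""

# CYP4F2-style: two single-variant alleles of non-no-function class that can
# co-occur on one chromosome as the composite *2+*3.
CYP4F2_TSV = """\
gene\tlabel\tfunction\tstructural\t19:15990431:C:T:rs2108622\t19:16008388:A:C:rs3093105
CYP4F2\t*1\tnormal\tnone\t\t
CYP4F2\t*2\tnormal\tnone\t\talt
CYP4F2\t*3\tdecreased\tnone\talt\t
"""

# DPYD-style overlap: *5 is a sub-definition of *9, so a *9 haplotype matches
# both -> ambiguous (same normal function, harmless downstream).
DPYD_TSV = """\
gene\tlabel\tfunction\tstructural\t1:97515839:T:C:rs1801159\t1:97547947:T:C:rs1801160
DPYD\t*1\tnormal\tnone\t\t
DPYD\t*5\tnormal\tnone\talt\t
DPYD\t*9\tnormal\tnone\talt\talt
"""


@pytest.fixture
def cyp2c19_table():
    return parse_definition_table(CYP2C19_TSV)


@pytest.fixture
def cyp4f2_table():
    return parse_definition_table(CYP4F2_TSV)


@pytest.fixture
def dpyd_table():
    return parse_definition_table(DPYD_TSV)


def hap(table, alt_labels=(), missing=(), ref_extra=()):
    """Build a haplotype state map: alt at the union of the named alleles'
    alt-variants, missing at ``missing`` variant keys, ref elsewhere."""
    alt = set()
    for label in alt_labels:
        alt |= table.allele(label).alt_variants
    states = {}
    for v in table.variants:
        if v.key in set(missing):
            states[v] = "missing"
        elif v in alt:
            states[v] = "alt"
        else:
            states[v] = "ref"
    return states


def random_table(rng: random.Random, max_variants=12, max_alleles=20, gene="G"):
    """A random, possibly overlapping/nested definition table (validated)."""
    n_var = rng.randint(1, max_variants)
    variants = []
    pos = 100
    for _ in range(n_var):
        pos += rng.randint(1, 50)
        ref, alt = rng.sample("ACGT", 2)
        variants.append(VariantDef("7", pos, ref, alt))
    alleles = [StarAlleleDef(gene, "*1", {}, FunctionClass.NORMAL)]
    seen = {frozenset()}
    n_alleles = rng.randint(1, max_alleles - 1)
    label_n = 2
    for _ in range(n_alleles):
        k = rng.randint(1, n_var)
        chosen = rng.sample(variants, k)
        required = {v: rng.choice(["ref", "alt"]) for v in chosen}
        key = frozenset(required.items())
        if key in seen:
            continue
        seen.add(key)
        fclass = rng.choice(list(FunctionClass))
        alleles.append(StarAlleleDef(gene, f"*{label_n}", required, fclass))
        label_n += 1
    return AlleleDefinitionTable(gene, variants, alleles, "*1").validate()


def random_hap(rng: random.Random, table):
    return {v: rng.choice(["ref", "alt", "missing"]) for v in table.variants}


def oracle_candidate_matches(hap_states, table):
    """Independent brute-force matcher: an allele matches iff its required
    (variant, state) pairs are a subset of the observed pairs; the reference
    matches iff no table variant is observed in the alternate state."""
    observed = {(v, s) for v, s in hap_states.items() if s != "missing"}
    out = set()
    for a in table.alleles:
        if a.structural is not Structural.NONE:
            continue
        if a.label == table.reference_label:
            if not any((v, "alt") in observed for v in table.variants):
                out.add(a.label)
        elif set(a.required_states.items()) <= observed:
            out.add(a.label)
    return out
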