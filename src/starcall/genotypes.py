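"""Phased VCF genotype handling.

Reads per-sample phased genotypes, applies the imputation-quality filter
(imputed calls with posterior probability below the threshold become
missing), merges directly genotyped and imputed sources with the direct
call taking precedence, and projects each sample onto the variants of a
definition table as a pair of haplotype state vectors.

States are the strings ``"ref"``, ``"alt"`` and ``"missing"``; they always
refer to the ref/alt of the variant's own record. Coordinates are 1-based
GRCh37 without a ``chr`` prefix (a contig-alias map can normalise inputs).

Imputed origin is read from a per-record INFO flag (default ``IMPUTED``) or,
when configured, a per-sample FORMAT string tag with values
``genotyped``/``imputed``. The probability attached to an imputed genotype is
the posterior of the called genotype: the maximum of the GP vector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .definitions import AlleleDefinitionTable, VariantDef
from .errors import AmbiguityError, DataError, FormatError

REF = "ref"
ALT = "alt"
MISSING = "missing"

GENOTYPED = "genotyped"
IMPUTED = "imputed"


@dataclass(frozen=True)
class SiteGenotype:
    """One sample's phased genotype at one biallelic site."""

    sample: str
    variant: VariantDef
    allele_a: str  # first GT field
    allele_b: str
    phased: bool = True
    origin: str = GENOTYPED
    gp: Optional[float] = None

    @property
    def key(self) -> tuple:
        return (self.sample, self.variant)

    @property
    def is_het(self) -> bool:
        return (
            self.allele_a != self.allele_b
            and MISSING not in (self.allele_a, self.allele_b)
        )

    def as_missing(self) -> "SiteGenotype":
        return replace(self, allele_a=MISSING, allele_b=MISSING)


@dataclass(frozen=True)
class SampleHaplotypes:
    """A sample's pair of phased state vectors over a table's variants."""

    sample: str
    hap_a: Mapping[VariantDef, str]
    hap_b: Mapping[VariantDef, str]


def _normalize_contig(contig: str, aliases: Optional[Mapping[str, str]]) -> str:
    if aliases and contig in aliases:
        return aliases[contig]
    return contig[3:] if contig.startswith("chr") else contig


def _allele_state(gt_index, alt_index: int) -> str:
    if gt_index is None:
        return MISSING
    if gt_index == 0:
        return REF
    # decomposition of multi-allelic records: any other alternate allele is
    # "not this alt", i.e. reference-like for this biallelic sub-record
    return ALT if gt_index == alt_index else REF


def read_phased_vcf(
    path,
    region: Optional[tuple] = None,
    samples: Optional[Sequence[str]] = None,
    imputed_info_flag: str = "IMPUTED",
    origin_format_tag: Optional[str] = None,
    gp_tag: str = "GP",
    contig_aliases: Optional[Mapping[str, str]] = None,
) -> list:
    """Read a VCF into a flat list of :class:`SiteGenotype`.

    ``region`` is an optional ``(contig, start, end)`` 1-based inclusive
    interval. Multi-allelic records are decomposed into one biallelic site
    per alternate allele. ``./.`` genotypes become (missing, missing).
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        wanted = list(samples) if samples is not None else list(vcf.header.samples)
        for rec in vcf:
            contig = _normalize_contig(rec.contig, contig_aliases)
            if region is not None:
                rcontig, rstart, rend = region
                if contig != _normalize_contig(rcontig, contig_aliases):
                    continue
                if not (rstart <= rec.pos <= rend):
                    continue
            if rec.alts is None:
                continue
            rec_origin = (
                IMPUTED
                if imputed_info_flag and rec.info.get(imputed_info_flag, False)
                else GENOTYPED
            )
            for alt_i, alt in enumerate(rec.alts, start=1):
                try:
                    variant = VariantDef(
                        contig, rec.pos, rec.ref, str(alt), rec.id
                    )
                except FormatError:
                    continue  # symbolic / degenerate alt
                for sample in wanted:
                    call = rec.samples[sample]
                    gt = call.get("GT")
                    if gt is None or len(gt) == 0:
                        states, phased = (MISSING, MISSING), True
                    elif len(gt) == 1:  # haploid record
                        s = _allele_state(gt[0], alt_i)
                        states, phased = (s, s), True
                    elif len(gt) == 2:
                        states = (
                            _allele_state(gt[0], alt_i),
                            _allele_state(gt[1], alt_i),
                        )
                        phased = bool(call.phased)
                    else:
                        raise FormatError(
                            f"malformed GT (ploidy {len(gt)}) at "
                            f"{contig}:{rec.pos} sample {sample}"
                        )
                    origin = rec_origin
                    if origin_format_tag is not None:
                        tag = call.get(origin_format_tag)
                        if tag is not None:
                            tag = str(tag).lower()
                            origin = IMPUTED if tag.startswith("i") else GENOTYPED
                    gp_val = call.get(gp_tag)
                    gp = None
                    if gp_val is not None:
                        try:
                            gp = max(float(g) for g in gp_val)
                        except TypeError:
                            gp = float(gp_val)
                    out.append(
                        SiteGenotype(
                            sample, variant, states[0], states[1], phased, origin, gp
                        )
                    )
    return out


def apply_probability_filter(
    genotypes: Iterable[SiteGenotype], threshold: float = 0.90
) -> list:
    """Blank out imputed genotypes whose posterior is below ``threshold``.

    The comparison is strict (a posterior exactly at the threshold is kept)
    and never touches directly genotyped records, whatever their GP.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out = []
    for g in genotypes:
        if g.origin == IMPUTED:
            if g.gp is None:
                raise DataError(
                    f"imputed genotype without GP at {g.variant.key} "
                    f"sample {g.sample}"
                )
            if g.gp < threshold:
                g = g.as_missing()
        out.append(g)
    return out


def _index_by_key(genotypes: Iterable[SiteGenotype], source: str) -> dict:
    index = {}
    for g in genotypes:
        prev = index.get(g.key)
        if prev is not None and (prev.allele_a, prev.allele_b) != (
            g.allele_a,
            g.allele_b,
        ):
            raise DataError(
                f"conflicting duplicate {source} genotypes at {g.variant.key} "
                f"sample {g.sample}"
            )
        index[g.key] = g
    return index


def merge_sources(
    genotyped: Iterable[SiteGenotype], imputed: Iterable[SiteGenotype]
) -> list:
    """Union of two genotype sources; the direct genotype call wins overlaps."""
    direct = _index_by_key(genotyped, GENOTYPED)
    imp = _index_by_key(imputed, IMPUTED)
    merged = dict(imp)
    merged.update(direct)
    return list(merged.values())


def build_sample_haplotypes(
    genotypes: Iterable[SiteGenotype],
    table: AlleleDefinitionTable,
    sample: str,
) -> SampleHaplotypes:
    """Project one sample's genotypes onto a definition table's variants.

    Table variants without a record are missing on both haplotypes. An
    unphased heterozygote is tolerated only if it is the sample's sole
    heterozygous site among the table variants (phase is then irrelevant for
    haplotype content); otherwise haplotype assignment would be ambiguous
    and an :class:`AmbiguityError` is raised.
    """
    table_variants = set(table.variants)
    by_variant = {}
    for g in genotypes:
        if g.sample == sample and g.variant in table_variants:
            by_variant[g.variant] = g
    unphased_hets = [
        g for g in by_variant.values() if g.is_het and not g.phased
    ]
    n_het = sum(1 for g in by_variant.values() if g.is_het)
    if unphased_hets and n_het > 1:
        sites = ", ".join(g.variant.key for g in unphased_hets)
        raise AmbiguityError(
            f"sample {sample}: unphased heterozygote(s) at {sites} with "
            f"{n_het} heterozygous table sites — haplotypes ambiguous"
        )
    hap_a, hap_b = {}, {}
    for v in table.variants:
        g = by_variant.get(v)
        if g is None:
            hap_a[v] = MISSING
            hap_b[v] = MISSING
        else:
            hap_a[v] = g.allele_a
            hap_b[v] = g.allele_b
    return SampleHaplotypes(sample, hap_a, hap_b)


def group_by_sample(genotypes: Iterable[SiteGenotype]) -> dict:
    """Bucket genotypes by sample id (one pass; for whole-cohort pipelines)."""
    grouped: dict = {}
    for g in genotypes:
        grouped.setdefault(g.sample, []).append(g)
    return grouped
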