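"""End-to-end cohort calling: VCF → haplotype calls → diplotypes → phenotypes.

Thin orchestration over the per-stage modules; exists so the CLI and the
synthetic-cohort round-trip tests share one code path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, TextIO

from .caller import HaplotypeCall, call_sample_gene
from .cnv import CnvRecord, integrate_cnv
from .definitions import AlleleDefinitionTable, PlatformProfile
from .genotypes import (
    apply_probability_filter,
    build_sample_haplotypes,
    group_by_sample,
    read_phased_vcf,
)
from .phenotype import (
    Diplotype,
    DiplotypePhenotypeMap,
    PhenotypeCall,
    PhenotypeStatus,
    enumerate_diplotypes,
    flag_high_risk,
    resolve_phenotype,
)
from .util import format_diplotype


@dataclass(frozen=True)
class SampleGeneResult:
    sample: str
    gene: str
    calls: tuple  # (HaplotypeCall, HaplotypeCall)
    final_labels: Optional[tuple]  # post-CNV labels when both resolved
    phenotype: Optional[PhenotypeCall]
    high_risk: Optional[bool]
    cnv_event: str = "normal"

    @property
    def diplotype(self) -> Optional[str]:
        if self.final_labels is None:
            return None
        return format_diplotype(*self.final_labels)


def call_cohort(
    vcf_path,
    tables: Mapping[str, AlleleDefinitionTable],
    phenotype_maps: Optional[Mapping[str, DiplotypePhenotypeMap]] = None,
    cnv_records: Optional[Iterable[CnvRecord]] = None,
    platform: Optional[PlatformProfile] = None,
    gp_threshold: float = 0.90,
    imputed_vcf_path=None,
    normal_labels: Optional[Mapping[str, set]] = None,
    samples: Optional[Sequence[str]] = None,
    nonfunctional_semantics: str = "full",
) -> list:
    """Run the full calling pipeline over a cohort VCF.

    When ``imputed_vcf_path`` is given, the two files are merged with the
    directly genotyped calls taking precedence; otherwise imputed origin is
    read from the main VCF's annotations. Returns one
    :class:`SampleGeneResult` per sample × gene.
    """
    from .genotypes import merge_sources

    genotypes = read_phased_vcf(vcf_path, samples=samples)
    if imputed_vcf_path is not None:
        imputed = read_phased_vcf(imputed_vcf_path, samples=samples)
        genotypes = merge_sources(genotypes, imputed)
    genotypes = apply_probability_filter(genotypes, gp_threshold)

    cnv_index: Dict[tuple, CnvRecord] = {}
    for r in cnv_records or ():
        cnv_index[(r.sample, r.gene)] = r

    grouped = group_by_sample(genotypes)
    if samples is None:
        sample_list = sorted(grouped)
    else:
        sample_list = list(samples)

    results = []
    for gene in sorted(tables):
        table = tables[gene]
        pmap = phenotype_maps.get(gene) if phenotype_maps else None
        for sample in sample_list:
            hap = build_sample_haplotypes(grouped.get(sample, ()), table, sample)
            calls = call_sample_gene(hap, table, nonfunctional_semantics)
            cnv = cnv_index.get((sample, gene))
            event = cnv.event if cnv is not None else "normal"
            final = None
            both_resolved = all(c.resolved_label is not None for c in calls)
            if both_resolved:
                if cnv is not None and cnv.event != "normal":
                    adj = integrate_cnv(calls, cnv, profile=platform)
                    final = adj.labels
                else:
                    final = tuple(c.resolved_label for c in calls)
            pheno = None
            risk = None
            if pmap is not None:
                if final is not None:
                    pheno = resolve_phenotype(
                        {Diplotype(gene, final)}, pmap
                    )
                else:
                    diplotypes = enumerate_diplotypes(calls)
                    if diplotypes:
                        pheno = resolve_phenotype(diplotypes, pmap)
                    else:
                        pheno = PhenotypeCall(
                            gene,
                            PhenotypeStatus.INDETERMINATE,
                            reason="no-match haplotype",
                        )
                risk = flag_high_risk(
                    pheno, normal_labels or {}
                ) if normal_labels is not None else None
            results.append(
                SampleGeneResult(sample, gene, calls, final, pheno, risk, event)
            )
    return results


def write_calls_tsv(results: Iterable[SampleGeneResult], stream: Optional[TextIO] = None) -> str:
    """Per-haplotype call table (one row per sample × gene × haplotype)."""
    buf = stream or io.StringIO()
    buf.write(
        "sample\tgene\thaplotype\tstatus\tresolved_label\tcandidates\t"
        "function\tunexplained_variants\twildtype_disclaimer\n"
    )
    for r in results:
        for hap_name, call in zip(("A", "B"), r.calls):
            buf.write(
                "\t".join(
                    [
                        r.sample,
                        r.gene,
                        hap_name,
                        call.status.value,
                        call.resolved_label or "",
                        ",".join(sorted(call.candidates)),
                        call.resolved_function.value
                        if call.resolved_function
                        else "",
                        ",".join(sorted(v.key for v in call.unexplained_variants)),
                        "1" if call.wildtype_disclaimer else "0",
                    ]
                )
                + "\n"
            )
    return buf.getvalue() if stream is None else ""


def write_phenotypes_tsv(results: Iterable[SampleGeneResult], stream: Optional[TextIO] = None) -> str:
    buf = stream or io.StringIO()
    buf.write("sample\tgene\tdiplotype\tphenotype\tstatus\thigh_risk\n")
    for r in results:
        pheno = r.phenotype
        buf.write(
            "\t".join(
                [
                    r.sample,
                    r.gene,
                    r.diplotype or "",
                    (pheno.phenotype or "") if pheno else "",
                    pheno.status.value if pheno else "",
                    {True: "1", False: "0", None: ""}[r.high_risk],
                ]
            )
            + "\n"
        )
    return buf.getvalue() if stream is None else ""
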