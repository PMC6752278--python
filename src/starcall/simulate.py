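"""Synthetic pharmacogenetic cohorts with ground truth.

Emulates the input structure of a biobank star-allele screen so every
pipeline stage is testable without restricted data: per-gene allele
definition tables, a phased multi-sample VCF (with platform masking,
imputed-site annotation and per-genotype posterior probabilities),
whole-gene CNV calls for a CYP2D6-like gene, diplotype→phenotype mapping
tables, and a truth sidecar recording each sample's haplotype labels,
diplotype and phenotype.

Model assumptions (documented limitations): haplotypes are drawn
independently per chromosome from the allele-frequency vector
(Hardy–Weinberg, no LD beyond the allele definitions themselves); every
non-reference allele owns a disjoint set of defining variants, so truth
labels are identifiable from complete genotypes; imputed-genotype posteriors
follow a two-component mixture with a small mass below the 0.90 filter
threshold to exercise the quality filter.

Identical specs (same seed) produce byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .definitions import (
    AlleleDefinitionTable,
    FunctionClass,
    PlatformProfile,
    StarAlleleDef,
    Structural,
    VariantDef,
)
from .errors import SimulationSpecError
from .phenotype import DiplotypePhenotypeMap
from .util import most_severe, severity_rank, sort_labels

# Metabolizer vocabulary used by generated mapping tables
POOR = "Poor metabolizer"
INTERMEDIATE = "Intermediate metabolizer"
NORMAL = "Normal metabolizer"
RAPID = "Rapid metabolizer"
ULTRARAPID = "Ultrarapid metabolizer"
VOCABULARY = frozenset({POOR, INTERMEDIATE, NORMAL, RAPID, ULTRARAPID})

NORMAL_LABELS = frozenset({NORMAL})

_BASES = ("A", "C", "G", "T")

_DEFAULT_FUNCTION_PATTERN = (
    FunctionClass.NO_FUNCTION,
    FunctionClass.DECREASED,
    FunctionClass.NORMAL,
    FunctionClass.INCREASED,
)


def simulate_table(
    gene: str,
    n_alleles: int = 4,
    seed: int = 0,
    contig: str = "10",
    variants_per_allele: Sequence[int] = (1, 3),
    function_mix: Optional[Sequence[FunctionClass]] = None,
    structural: bool = False,
) -> AlleleDefinitionTable:
    """Generate a valid definition table with ``n_alleles`` non-reference alleles.

    Each non-reference allele receives its own disjoint set of defining
    variants (1 up to ``variants_per_allele[1]`` of them; the second allele is
    forced multi-variant when the cap allows, and the default function mix
    includes a no-function allele). ``structural=True`` adds a *5 deletion row
    and an ``xN`` duplication row per the CYP2D6 convention.
    """
    if n_alleles < 1:
        raise SimulationSpecError("need at least one non-reference allele")
    lo, hi = variants_per_allele
    if lo < 1 or hi < lo:
        raise SimulationSpecError(f"bad variants_per_allele range ({lo}, {hi})")
    if function_mix is not None and len(function_mix) != n_alleles:
        raise SimulationSpecError(
            f"function_mix length {len(function_mix)} != n_alleles {n_alleles}"
        )
    rng = np.random.default_rng(seed)
    if function_mix is None:
        function_mix = [
            _DEFAULT_FUNCTION_PATTERN[i % len(_DEFAULT_FUNCTION_PATTERN)]
            for i in range(n_alleles)
        ]
    counts = [int(rng.integers(lo, hi + 1)) for _ in range(n_alleles)]
    if hi > 1 and all(c == 1 for c in counts):
        counts[min(1, n_alleles - 1)] = 2  # guarantee one multi-variant allele
    positions = rng.choice(
        np.arange(1_000_000, 2_000_000), size=sum(counts), replace=False
    )
    positions = np.sort(positions)
    variants = []
    for pos in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(
            VariantDef(contig, int(pos), _BASES[ref], _BASES[alt], f"rs{int(pos)}")
        )
    order = list(rng.permutation(len(variants)))
    alleles = [StarAlleleDef(gene, "*1", {}, FunctionClass.NORMAL)]
    # skip *5 so the deletion allele can use its conventional name
    numbers = [n for n in range(2, 2 + n_alleles + 1) if n != 5][:n_alleles]
    cursor = 0
    for num, count, fclass in zip(numbers, counts, function_mix):
        mine = [variants[order[cursor + j]] for j in range(count)]
        cursor += count
        alleles.append(
            StarAlleleDef(gene, f"*{num}", {v: "alt" for v in mine}, fclass)
        )
    if structural:
        alleles.append(
            StarAlleleDef(gene, "*5", {}, FunctionClass.NO_FUNCTION, Structural.DELETION)
        )
        base = alleles[1]
        alleles.append(
            StarAlleleDef(
                gene,
                base.label + "xN",
                dict(base.required_states),
                base.function_class,
                Structural.DUPLICATION,
            )
        )
    table = AlleleDefinitionTable(gene, variants, alleles, "*1")
    return table.validate()


# ---------------------------------------------------------------------------
# Phenotype rules shared by the generator's truth and the generated map


def label_function(label: str, table: AlleleDefinitionTable, deletion_label: str = "*5") -> str:
    """Function class implied by a (possibly composite/xN/deletion) label."""
    if "+" in label:
        return most_severe(
            label_function(m, table, deletion_label) for m in label.split("+")
        )
    if label == deletion_label:
        return FunctionClass.NO_FUNCTION.value
    dup = label.endswith("xN")
    base = label[:-2] if dup else label
    fn = table.allele(base).function_class.value
    if dup and fn == "normal":
        return "increased"  # an extra functional copy raises activity
    return fn


def diplotype_phenotype(fn_a: str, fn_b: str) -> str:
    """Metabolizer phenotype from the pair of allele function classes."""
    fns = (fn_a, fn_b)
    if fns == ("no_function", "no_function"):
        return POOR
    if "no_function" in fns or "decreased" in fns:
        return INTERMEDIATE
    if fns == ("increased", "increased"):
        return ULTRARAPID
    if "increased" in fns:
        return RAPID
    return NORMAL


def build_phenotype_map(
    table: AlleleDefinitionTable,
    deletion_label: str = "*5",
    include_xn: bool = True,
    include_composites: bool = True,
) -> DiplotypePhenotypeMap:
    """Complete mapping table over the table's labels plus CNV and composite
    labels, derived from allele function classes. Pairs involving an
    unknown-function allele are left out (they resolve as indeterminate)."""
    base = [a.label for a in table.non_structural_alleles()]
    universe = list(base)
    if include_xn:
        universe += [l + "xN" for l in base]
    if include_composites:
        non_ref = [l for l in base if l != table.reference_label]
        for i in range(len(non_ref)):
            for j in range(i + 1, len(non_ref)):
                a, b = table.allele(non_ref[i]), table.allele(non_ref[j])
                if not (a.alt_variants & b.alt_variants):
                    universe.append("+".join(sort_labels([a.label, b.label])))
    universe.append(deletion_label)
    pmap = DiplotypePhenotypeMap(table.gene, {}, VOCABULARY)
    for i, la in enumerate(universe):
        for lb in universe[i:]:
            fa = label_function(la, table, deletion_label)
            fb = label_function(lb, table, deletion_label)
            if "unknown" in (fa, fb):
                continue
            pmap.add(la, lb, diplotype_phenotype(fa, fb))
    return pmap


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class GeneSimSpec:
    """Per-gene simulation parameters.

    ``allele_freqs`` covers the non-structural labels of the gene's table and
    must sum to 1; composite events (two non-reference alleles on one
    chromosome, CYP4F2-style) and CNV events (CYP2D6-style) are drawn on top.
    """

    allele_freqs: Dict[str, float]
    composite_rate: float = 0.0
    deletion_rate: float = 0.0
    duplication_rate: float = 0.0

    def validate(self, gene: str) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationSpecError(f"{gene}: allele frequencies sum to {total}")
        for name, rate in (
            ("composite_rate", self.composite_rate),
            ("deletion_rate", self.deletion_rate),
            ("duplication_rate", self.duplication_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise SimulationSpecError(f"{gene}: {name}={rate} outside [0,1]")
        if self.deletion_rate + self.duplication_rate > 1.0:
            raise SimulationSpecError(f"{gene}: CNV rates exceed 1")


@dataclass
class SimulationSpec:
    seed: int
    n_samples: int
    genes: Dict[str, GeneSimSpec]
    platform: PlatformProfile = field(default_factory=lambda: PlatformProfile("GS"))
    missingness: float = 0.0
    imputed_fraction: float = 0.5
    gp_low_rate: float = 0.02

    def validate(self) -> "SimulationSpec":
        if self.n_samples < 1:
            raise SimulationSpecError("n_samples must be >= 1")
        for rate, name in (
            (self.missingness, "missingness"),
            (self.imputed_fraction, "imputed_fraction"),
            (self.gp_low_rate, "gp_low_rate"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise SimulationSpecError(f"{name}={rate} outside [0,1]")
        for gene, gs in self.genes.items():
            gs.validate(gene)
        return self


@dataclass(frozen=True)
class TruthRecord:
    sample: str
    gene: str
    snv_labels: tuple  # SNV-level labels per physical haplotype
    cnv_event: str
    final_labels: tuple  # after CNV assignment
    phenotype: str


@dataclass
class SimulatedCohort:
    spec: SimulationSpec
    tables: Dict[str, AlleleDefinitionTable]
    phenotype_maps: Dict[str, DiplotypePhenotypeMap]
    truth: list  # list[TruthRecord]
    vcf_text: str
    cnv_records: list  # (sample, gene, event) rows as cnv.CnvRecord

    def write(self, out_dir) -> dict:
        from .cnv import write_cnv_table

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "tables").mkdir(exist_ok=True)
        paths = {"vcf": out_dir / "cohort.vcf", "cnv": out_dir / "cnv.tsv",
                 "truth": out_dir / "truth.tsv", "map": out_dir / "phenotype_map.tsv"}
        paths["vcf"].write_text(self.vcf_text)
        paths["cnv"].write_text(write_cnv_table(self.cnv_records))
        buf = io.StringIO()
        buf.write(
            "sample\tgene\tsnv_a\tsnv_b\tcnv_event\tfinal_a\tfinal_b\tphenotype\n"
        )
        for t in self.truth:
            buf.write(
                f"{t.sample}\t{t.gene}\t{t.snv_labels[0]}\t{t.snv_labels[1]}\t"
                f"{t.cnv_event}\t{t.final_labels[0]}\t{t.final_labels[1]}\t"
                f"{t.phenotype}\n"
            )
        paths["truth"].write_text(buf.getvalue())
        map_buf = io.StringIO()
        first = True
        for gene in sorted(self.phenotype_maps):
            pmap = self.phenotype_maps[gene]
            text = pmap.to_tsv()
            if not first:  # keep a single header block
                text = "\n".join(
                    ln for ln in text.splitlines()
                    if not ln.startswith(("#", "gene\t"))
                ) + "\n"
            map_buf.write(text)
            first = False
        paths["map"].write_text(map_buf.getvalue())
        for gene, table in self.tables.items():
            (out_dir / "tables" / f"{gene}.tsv").write_text(table.to_tsv())
        return paths


def _hap_states(label: str, table: AlleleDefinitionTable, deletion_label: str) -> frozenset:
    """Alt-state variant set implied by a truth label."""
    if label == deletion_label:
        return frozenset()
    out = set()
    for member in label.split("+"):
        base = member[:-2] if member.endswith("xN") else member
        out |= table.allele(base).alt_variants
    return frozenset(out)


def _assign_duplication(labels, functions, priority=("*2", "*1", "*4")):
    for p in priority:
        if p in labels:
            i = labels.index(p)
            return tuple(
                l + "xN" if k == i else l for k, l in enumerate(labels)
            )
    i = min(range(2), key=lambda k: (severity_rank(functions[k]), k))
    return tuple(l + "xN" if k == i else l for k, l in enumerate(labels))


def simulate_cohort(
    spec: SimulationSpec,
    tables: Mapping[str, AlleleDefinitionTable],
    deletion_label: str = "*5",
) -> SimulatedCohort:
    """Draw a phased cohort with ground truth under ``spec``.

    Haplotype labels are drawn independently from each gene's frequency
    vector; composite events overlay the two lowest-numbered non-reference
    alleles on one chromosome; CNV events delete one gene copy (the deleted
    haplotype contributes only reference states to the VCF) or duplicate one
    allele per the *2>*1>*4 order. Platform-untypable positions are absent
    from the VCF; random missingness blanks individual genotypes; imputed
    records carry an ``IMPUTED`` INFO flag and per-sample GP posteriors.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    width = max(5, len(str(n)))
    sample_ids = [f"S{i:0{width}d}" for i in range(1, n + 1)]

    truth: list = []
    cnv_rows: list = []
    # per gene: sample -> pair of alt-variant frozensets for VCF emission
    gene_hap_states: Dict[str, list] = {}
    phenotype_maps = {}

    for gene in sorted(spec.genes):
        gs = spec.genes[gene]
        table = tables[gene]
        pmap = build_phenotype_map(table, deletion_label)
        phenotype_maps[gene] = pmap
        labels = [a.label for a in table.non_structural_alleles()]
        missing_freqs = set(gs.allele_freqs) - set(labels)
        if missing_freqs:
            raise SimulationSpecError(
                f"{gene}: frequencies given for unknown labels {sorted(missing_freqs)}"
            )
        freq_labels = sort_labels(gs.allele_freqs)
        probs = np.array([gs.allele_freqs[l] for l in freq_labels])
        # composite members must not trip the nonfunctional-first pass, or the
        # composite would (correctly) resolve to the no-function allele alone;
        # unknown-function members would make the phenotype unmappable
        comp_pool = [
            l
            for l in sort_labels(labels)
            if l != table.reference_label
            and table.allele(l).function_class
            not in (FunctionClass.NO_FUNCTION, FunctionClass.UNKNOWN)
        ]
        if gs.composite_rate > 0 and len(comp_pool) < 2:
            raise SimulationSpecError(
                f"{gene}: composite events need >= 2 non-reference alleles of "
                "assayed, non-no-function class"
            )
        composite_label = (
            "+".join(sort_labels(comp_pool[:2])) if len(comp_pool) >= 2 else None
        )

        draw = rng.choice(len(freq_labels), size=(n, 2), p=probs)
        comp = rng.random((n, 2)) < gs.composite_rate
        cnv_draw = rng.random(n)
        states_for_gene = []
        for i, sample in enumerate(sample_ids):
            hap_labels = [freq_labels[draw[i, 0]], freq_labels[draw[i, 1]]]
            for h in range(2):
                if comp[i, h]:
                    hap_labels[h] = composite_label
            event = "normal"
            if cnv_draw[i] < gs.deletion_rate:
                event = "deletion"
            elif cnv_draw[i] < gs.deletion_rate + gs.duplication_rate:
                event = "duplication"

            if event == "deletion":
                # one physical copy remains; the deleted haplotype reads as
                # reference at every SNV
                kept = hap_labels[0]
                snv = (table.reference_label, kept)
                final = (deletion_label, kept)
                cnv_rows.append((sample, gene, event, 1))
            elif event == "duplication":
                snv = tuple(hap_labels)
                functions = [label_function(l, table, deletion_label) for l in snv]
                final = _assign_duplication(list(snv), functions)
                cnv_rows.append((sample, gene, event, 3))
            else:
                snv = tuple(hap_labels)
                final = snv

            fns = [label_function(l, table, deletion_label) for l in final]
            phenotype = diplotype_phenotype(*sorted(fns, key=severity_rank))
            truth.append(
                TruthRecord(sample, gene, snv, event, final, phenotype)
            )
            states_for_gene.append(
                (
                    _hap_states(snv[0], table, deletion_label),
                    _hap_states(snv[1], table, deletion_label),
                )
            )
        gene_hap_states[gene] = states_for_gene

    vcf_text = _emit_vcf(spec, tables, gene_hap_states, sample_ids, rng)

    from .cnv import CnvRecord

    cnv_records = [CnvRecord(s, g, e, cn) for s, g, e, cn in cnv_rows]
    return SimulatedCohort(
        spec, dict(tables), phenotype_maps, truth, vcf_text, cnv_records
    )


def _emit_vcf(spec, tables, gene_hap_states, sample_ids, rng) -> str:
    rows = []  # (contig, pos, variant, gene)
    for gene in sorted(spec.genes):
        table = tables[gene]
        for v in table.variants:
            if spec.platform.is_typable(v):
                rows.append((v.contig, v.pos, v, gene))
    rows.sort(key=lambda r: (r[0], r[1]))

    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Imputed site">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">\n'
    )
    for contig in sorted({r[0] for r in rows}):
        buf.write(f"##contig=<ID={contig}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
        + "\n"
    )
    n = len(sample_ids)
    for contig, pos, v, gene in rows:
        imputed = bool(rng.random() < spec.imputed_fraction)
        miss_mask = rng.random(n) < spec.missingness
        if imputed:
            low = rng.random(n) < spec.gp_low_rate
            gp_hi = rng.uniform(0.95, 1.0, size=n)
            gp_lo = rng.uniform(0.50, 0.899, size=n)
            gps = np.where(low, gp_lo, gp_hi)
        info = "IMPUTED" if imputed else "."
        fmt = "GT:GP" if imputed else "GT"
        cells = []
        states = gene_hap_states[gene]
        for i in range(n):
            if miss_mask[i]:
                gt = ".|."
            else:
                a = 1 if v in states[i][0] else 0
                b = 1 if v in states[i][1] else 0
                gt = f"{a}|{b}"
            if imputed:
                p = gps[i]
                rest = (1.0 - p) / 2.0
                gt = f"{gt}:{rest:.3f},{p:.3f},{rest:.3f}"
            cells.append(gt)
        buf.write(
            f"{contig}\t{pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t"
            f"{info}\t{fmt}\t" + "\t".join(cells) + "\n"
        )
    return buf.getvalue()
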