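"""Diplotype enumeration and metabolizer-phenotype translation.

A diplotype is the unordered pair of star alleles a person carries for one
gene; phenotype translation is a lookup into a diplotype→phenotype mapping
table (the per-gene vocabulary covers metabolizer classes, dose phenotypes,
treatment-response labels, or transporter function, depending on the gene).
When a haplotype call is ambiguous, every candidate diplotype is looked up:
if all of them agree, the phenotype is still determinate — this is exactly
why same-function ambiguities (e.g. DPYD *5/*6/*9) are harmless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Set, TextIO, Union

from .caller import CallStatus, HaplotypeCall
from .errors import FormatError
from .util import format_diplotype, sort_labels


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of allele labels; *1/*2 equals *2/*1."""

    gene: str
    labels: tuple

    def __init__(self, gene: str, labels: Iterable[str]):
        labels = tuple(sort_labels(labels))
        if len(labels) != 2:
            raise ValueError(f"diplotype needs exactly 2 labels, got {labels}")
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "labels", labels)

    def __str__(self) -> str:
        return format_diplotype(*self.labels)


class PhenotypeStatus(str, Enum):
    DETERMINATE = "determinate"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PhenotypeCall:
    gene: str
    status: PhenotypeStatus
    phenotype: Optional[str] = None
    candidate_diplotypes: frozenset = frozenset()
    reason: str = ""


@dataclass
class DiplotypePhenotypeMap:
    """Per-gene mapping from unordered allele pairs to phenotype labels.

    ``vocabulary`` optionally declares the allowed phenotype labels; entries
    outside it are rejected at load time.
    """

    gene: str
    entries: dict = field(default_factory=dict)  # sorted label pair -> phenotype
    vocabulary: Optional[frozenset] = None

    @staticmethod
    def _key(labels: Iterable[str]) -> tuple:
        return tuple(sort_labels(labels))

    def add(self, label_a: str, label_b: str, phenotype: str) -> None:
        if self.vocabulary is not None and phenotype not in self.vocabulary:
            raise FormatError(
                f"{self.gene}: phenotype {phenotype!r} outside declared vocabulary"
            )
        self.entries[self._key((label_a, label_b))] = phenotype

    def lookup(self, diplotype: Diplotype) -> Optional[str]:
        return self.entries.get(self._key(diplotype.labels))

    def to_tsv(self, stream: Optional[TextIO] = None) -> str:
        buf = stream or io.StringIO()
        if self.vocabulary is not None:
            buf.write("#phenotypes: " + "|".join(sorted(self.vocabulary)) + "\n")
        buf.write("gene\tallele1\tallele2\tphenotype\n")
        for (a, b), ph in sorted(self.entries.items()):
            buf.write(f"{self.gene}\t{a}\t{b}\t{ph}\n")
        return buf.getvalue() if stream is None else ""


def parse_phenotype_maps(source: Union[str, TextIO]) -> dict:
    """Parse a mapping TSV (gene, allele1, allele2, phenotype) into per-gene maps.

    A leading ``#phenotypes: a|b|c`` comment declares the vocabulary for the
    genes that follow in the file (shared across the file).
    """
    text = source.read() if hasattr(source, "read") else source
    vocabulary = None
    maps: dict = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    body = []
    for ln in lines:
        if ln.startswith("#phenotypes:"):
            vocabulary = frozenset(
                t.strip() for t in ln.split(":", 1)[1].split("|") if t.strip()
            )
        elif not ln.startswith("#"):
            body.append(ln)
    if not body:
        return maps
    header = body[0].split("\t")
    if header != ["gene", "allele1", "allele2", "phenotype"]:
        raise FormatError(
            f"phenotype map columns must be gene, allele1, allele2, phenotype; got {header}"
        )
    for ln in body[1:]:
        cells = ln.split("\t")
        if len(cells) != 4:
            raise FormatError(f"bad phenotype map row {ln!r}")
        gene, a, b, ph = cells
        pmap = maps.setdefault(gene, DiplotypePhenotypeMap(gene, {}, vocabulary))
        pmap.add(a, b, ph)
    return maps


def enumerate_diplotypes(calls: Sequence[HaplotypeCall]) -> Set[Diplotype]:
    """All diplotypes consistent with a pair of haplotype calls.

    Resolved haplotypes (single or composite) contribute their resolved label;
    ambiguous haplotypes contribute every full-match candidate. A no-match
    haplotype yields the empty set — there is no allele to pair.
    """
    call_a, call_b = calls
    if CallStatus.NO_MATCH in (call_a.status, call_b.status):
        return set()
    set_a = call_a.candidate_labels
    set_b = call_b.candidate_labels
    return {Diplotype(call_a.gene, (a, b)) for a in set_a for b in set_b}


def resolve_phenotype(
    diplotypes: Set[Diplotype], pmap: DiplotypePhenotypeMap
) -> PhenotypeCall:
    """Translate candidate diplotypes to a phenotype.

    Determinate iff every candidate is present in the map and all map to the
    same phenotype; any missing entry or disagreement is indeterminate.
    """
    if not diplotypes:
        raise ValueError("resolve_phenotype: empty diplotype set")
    gene = next(iter(diplotypes)).gene
    phenotypes = set()
    missing = []
    for d in diplotypes:
        ph = pmap.lookup(d)
        if ph is None:
            missing.append(str(d))
        else:
            phenotypes.add(ph)
    cands = frozenset(diplotypes)
    if missing:
        return PhenotypeCall(
            gene,
            PhenotypeStatus.INDETERMINATE,
            candidate_diplotypes=cands,
            reason=f"no map entry for {', '.join(sorted(missing))}",
        )
    if len(phenotypes) != 1:
        return PhenotypeCall(
            gene,
            PhenotypeStatus.INDETERMINATE,
            candidate_diplotypes=cands,
            reason=f"candidates map to {len(phenotypes)} phenotypes",
        )
    return PhenotypeCall(
        gene,
        PhenotypeStatus.DETERMINATE,
        phenotype=next(iter(phenotypes)),
        candidate_diplotypes=cands,
    )


def phenotype_sample(
    calls: Sequence[HaplotypeCall], pmap: DiplotypePhenotypeMap
) -> PhenotypeCall:
    """Convenience: diplotype enumeration + phenotype resolution, no-match safe."""
    diplotypes = enumerate_diplotypes(calls)
    if not diplotypes:
        return PhenotypeCall(
            calls[0].gene,
            PhenotypeStatus.INDETERMINATE,
            reason="no-match haplotype",
        )
    return resolve_phenotype(diplotypes, pmap)


def flag_high_risk(
    call: PhenotypeCall, normal_labels: Mapping[str, Set[str]]
) -> Optional[bool]:
    """True iff a determinate phenotype is outside the gene's normal set.

    Indeterminate calls return ``None`` (undefined risk), never a boolean.
    """
    if call.status is not PhenotypeStatus.DETERMINATE:
        return None
    normal = normal_labels.get(call.gene, set())
    return call.phenotype not in normal
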