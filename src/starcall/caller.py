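"""Haplotype → star-allele resolution.

Matching semantics: a star allele matches a phased haplotype iff every one of
its required variant states is actually observed there — a missing state never
satisfies a requirement. The reference allele (*1) matches iff no alternate
state is observed at any table variant. Structural alleles (deletion /
duplication) are never matched from SNV states; they enter through the
copy-number integrator.

Resolution ladder (applied per haplotype):

1. Nonfunctional-first pass — only no-function alleles are tested; any hit
   resolves the haplotype immediately (ties broken by the largest definition,
   then label collation).
2. All remaining alleles. A single candidate resolves directly. Among several
   candidates, a unique decreased-function candidate overrides normal-function
   ones; candidates with pairwise-disjoint alternate requirements that jointly
   explain every observed alternate state form a composite call (``*2+*3``);
   anything else is an ambiguous call. No candidate at all, with at least one
   observed alternate state, is a no-match.

Because missing data can hide the distinction between alleles, every call also
carries the *compatible* set — alleles whose requirements are merely not
contradicted by the observed states — and reference calls made in the presence
of missing table variants carry a wild-type disclaimer flag: such a *1 is a
default, not a demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

from .definitions import (
    AlleleDefinitionTable,
    FunctionClass,
    StarAlleleDef,
    Structural,
)
from .genotypes import ALT, MISSING, SampleHaplotypes
from .util import most_severe, severity_rank, sort_labels


class CallStatus(str, Enum):
    SINGLE = "single"
    COMPOSITE = "composite"
    AMBIGUOUS = "ambiguous"
    NO_MATCH = "no_match"


@dataclass(frozen=True)
class HaplotypeCall:
    gene: str
    status: CallStatus
    candidates: frozenset = frozenset()  # fully matching labels
    resolved_label: Optional[str] = None
    resolved_function: Optional[FunctionClass] = None
    unexplained_variants: frozenset = frozenset()
    compatible: frozenset = frozenset()  # labels not contradicted (missing-aware)
    wildtype_disclaimer: bool = False

    @property
    def candidate_labels(self) -> frozenset:
        """Labels this haplotype may carry: the resolved one, or for an
        ambiguous call every full-match candidate."""
        if self.resolved_label is not None:
            return frozenset({self.resolved_label})
        return self.candidates


def _matches(allele: StarAlleleDef, hap: Mapping) -> bool:
    return all(hap.get(v) == state for v, state in allele.required_states.items())


def _compatible(allele: StarAlleleDef, hap: Mapping) -> bool:
    return all(
        hap.get(v) in (state, MISSING) for v, state in allele.required_states.items()
    )


def _observed_alt(hap: Mapping, table: AlleleDefinitionTable) -> frozenset:
    return frozenset(v for v in table.variants if hap.get(v) == ALT)


def candidate_matches(hap: Mapping, table: AlleleDefinitionTable) -> frozenset:
    """All non-structural allele labels fully matched by the haplotype."""
    observed_alt = _observed_alt(hap, table)
    out = set()
    for a in table.non_structural_alleles():
        if a.label == table.reference_label:
            if not observed_alt:
                out.add(a.label)
        elif _matches(a, hap):
            out.add(a.label)
    return frozenset(out)


def compatible_matches(hap: Mapping, table: AlleleDefinitionTable) -> frozenset:
    """Labels whose requirements are not contradicted by any observed state."""
    observed_alt = _observed_alt(hap, table)
    out = set()
    for a in table.non_structural_alleles():
        if a.label == table.reference_label:
            if not observed_alt:
                out.add(a.label)
        elif _compatible(a, hap):
            out.add(a.label)
    return frozenset(out)


def _pick_nonfunctional(hits: list) -> StarAlleleDef:
    # largest definition first, then label collation; deterministic
    return sorted(
        hits, key=lambda a: (-len(a.required_states), a.label)
    )[0]


def resolve_call(
    hap: Mapping,
    table: AlleleDefinitionTable,
    nonfunctional_semantics: str = "full",
) -> HaplotypeCall:
    """Resolve one phased haplotype to a star-allele call.

    ``nonfunctional_semantics`` selects whether the nonfunctional-first pass
    requires a full match (``"full"``, default) or mere compatibility under
    missingness (``"compatible"``).
    """
    if nonfunctional_semantics not in ("full", "compatible"):
        raise ValueError(f"bad nonfunctional_semantics {nonfunctional_semantics!r}")
    observed_alt = _observed_alt(hap, table)
    any_missing = any(hap.get(v) == MISSING for v in table.variants)
    compat = compatible_matches(hap, table)

    nonfunctional = [
        a
        for a in table.non_structural_alleles()
        if a.function_class is FunctionClass.NO_FUNCTION
        and a.label != table.reference_label
    ]
    test = _matches if nonfunctional_semantics == "full" else _compatible
    pass1_hits = [a for a in nonfunctional if test(a, hap)]
    if pass1_hits:
        best = _pick_nonfunctional(pass1_hits)
        unexplained = observed_alt - best.alt_variants
        return HaplotypeCall(
            gene=table.gene,
            status=CallStatus.SINGLE,
            candidates=frozenset(a.label for a in pass1_hits),
            resolved_label=best.label,
            resolved_function=best.function_class,
            unexplained_variants=unexplained,
            compatible=compat,
        )

    remaining = [
        a
        for a in table.non_structural_alleles()
        if a.function_class is not FunctionClass.NO_FUNCTION
        or a.label == table.reference_label
    ]
    cands = []
    for a in remaining:
        if a.label == table.reference_label:
            if not observed_alt:
                cands.append(a)
        elif _matches(a, hap):
            cands.append(a)
    cand_labels = frozenset(a.label for a in cands)

    if not cands:
        # reference would have matched were there no observed alt states
        return HaplotypeCall(
            gene=table.gene,
            status=CallStatus.NO_MATCH,
            candidates=frozenset(),
            unexplained_variants=observed_alt,
            compatible=compat,
        )

    if len(cands) == 1:
        a = cands[0]
        return HaplotypeCall(
            gene=table.gene,
            status=CallStatus.SINGLE,
            candidates=cand_labels,
            resolved_label=a.label,
            resolved_function=a.function_class,
            unexplained_variants=observed_alt - a.alt_variants,
            compatible=compat,
            wildtype_disclaimer=(a.label == table.reference_label and any_missing),
        )

    # composite first: candidates with pairwise-disjoint alternate
    # requirements that jointly explain every observed alternate state are
    # genuinely co-occurring alleles, not an ambiguity to adjudicate
    alt_sets = [a.alt_variants for a in cands]
    disjoint = all(
        not (alt_sets[i] & alt_sets[j])
        for i in range(len(alt_sets))
        for j in range(i + 1, len(alt_sets))
    )
    union = frozenset().union(*alt_sets)
    if disjoint and union == observed_alt and all(alt_sets):
        label = "+".join(sort_labels(a.label for a in cands))
        function = FunctionClass(
            most_severe(a.function_class.value for a in cands)
        )
        return HaplotypeCall(
            gene=table.gene,
            status=CallStatus.COMPOSITE,
            candidates=cand_labels,
            resolved_label=label,
            resolved_function=function,
            unexplained_variants=frozenset(),
            compatible=compat,
        )

    decreased = [a for a in cands if a.function_class is FunctionClass.DECREASED]
    normals = [a for a in cands if a.function_class is FunctionClass.NORMAL]
    if len(decreased) == 1 and len(decreased) + len(normals) == len(cands):
        a = decreased[0]
        return HaplotypeCall(
            gene=table.gene,
            status=CallStatus.SINGLE,
            candidates=cand_labels,
            resolved_label=a.label,
            resolved_function=a.function_class,
            unexplained_variants=observed_alt - a.alt_variants,
            compatible=compat,
        )

    unexplained = observed_alt - union
    return HaplotypeCall(
        gene=table.gene,
        status=CallStatus.AMBIGUOUS,
        candidates=cand_labels,
        unexplained_variants=unexplained,
        compatible=compat,
    )


def call_sample_gene(
    samp: SampleHaplotypes,
    table: AlleleDefinitionTable,
    nonfunctional_semantics: str = "full",
) -> tuple:
    """Resolve both of a sample's haplotypes independently."""
    return (
        resolve_call(samp.hap_a, table, nonfunctional_semantics),
        resolve_call(samp.hap_b, table, nonfunctional_semantics),
    )


def call_function(call: HaplotypeCall, table: AlleleDefinitionTable) -> Optional[FunctionClass]:
    """Function class of a resolved call (composite → most severe member)."""
    if call.resolved_function is not None:
        return call.resolved_function
    if call.resolved_label is None:
        return None
    members = call.resolved_label.split("+")
    return FunctionClass(
        most_severe(table.allele(m).function_class.value for m in members)
    )


__all__ = [
    "CallStatus",
    "HaplotypeCall",
    "candidate_matches",
    "compatible_matches",
    "resolve_call",
    "call_sample_gene",
    "call_function",
    "severity_rank",
]
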