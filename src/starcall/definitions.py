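"""Star-allele definition tables: parsing, validation, curation, platform masking.

A definition table is the per-gene matrix that maps each named (star) allele
to the variant states required for a haplotype to carry it. The reference
allele (conventionally ``*1``) requires nothing and is called when no
alternate state is observed at any table variant. Structural alleles
(whole-gene deletion such as CYP2D6 ``*5``, and duplications) carry no SNV
requirements and are resolved from copy-number calls, not from genotypes.

File dialect (TSV, UTF-8): fixed columns ``gene, label, function,
structural`` followed by one column per variant, headed
``contig:pos:ref:alt[:rsid]``; allele-row cells contain ``ref``, ``alt`` or
blank (blank = state not required).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from .errors import CurationError, FormatError
from .util import most_severe, round_half_away, star_sort_key


class FunctionClass(str, Enum):
    NO_FUNCTION = "no_function"
    DECREASED = "decreased"
    NORMAL = "normal"
    INCREASED = "increased"
    UNKNOWN = "unknown"


class Structural(str, Enum):
    NONE = "none"
    DELETION = "deletion"
    DUPLICATION = "duplication"


@dataclass(frozen=True)
class VariantDef:
    """A biallelic variant position on the forward GRCh37 strand.

    Identity (equality/hash) is ``(contig, pos, ref, alt)``; the rsid is
    annotation only, so records parsed with and without an rsid compare equal.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError(f"empty ref/alt at {self.contig}:{self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    def column_header(self) -> str:
        return self.key + (f":{self.rsid}" if self.rsid else "")

    @classmethod
    def from_key(cls, key: str) -> "VariantDef":
        parts = key.split(":")
        if len(parts) not in (4, 5):
            raise FormatError(f"bad variant column header {key!r}")
        contig, pos, ref, alt = parts[:4]
        rsid = parts[4] if len(parts) == 5 else None
        try:
            pos_i = int(pos)
        except ValueError as exc:
            raise FormatError(f"non-integer position in {key!r}") from exc
        return cls(contig, pos_i, ref, alt, rsid)


@dataclass(frozen=True)
class StarAlleleDef:
    """One named allele: the variant states it requires plus its function class."""

    gene: str
    label: str
    required_states: Mapping[VariantDef, str]  # values: "ref" | "alt"
    function_class: FunctionClass = FunctionClass.NORMAL
    structural: Structural = Structural.NONE

    def __post_init__(self):
        for v, state in self.required_states.items():
            if state not in ("ref", "alt"):
                raise FormatError(
                    f"{self.gene} {self.label}: required state {state!r} at "
                    f"{v.key} must be 'ref' or 'alt'"
                )
        if self.structural is Structural.DELETION and self.required_states:
            raise FormatError(
                f"{self.gene} {self.label}: deletion alleles carry no variant "
                "requirements"
            )

    @property
    def alt_variants(self) -> frozenset:
        """Variants this allele requires in the alternate state."""
        return frozenset(v for v, s in self.required_states.items() if s == "alt")


@dataclass
class AlleleDefinitionTable:
    """A gene's complete star-allele definition matrix."""

    gene: str
    variants: list  # ordered list[VariantDef]
    alleles: list  # list[StarAlleleDef]
    reference_label: str = "*1"
    # labels / variant keys removed by earlier curation; lets a directive list
    # be re-applied idempotently while still flagging targets that never existed
    removed_labels: set = field(default_factory=set)
    removed_variant_keys: set = field(default_factory=set)

    def validate(self) -> "AlleleDefinitionTable":
        seen_v = set()
        for v in self.variants:
            if v in seen_v:
                raise FormatError(f"{self.gene}: duplicate variant {v.key}")
            seen_v.add(v)
        labels = [a.label for a in self.alleles]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"{self.gene}: duplicate allele labels {dupes}")
        refs = [a for a in self.alleles if a.label == self.reference_label]
        if len(refs) != 1:
            raise FormatError(
                f"{self.gene}: expected exactly one reference allele "
                f"{self.reference_label!r}, found {len(refs)}"
            )
        ref = refs[0]
        if ref.required_states or ref.structural is not Structural.NONE:
            raise FormatError(
                f"{self.gene}: reference allele must have no required states"
            )
        if ref.function_class is not FunctionClass.NORMAL:
            raise FormatError(f"{self.gene}: reference allele must be normal function")
        defs_seen = {}
        for a in self.alleles:
            for v in a.required_states:
                if v not in seen_v:
                    raise FormatError(
                        f"{self.gene} {a.label}: required variant {v.key} not a "
                        "table column"
                    )
            if a.structural is Structural.NONE:
                key = frozenset(a.required_states.items())
                if key in defs_seen:
                    raise FormatError(
                        f"{self.gene}: alleles {defs_seen[key]} and {a.label} "
                        "share an identical definition"
                    )
                defs_seen[key] = a.label
        return self

    # -- lookups -----------------------------------------------------------

    def allele(self, label: str) -> StarAlleleDef:
        for a in self.alleles:
            if a.label == label:
                return a
        raise KeyError(f"{self.gene}: no allele {label!r}")

    @property
    def labels(self) -> list:
        return [a.label for a in self.alleles]

    @property
    def reference(self) -> StarAlleleDef:
        return self.allele(self.reference_label)

    def non_structural_alleles(self) -> list:
        return [a for a in self.alleles if a.structural is Structural.NONE]

    # -- serialization -----------------------------------------------------

    def to_tsv(self, stream: Optional[TextIO] = None) -> str:
        buf = stream or io.StringIO()
        header = ["gene", "label", "function", "structural"] + [
            v.column_header() for v in self.variants
        ]
        buf.write("\t".join(header) + "\n")
        for a in self.alleles:
            cells = [a.gene, a.label, a.function_class.value, a.structural.value]
            for v in self.variants:
                cells.append(a.required_states.get(v, ""))
            buf.write("\t".join(cells) + "\n")
        return buf.getvalue() if stream is None else ""


def parse_definition_table(
    source: Union[str, TextIO], gene: Optional[str] = None
) -> AlleleDefinitionTable:
    """Parse a TSV definition table and validate it.

    ``source`` is a text stream or the table text itself. If ``gene`` is
    given, rows for other genes are rejected.
    """
    text = source.read() if hasattr(source, "read") else source
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError("empty definition table")
    header = lines[0].rstrip("\n").split("\t")
    if header[:4] != ["gene", "label", "function", "structural"]:
        raise FormatError(
            "definition table must start with columns gene, label, function, "
            f"structural; got {header[:4]}"
        )
    variants = [VariantDef.from_key(h) for h in header[4:]]
    alleles = []
    table_gene = gene
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(header):
            cells += [""] * (len(header) - len(cells))
        row_gene, label, function, structural = cells[:4]
        if table_gene is None:
            table_gene = row_gene
        if row_gene != table_gene:
            raise FormatError(
                f"line {lineno}: gene {row_gene!r} does not match {table_gene!r}"
            )
        try:
            fclass = FunctionClass(function or "normal")
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unknown function {function!r}") from exc
        try:
            struct = Structural(structural or "none")
        except ValueError as exc:
            raise FormatError(
                f"line {lineno}: unknown structural kind {structural!r}"
            ) from exc
        required = {}
        for v, cell in zip(variants, cells[4:]):
            cell = cell.strip()
            if not cell:
                continue
            if cell not in ("ref", "alt"):
                raise FormatError(
                    f"line {lineno}: cell {cell!r} at {v.key} must be 'ref', "
                    "'alt' or blank"
                )
            required[v] = cell
        alleles.append(
            StarAlleleDef(table_gene, label, required, fclass, struct)
        )
    if table_gene is None:
        raise FormatError("definition table has no allele rows")
    ref_candidates = [
        a
        for a in alleles
        if not a.required_states and a.structural is Structural.NONE
    ]
    if not ref_candidates:
        raise FormatError(f"{table_gene}: no reference row (empty requirements)")
    reference_label = ref_candidates[0].label
    table = AlleleDefinitionTable(table_gene, variants, alleles, reference_label)
    return table.validate()


# ---------------------------------------------------------------------------
# Platform profiles


@dataclass(frozen=True)
class PlatformProfile:
    """Which table variants a genotyping platform can interrogate.

    ``typable`` is either the string ``"all"`` (sequencing-like: every
    position is covered) or a frozenset of ``(contig, pos)`` coordinates.
    ``supports_cnv`` reflects whether gene-level copy number can be called
    on this platform; structural alleles are dropped where it cannot.
    """

    name: str
    typable: Union[str, frozenset] = "all"
    supports_cnv: bool = True

    def is_typable(self, variant: VariantDef) -> bool:
        if self.typable == "all":
            return True
        return (variant.contig, variant.pos) in self.typable

    @classmethod
    def from_positions(
        cls, name: str, positions: Iterable, supports_cnv: bool
    ) -> "PlatformProfile":
        return cls(name, frozenset((str(c), int(p)) for c, p in positions), supports_cnv)


def typability_report(
    variants: Sequence[VariantDef], profile: PlatformProfile
) -> tuple:
    """Count how many definition-table variants a platform can directly type.

    Returns ``(count, percent)`` with the percentage rounded to the integer,
    half away from zero.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("typability_report: empty variant list")
    count = sum(1 for v in variants if profile.is_typable(v))
    percent = int(round_half_away(100.0 * count / len(variants)))
    return count, percent


# ---------------------------------------------------------------------------
# Curation


class CurationAction(str, Enum):
    DROP_ALLELE = "drop_allele"
    MERGE_ALLELES = "merge_alleles"
    DROP_VARIANT_FROM_ALLELE = "drop_variant_from_allele"
    DROP_STRUCTURAL_FOR_PLATFORM = "drop_structural_for_platform"


@dataclass(frozen=True)
class CurationDirective:
    """One manual pruning rule applied to a definition table.

    ``targets`` holds allele labels, except for ``drop_variant_from_allele``
    where the first target is the allele label and the rest are variant keys
    (``contig:pos:ref:alt``). ``drop_structural_for_platform`` with empty
    targets drops every structural allele (when the platform lacks CNV
    support).
    """

    gene: str
    action: CurationAction
    targets: tuple = ()
    merged_label: Optional[str] = None
    reason: str = ""

    def __post_init__(self):
        if self.action is CurationAction.MERGE_ALLELES and not self.merged_label:
            raise CurationError(
                f"{self.gene}: merge_alleles directive needs merged_label"
            )


def parse_curation_directives(source: Union[str, TextIO]) -> list:
    """Parse a directives TSV: gene, action, targets (comma-sep), merged_label, reason."""
    text = source.read() if hasattr(source, "read") else source
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    expected = ["gene", "action", "targets", "merged_label", "reason"]
    if header != expected:
        raise FormatError(f"curation file columns must be {expected}, got {header}")
    directives = []
    for line in lines[1:]:
        cells = line.split("\t")
        cells += [""] * (5 - len(cells))
        gene, action, targets, merged_label, reason = cells[:5]
        try:
            act = CurationAction(action)
        except ValueError as exc:
            raise FormatError(f"unknown curation action {action!r}") from exc
        tgt = tuple(t.strip() for t in targets.split(",") if t.strip())
        directives.append(
            CurationDirective(gene, act, tgt, merged_label or None, reason)
        )
    return directives


def _drop_allele(table: AlleleDefinitionTable, d: CurationDirective) -> None:
    labels = set(table.labels)
    for t in d.targets:
        if t not in labels and t not in table.removed_labels:
            raise CurationError(
                f"{d.gene}: drop_allele target {t!r} not in table ({d.reason or d.action.value})"
            )
    table.alleles = [a for a in table.alleles if a.label not in set(d.targets)]
    table.removed_labels.update(set(d.targets) & labels)


def _merge_alleles(table: AlleleDefinitionTable, d: CurationDirective) -> None:
    if d.merged_label in set(table.labels) and not (
        set(d.targets) & set(table.labels)
    ):
        return  # already applied
    sources = []
    for t in d.targets:
        try:
            sources.append(table.allele(t))
        except KeyError:
            raise CurationError(f"{d.gene}: merge target {t!r} not in table") from None
    if len(sources) < 2:
        raise CurationError(f"{d.gene}: merge_alleles needs >= 2 targets")
    # The merged definition keeps the states shared by every source, i.e. the
    # definition compatible with the union of their carriers; a proxy-variant
    # collapse must not tighten requirements.
    shared = dict(sources[0].required_states)
    for src in sources[1:]:
        shared = {
            v: s for v, s in shared.items() if src.required_states.get(v) == s
        }
    for src in sources:
        for v, s in src.required_states.items():
            for other in sources:
                if v in other.required_states and other.required_states[v] != s:
                    raise CurationError(
                        f"{d.gene}: merge targets disagree on {v.key}"
                    )
    if not shared:
        raise CurationError(
            f"{d.gene}: merged allele {d.merged_label!r} would require nothing"
        )
    merged = StarAlleleDef(
        table.gene,
        d.merged_label,
        shared,
        FunctionClass(most_severe(s.function_class.value for s in sources)),
        Structural.NONE,
    )
    keep = [a for a in table.alleles if a.label not in set(d.targets)]
    keep.append(merged)
    table.alleles = keep
    table.removed_labels.update(d.targets)


def _drop_variant_from_allele(table: AlleleDefinitionTable, d: CurationDirective) -> None:
    if len(d.targets) < 2:
        raise CurationError(
            f"{d.gene}: drop_variant_from_allele needs (label, variant...) targets"
        )
    label, *variant_keys = d.targets
    try:
        allele = table.allele(label)
    except KeyError:
        if label in table.removed_labels:
            return
        raise CurationError(f"{d.gene}: allele {label!r} not in table") from None
    by_key = {v.key: v for v in table.variants}
    new_required = dict(allele.required_states)
    for vk in variant_keys:
        v = by_key.get(vk)
        if v is None:
            if vk in table.removed_variant_keys:
                continue  # column pruned by an earlier application
            raise CurationError(f"{d.gene}: variant {vk!r} is not a table column")
        new_required.pop(v, None)
    table.alleles = [
        replace(a, required_states=new_required) if a.label == label else a
        for a in table.alleles
    ]


def _drop_structural(
    table: AlleleDefinitionTable, d: CurationDirective, profile: Optional[PlatformProfile]
) -> None:
    if profile is None or profile.supports_cnv:
        return  # platform can call CNVs: structural alleles stay
    structural = {
        a.label for a in table.alleles if a.structural is not Structural.NONE
    }
    targets = set(d.targets) or structural
    unknown = targets - set(table.labels) - table.removed_labels
    if unknown:
        raise CurationError(
            f"{d.gene}: drop_structural targets {sorted(unknown)} not in table"
        )
    non_structural = (targets & set(table.labels)) - structural
    if non_structural:
        raise CurationError(
            f"{d.gene}: targets {sorted(non_structural)} are not structural alleles"
        )
    table.alleles = [a for a in table.alleles if a.label not in targets]
    table.removed_labels.update(targets & structural)


def apply_curation(
    table: AlleleDefinitionTable,
    directives: Iterable[CurationDirective],
    profile: Optional[PlatformProfile] = None,
) -> AlleleDefinitionTable:
    """Apply curation directives in order and return a re-validated table.

    Directives for other genes are ignored, so one directives file can cover a
    whole gene panel. After application, variant columns no longer required by
    any surviving allele are pruned from the table.
    """
    out = AlleleDefinitionTable(
        table.gene,
        list(table.variants),
        list(table.alleles),
        table.reference_label,
        set(table.removed_labels),
        set(table.removed_variant_keys),
    )
    for d in directives:
        if d.gene != table.gene:
            continue
        if d.action is CurationAction.DROP_ALLELE:
            _drop_allele(out, d)
        elif d.action is CurationAction.MERGE_ALLELES:
            _merge_alleles(out, d)
        elif d.action is CurationAction.DROP_VARIANT_FROM_ALLELE:
            _drop_variant_from_allele(out, d)
        elif d.action is CurationAction.DROP_STRUCTURAL_FOR_PLATFORM:
            _drop_structural(out, d, profile)
    used = set()
    for a in out.alleles:
        used.update(a.required_states)
    out.removed_variant_keys.update(v.key for v in out.variants if v not in used)
    out.variants = [v for v in out.variants if v in used]
    out.alleles = sorted(out.alleles, key=lambda a: star_sort_key(a.label))
    return out.validate()
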