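"""Whole-gene copy-number integration for CYP2D6-style genes.

Copy-number events are consumed as per-sample calls (they are discovered
upstream, from sequencing depth or array intensities). A whole-gene deletion
replaces one haplotype's SNV-derived label with the deletion allele (*5 for
CYP2D6); a duplication appends the ``xN`` suffix to one existing label,
choosing which by the published European duplication order *2 > *1 > *4.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence, TextIO, Union

from .caller import HaplotypeCall
from .definitions import PlatformProfile
from .errors import ConfigurationError, DataError
from .util import severity_rank

DEFAULT_DUPLICATION_PRIORITY = ("*2", "*1", "*4")


@dataclass(frozen=True)
class CnvRecord:
    sample: str
    gene: str
    event: str  # "deletion" | "duplication" | "normal"
    copy_number: Optional[int] = None

    def __post_init__(self):
        if self.event not in ("deletion", "duplication", "normal"):
            raise DataError(f"unknown CNV event {self.event!r}")
        if self.copy_number is not None:
            if self.copy_number < 0:
                raise DataError("copy_number must be non-negative")
            if self.event == "deletion" and self.copy_number > 1:
                raise DataError(
                    f"deletion with copy_number {self.copy_number} (> 1)"
                )
            if self.event == "duplication" and self.copy_number < 3:
                raise DataError(
                    f"duplication with copy_number {self.copy_number} (< 3)"
                )


def read_cnv_table(source: Union[str, TextIO]) -> list:
    """Parse a CNV TSV: sample, gene, event, copy_number (blank allowed)."""
    text = source.read() if hasattr(source, "read") else source
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    if header[:3] != ["sample", "gene", "event"]:
        raise DataError(f"CNV table columns must start sample, gene, event; got {header}")
    records = []
    for line in lines[1:]:
        cells = line.split("\t")
        cells += [""] * (4 - len(cells))
        sample, gene, event, cn = cells[:4]
        records.append(
            CnvRecord(sample, gene, event, int(cn) if cn.strip() else None)
        )
    return records


@dataclass(frozen=True)
class CnvAdjustment:
    """Result of applying a CNV event to a pair of resolved labels."""

    labels: tuple  # adjusted (label_a, label_b)
    flagged: bool = False
    note: str = ""


def _resolved_labels(calls) -> tuple:
    labels = []
    for c in calls:
        if isinstance(c, HaplotypeCall):
            if c.resolved_label is None:
                raise DataError(
                    f"{c.gene}: CNV integration needs resolved calls, got "
                    f"status {c.status.value}"
                )
            labels.append(c.resolved_label)
        else:
            labels.append(str(c))
    return tuple(labels)


def _functions(calls, labels):
    out = []
    for c, lbl in zip(calls, labels):
        if isinstance(c, HaplotypeCall) and c.resolved_function is not None:
            out.append(c.resolved_function.value)
        else:
            out.append("normal" if lbl in ("*1",) else "unknown")
    return out


def integrate_cnv(
    calls: Sequence,
    cnv: CnvRecord,
    priority: Sequence[str] = DEFAULT_DUPLICATION_PRIORITY,
    deletion_label: str = "*5",
    reference_label: str = "*1",
    profile: Optional[PlatformProfile] = None,
) -> CnvAdjustment:
    """Adjust a pair of haplotype calls for a whole-gene CNV event.

    ``calls`` is a pair of resolved :class:`HaplotypeCall` objects (or bare
    labels in tests). Deletions replace the reference-labelled haplotype when
    one is present — a deleted gene copy cannot have contributed observed
    alternate states — otherwise the less severe label is replaced and the
    record is flagged. Duplications suffix ``xN`` to the first label found in
    ``priority``; if neither label is listed, the more severe one is suffixed
    and the record is flagged.
    """
    if profile is not None and not profile.supports_cnv and cnv.event != "normal":
        raise ConfigurationError(
            f"platform {profile.name!r} cannot call copy number for {cnv.gene}; "
            "structural alleles were dropped for this platform"
        )
    labels = _resolved_labels(calls)
    if cnv.event == "normal":
        return CnvAdjustment(labels)

    if cnv.event == "deletion":
        if reference_label in labels:
            idx = labels.index(reference_label)
            flagged, note = False, ""
        else:
            functions = _functions(calls, labels)
            # replace the LESS severe label (higher severity rank)
            idx = max(range(2), key=lambda i: (severity_rank(functions[i]), i))
            flagged = True
            note = (
                "deletion without a reference-labelled haplotype; replaced "
                f"{labels[idx]}"
            )
        new = list(labels)
        new[idx] = deletion_label
        return CnvAdjustment(tuple(new), flagged, note)

    # duplication
    for p in priority:
        if p in labels:
            idx = labels.index(p)
            new = list(labels)
            new[idx] = new[idx] + "xN"
            return CnvAdjustment(tuple(new))
    functions = _functions(calls, labels)
    idx = min(range(2), key=lambda i: (severity_rank(functions[i]), i))
    new = list(labels)
    new[idx] = new[idx] + "xN"
    return CnvAdjustment(
        tuple(new),
        flagged=True,
        note=f"no priority allele present; duplicated {labels[idx]}",
    )


def write_cnv_table(records: Sequence[CnvRecord], stream: Optional[TextIO] = None) -> str:
    buf = stream or io.StringIO()
    buf.write("sample\tgene\tevent\tcopy_number\n")
    for r in records:
        cn = "" if r.copy_number is None else str(r.copy_number)
        buf.write(f"{r.sample}\t{r.gene}\t{r.event}\t{cn}\n")
    return buf.getvalue() if stream is None else ""
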