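"""Shared helpers: star-label collation, function-class severity, rounding.

Star labels are collated numerically (``*2`` < ``*10``), with alphanumeric
suffixes breaking ties (``*9A`` < ``*9B``), so that diplotype keys like
``*1/*2`` are byte-identical regardless of haplotype order. Composite labels
(``*2+*3``) collate by their member sequence; a duplication suffix (``xN``)
sorts after the plain label.
"""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_STAR_RE = re.compile(r"^\*?(\d+)([A-Za-z0-9_.]*)$")


def _member_key(label: str) -> tuple:
    dup = label.endswith("xN")
    core = label[:-2] if dup else label
    m = _STAR_RE.match(core)
    if m:
        return (0, int(m.group(1)), m.group(2), int(dup))
    # non-numeric labels (e.g. named haplotypes) sort after star numbers
    return (1, 0, core, int(dup))


def star_sort_key(label: str) -> tuple:
    """Collation key for a star-allele label, composite-aware."""
    return tuple(_member_key(part) for part in label.split("+"))


def sort_labels(labels) -> list[str]:
    return sorted(labels, key=star_sort_key)


def format_diplotype(label_a: str, label_b: str) -> str:
    """Render an unordered allele pair in canonical order, e.g. ``*1/*2``."""
    a, b = sort_labels([label_a, label_b])
    return f"{a}/{b}"


# Function-class severity, most severe first. ``unknown`` ranks least severe:
# it never overrides an assayed class.
SEVERITY_ORDER = ("no_function", "decreased", "normal", "increased", "unknown")
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


def severity_rank(function_class: str) -> int:
    """0 = most severe (no_function). Unknown classes rank last."""
    return _SEVERITY_RANK.get(function_class, len(SEVERITY_ORDER))


def most_severe(classes) -> str:
    classes = list(classes)
    if not classes:
        raise ValueError("most_severe() of empty sequence")
    return min(classes, key=severity_rank)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used in all printed
    percentages), avoiding both banker's rounding and binary float-scaling
    artifacts: the value is rounded on its shortest decimal representation."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
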