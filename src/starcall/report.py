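"""Cohort aggregation and clinical-impact statistics.

Covers the descriptive outputs of a biobank-scale pharmacogenetic screen:
allele / diplotype / phenotype frequency tables, call-status rates
(single, composite, ambiguous, no-match), carrier percentages, comparison of
observed phenotype proportions against reference populations with a
one-proportion z-test (evaluated in log space so that p-values like 1e-155
are reported rather than underflowing to zero), the fraction of individuals
with at least one actionable (non-normal) phenotype, and drug-exposure impact
in DDD/1000 inhabitants/day (defined daily doses — the WHO drug-consumption
unit — weighted by the at-risk fraction).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import norm

from .phenotype import PhenotypeStatus
from .util import round_half_away

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# Frequency summaries


@dataclass
class GeneSummary:
    gene: str
    allele_counts: Counter = field(default_factory=Counter)
    status_counts: Counter = field(default_factory=Counter)  # haplotype level
    diplotype_counts: Counter = field(default_factory=Counter)
    phenotype_counts: Counter = field(default_factory=Counter)

    def frequencies(self, counts: Counter) -> dict:
        total = sum(counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in counts.items()}


@dataclass
class CohortSummary:
    n_samples: int
    genes: dict = field(default_factory=dict)  # gene -> GeneSummary

    def gene(self, name: str) -> GeneSummary:
        return self.genes.setdefault(name, GeneSummary(name))


def summarize_cohort(records: Iterable[tuple]) -> CohortSummary:
    """Aggregate per-sample records into cohort frequency tables.

    ``records`` yields ``(sample, gene, (call_a, call_b), phenotype_call)``
    tuples; the diplotype counted is the resolved pair when both haplotypes
    resolved, else the literal string ``"ambiguous"`` / ``"no_match"``.
    Sample order does not affect the result.
    """
    summary = CohortSummary(0)
    samples = set()
    for sample, gene, calls, pheno in records:
        samples.add(sample)
        gs = summary.gene(gene)
        labels = []
        for c in calls:
            gs.status_counts[c.status.value] += 1
            if c.resolved_label is not None:
                gs.allele_counts[c.resolved_label] += 1
                labels.append(c.resolved_label)
            else:
                gs.allele_counts[c.status.value] += 1
        if len(labels) == 2:
            from .util import format_diplotype

            gs.diplotype_counts[format_diplotype(*labels)] += 1
        else:
            statuses = sorted(c.status.value for c in calls if c.resolved_label is None)
            gs.diplotype_counts[statuses[0]] += 1
        if pheno is not None:
            if pheno.status is PhenotypeStatus.DETERMINATE:
                gs.phenotype_counts[pheno.phenotype] += 1
            else:
                gs.phenotype_counts["indeterminate"] += 1
    summary.n_samples = len(samples)
    return summary


# ---------------------------------------------------------------------------
# Carrier percentages and proportion tests


def carrier_percentage(k: int, n: int, decimals: int = 2) -> float:
    """Percentage of carriers, rounded half away from zero to ``decimals``."""
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    if not (0 <= k <= n):
        raise ValueError(f"carrier count {k} outside [0, {n}]")
    return round_half_away(100.0 * k / n, decimals)


@dataclass(frozen=True)
class ProportionTest:
    p_hat: float
    p0: float
    n: int
    z: float
    p_two_sided: float  # may be subnormal for extreme z; see log10_p
    log10_p: float

    def format_p(self, digits: int = 2) -> str:
        """Scientific-notation rendering straight from log space (never 0)."""
        exponent = math.floor(self.log10_p)
        mantissa = 10.0 ** (self.log10_p - exponent)
        return f"{round(mantissa, digits)}e{exponent:+03d}"


def one_proportion_ztest(p_hat: float, p0: float, n: int) -> ProportionTest:
    """Two-sided one-proportion z-test against reference proportion ``p0``.

    z = (p_hat - p0) / sqrt(p0 (1 - p0) / n). The two-sided tail probability
    is evaluated through the normal log-survival function, so extreme
    statistics (|z| well beyond 38) keep a finite log10 p-value.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"reference proportion must be in (0, 1), got {p0}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    se = math.sqrt(p0 * (1.0 - p0) / n)
    z = (p_hat - p0) / se
    log_p = math.log(2.0) + float(norm.logsf(abs(z)))
    log_p = min(log_p, 0.0)  # two-sided p capped at 1
    p = math.exp(log_p)
    return ProportionTest(p_hat, p0, n, z, p, log_p / _LN10)


# ---------------------------------------------------------------------------
# Actionable fraction and DDD impact


def actionable_fraction(phenotype_flags: Mapping[str, Iterable]) -> float:
    """Fraction of samples flagged high-risk for at least one gene.

    ``phenotype_flags`` maps sample id → iterable of per-gene risk flags
    (True / False / None, None meaning indeterminate). A sample counts as
    actionable iff any flag is True.
    """
    if not phenotype_flags:
        raise ValueError("actionable_fraction: empty cohort")
    hits = sum(
        1
        for flags in phenotype_flags.values()
        if any(bool(f) for f in flags if f is not None)
    )
    return hits / len(phenotype_flags)


@dataclass(frozen=True)
class DrugImpact:
    scope: str
    ddd_per_1000: float
    risk_fraction: float
    affected_ddd: float

    def __post_init__(self):
        if self.ddd_per_1000 < 0 or not (0.0 <= self.risk_fraction <= 1.0):
            raise ValueError("DDD and risk fraction must be non-negative (fraction <= 1)")


def ddd_impact(ddd_per_1000: float, risk_fraction: float, scope: str = "gene") -> DrugImpact:
    """Population drug exposure affected by actionable phenotypes."""
    return DrugImpact(scope, ddd_per_1000, risk_fraction, ddd_per_1000 * risk_fraction)


def portfolio_impact(impacts: Sequence[DrugImpact]) -> DrugImpact:
    """Sum per-drug affected exposure into one portfolio figure."""
    if not impacts:
        raise ValueError("portfolio_impact: no impacts")
    total_ddd = sum(i.ddd_per_1000 for i in impacts)
    total_affected = sum(i.affected_ddd for i in impacts)
    frac = total_affected / total_ddd if total_ddd > 0 else 0.0
    return DrugImpact("portfolio", total_ddd, frac, total_affected)
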