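# Methods

## Problem and model

A pharmacogene's clinically recognised haplotypes (star alleles) are defined
by sets of required variant states in an allele definition table; an
individual's unordered pair of star alleles (diplotype) determines a
metabolizer phenotype through a lookup table, and any phenotype other than
the gene's normal category calls for non-standard dosing of the linked
drugs. `starcall` implements this translation for phased, imputed cohort
genotypes, together with the cohort-level statistics used to quantify
population impact.

## Matching semantics and the resolution ladder

A non-structural allele matches a phased haplotype iff **every** required
variant state is observed on it. Missing data never satisfies a requirement;
this is the conservative choice — a call is only made from evidence — and it
is why calls carry two extra pieces of information:

- the **compatible set**: alleles whose requirements are merely not
  contradicted by any observed state. Ambiguity driven by missingness is
  therefore visible rather than silently resolved.
- a **wild-type disclaimer flag** on reference (\*1) calls made while one or
  more table variants were missing: such a call asserts "no known variant
  observed", not "no variant present".

The reference allele matches iff no alternate state is observed at any table
variant, so every haplotype either has a candidate or at least one observed
alternate state (no-match).

Resolution proceeds per haplotype:

1. **No-function first.** Only no-function alleles are tested; any full
   match resolves immediately. Ties are broken by the larger definition,
   then label collation — both documented and deterministic; the tie-break
   is configurable in principle but fixed here. A flag
   (`nonfunctional_semantics="compatible"`) switches this pass to
   compatibility matching under missingness; the default is full matching,
   which never calls a loss-of-function allele without observing its
   defining variants.
2. **Remaining alleles.** A single candidate resolves directly. With several
   candidates the ladder distinguishes:
   - **composite** — candidates with pairwise-disjoint alternate
     requirements whose union exactly explains the observed alternate
     states are reported as co-occurring alleles (`*2+*3`), with the most
     severe member function (severity order: no-function > decreased >
     normal > increased). The composite branch is evaluated *before* the
     decreased-over-normal override: a disjoint, fully explaining candidate
     set is physical co-occurrence, whereas the override exists for
     overlapping definitions that cannot all be true. With override-first,
     a normal+decreased composite would collapse to the decreased allele
     and leave observed variants unexplained.
   - **decreased-function override** — exactly one decreased-function
     candidate among otherwise normal-function ones resolves to the
     decreased allele.
   - otherwise **ambiguous**, with all candidates retained; downstream
     phenotyping stays determinate whenever all candidate diplotypes agree
     (the common situation for same-function ambiguities such as
     DPYD \*5/\*6/\*9).

Statuses partition outcomes; identical inputs always produce identical
calls.

## Genotype handling

Imputed genotypes are filtered at a posterior-probability threshold of 0.90
(strictly below is removed; the boundary is kept). "Probability" is the
posterior of the called genotype — the maximum of the GP vector; dosage- or
INFO-score-based filtering is out of scope. Directly genotyped records are
exempt from the filter, and when a site is both genotyped and imputed the
direct call wins. Origin is read from an `IMPUTED` INFO flag by default, or
from a configurable per-sample FORMAT tag; two-file input (separate
genotyped and imputed VCFs) is merged with the same preference. Coordinates
are 1-based GRCh37 without a `chr` prefix (a contig-alias map normalises
inputs); no strand flipping is attempted. Unphased heterozygotes are a hard
error when a sample has more than one heterozygous table site — phase then
matters — and are accepted otherwise.

## Curation

Definition tables ship in a simple TSV dialect (one allele row; variant
columns keyed `contig:pos:ref:alt[:rsid]`) rather than any spreadsheet
layout, which varies by download date. Curation directives are data, not
code: drop alleles (e.g. unknown-function alleles), merge proxy suballeles
(the merged allele keeps the states shared by all sources — the definition
compatible with the union of their carriers; tightening requirements would
defeat the purpose of collapsing proxies), drop a redundant proxy variant
from an allele (the complete-LD case where one variant suffices), and drop
structural alleles on platforms that cannot call copy number. After
curation, variant columns no longer required by any allele are pruned.
Re-applying a directive list is a no-op: the table remembers removed labels,
so already-applied directives are recognised while genuinely unknown targets
still raise errors.

## Copy-number integration

Whole-gene CNV calls are consumed, not discovered. A deletion replaces the
reference-labelled haplotype with \*5 when one is present — a deleted copy
cannot have contributed observed alternate states — and otherwise replaces
the less severe label and flags the record as inconsistent. A duplication
suffixes `xN` to the first of the sample's labels in the priority order
\*2 > \*1 > \*4 (configurable); if neither label is listed, the more severe
label is duplicated and the record flagged. Copy numbers above 3 are treated
as duplications with unannotated multiplicity. Requesting CNV integration on
a platform without copy-number support is a configuration error, matching
the curation rule that removes structural alleles there.

## Statistics

Percentages are rounded half away from zero at the printed precision,
computed on the shortest decimal representation to avoid binary float
artifacts. The one-proportion z-test uses
z = (p̂ − p₀)/√(p₀(1 − p₀)/n) with a two-sided tail probability evaluated
through the normal log-survival function; log₁₀ p is carried natively so
extreme comparisons render in scientific notation instead of underflowing.
No multiple-testing correction is applied; reported p-values are raw. The
actionable fraction is the share of samples with at least one determinate
non-normal phenotype across genes; indeterminate calls contribute no flag.
Drug impact multiplies exposure (DDD/1000 inhabitants/day; DDD = WHO defined
daily dose) by the at-risk fraction, summing per-drug products for a
portfolio.

## Synthetic cohorts

The generator emulates the input structure of a biobank screen: per-gene
tables, a phased VCF, CNV calls, phenotype maps, and a truth sidecar. Key
modelling choices:

- Haplotypes are drawn independently per chromosome from an
  allele-frequency vector (Hardy–Weinberg); real linkage structure is not
  modelled.
- Each generated non-reference allele owns a disjoint set of defining
  variants, so truth labels are identifiable from complete genotypes; real
  tables contain nested/overlapping definitions, which the caller handles
  (ambiguous status) but the generator's default truth avoids.
- Composite events overlay two non-no-function alleles on one chromosome
  (rate per haplotype); CYP2D6-like deletion/duplication events default to
  rates 0.0331 and 0.0079, the carrier rates observed in a 32,369-sample
  biobank cohort.
- Imputed sites carry GP posteriors from a two-component mixture:
  U(0.95, 1) normally, U(0.50, 0.899) with probability `gp_low_rate`
  (default 0.02) to exercise the strict 0.90 filter.
- Platform masks remove untyped positions from the VCF entirely; random
  missingness blanks individual genotypes.

Identical specs (same seed) produce byte-identical VCF, TSV and truth
output. Passing end-to-end tests on these cohorts demonstrates internal
consistency of the pipeline — not robustness to real-data features such as
LD, strand issues, or definition-table errata.

## Problem sizes and numerical choices

End-to-end recovery runs use n = 10,000 samples over three genes (a
CYP2C19-like gene with an increased-function allele, a CYP2D6-like gene with
CNVs, a CYP4F2-like gene with composites); the deletion-carrier measurement
uses n = 32,000 with a single CNV gene; the actionable-fraction measurement
draws per-gene Bernoulli risk flags for n = 42,092 samples at the eleven
published per-gene high-risk fractions. These sizes give binomial standard
errors well inside the tolerances being checked while keeping runs to
minutes on one CPU. The CYP4F2 composite per-haplotype rate is set to
1 − √(1 − 0.155) so the expected fraction of samples carrying at least one
composite chromosome is 15.5%.

The z-test evaluated at the published rounded proportions (30.8% vs 26.9%,
n = 42,092) yields p ≈ 8.8e-73 against a printed 1.64e-72 — input rounding
at three significant digits moves the answer within an order of magnitude at
this extremity, and more for the ultrarapid comparison (≈ 4.4e-154 vs
1.53e-155); both are reported as computed.

## Known limitations

- No phasing, imputation, liftover or reference-FASTA validation; phased
  input is trusted.
- Activity-score arithmetic is not implemented; function classes are the
  unit of severity.
- Composite (`*2+*3`), duplicated (`xN`) and deletion labels require
  explicit phenotype-map entries; absent entries yield indeterminate calls
  rather than a guess.
- Multiallelic CNVs beyond deletion/duplication are flagged and passed
  through, not assigned.
- The shipped curation-directive file illustrates the pruning categories
  with synthetic stand-ins; it is not a reproduction of any specific
  released table.
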