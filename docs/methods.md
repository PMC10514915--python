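# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Association model

Each variant is tested on an *allelic* 2×2 table — allele counts, not
genotype counts — with cases and controls as rows and ref/alt as columns.
Missing allele slots are excluded, never imputed. The allelic framing was
chosen over a genotypic or dominant coding because the downstream burden
statistic pools allele counts, and a single consistent unit keeps the two
stages directly comparable. No covariate adjustment, genomic control or
population-structure correction is attempted; the package targets small,
ethnically matched cohorts where an exact test on raw counts is the
operating assumption.

**Fisher's exact test.** One-sided p-values are hypergeometric tail sums.
The two-sided p-value uses the minimum-likelihood convention: the sum of
point probabilities no larger than the observed one. Because "no larger"
is numerically fragile at ties, the comparison uses a relative tolerance
of 1e-7 (`pmf_k <= pmf_obs * (1 + 1e-7)`), which makes the definition
reproducible across platforms and is verified in the test suite against
exhaustive enumeration in exact integer arithmetic (agreement to 1e-12 on
every table with margins ≤ 30). The pmf is evaluated over the whole
support via log-gamma rather than a frozen scipy distribution purely for
speed; accuracy is covered by the same enumeration check.

**Odds ratio.** The point estimate is the sample cross-product ratio
`(case_alt × control_ref) / (case_ref × control_alt)` with a Woolf
log-normal 95% interval `exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d))`.
A conditional-MLE odds ratio was deliberately not used: the published
tables this package mirrors print the cross-product ratio (verified on
all four rows to 6 decimals). With a zero cell the point estimate is
reported as 0 or infinity and the interval falls back to the
Haldane–Anscombe +0.5 correction, flagged in the output.

**Significance screen.** `p < 1e-7` and `OR > 1`, both strict; the p
threshold is an exome-wide Bonferroni-style cutoff and the OR condition
restricts to risk (not protective) direction.

## Filter cascades

Both cascades are pure row predicates over the annotation table, so the
surviving set is an intersection and is invariant to stage order; only the
per-stage accounting depends on order, and it is reported in the
conventional order (association/panel → impact → frequency). Decisions
that the annotation sources leave open:

- *Missing impact* rows are excluded by the impact filter (they cannot be
  shown to be MODERATE/HIGH) and counted in the log.
- *Missing population AF* is treated as 0 (a novel variant) and kept:
  variants absent from gnomAD/1000G are precisely the rare candidates the
  screen exists to find. They are flagged in the log.
- AF thresholds are strict (`< 0.01`); the AF columns are single scalar
  "total" frequencies, not sub-population values.
- Gene symbols match case-sensitively after whitespace trimming; no alias
  resolution is attempted.

## Prioritization

The vote asks whether at least half of the in-silico predictors call the
variant deleterious. The denominator is the number of *available*
(non-missing) calls with threshold `ceil(n_available / 2)`; a fixed /18
denominator is available by configuration but not default, because many
tools abstain on non-missense variants and a fixed denominator would
silently convert abstentions into benign votes. Uncertain calls count in
the denominator but never the numerator. Raw labels normalize through a
configurable table; two genuinely ambiguous mappings default as follows
and are reversible in `PrioritizerConfig`:

- Mutation Assessor "M" (medium) counts as deleterious. Published
  candidate rows carry "M" with no higher grade present, so the stricter
  "high only" reading would contradict the printed outcomes; both
  behaviours are supported.
- The bare "P" label maps to deleterious (probably damaging).

Loss-of-function consequences (stop-gain, frameshift, splice
acceptor/donor) bypass the vote entirely — the predictors are
missense-oriented and typically abstain — and the bypass is recorded in
the decision's reason trail. CADD must be strictly greater than 20
(missing CADD fails with an explicit reason). A clinical-significance
label excludes the variant only when it normalizes to `benign`;
uncertain and conflicting interpretations are retained, and no ACMG
re-classification is computed. Every decision carries an ordered list of
rule outcomes so the verdict is auditable; identical inputs and
configuration produce byte-identical decision tables.

## Gene-level burden

All called sites annotated to a gene — regardless of impact class,
synonymous sites included — contribute their ref/alt allele counts to one
pooled case-vs-control table; candidate-variant filters never apply here.
Sites annotated to several genes contribute to each. The test is the same
exact test as the association stage; correction is Bonferroni with factor
equal to the number of genes in the current scan (a small candidate list,
not the exome), and significance is called at α = 0.05 after correction.
The pooled odds ratio is a weighted aggregate across sites; under
per-site heterogeneity it approaches the per-site enrichment factor only
in the rare-allele regime (see the generator notes below).

## Over-representation

For a query of q genes against a term of K genes in a universe of N,
`expected = K·q/N`, `strength = log10(observed/expected)`, and the
p-value is the one-sided hypergeometric tail (enrichment only — depletion
is meaningless for a 12-gene query). N defaults to 19,566, the human
protein universe of the annotation server whose printed strengths this
module reproduces; the value was recovered by checking that all five
published (observed, background) pairs yield the printed 2-decimal
strengths at that N, and it is configurable. FDR is Benjamini–Hochberg
(via statsmodels) within each annotation category independently, matching
the per-category term counts such servers report; a single global family
is available by flag. Published FDR values cannot be reproduced without
the full unprinted term universe, so only strengths are compared.
With zero overlap the strength is undefined (reported missing) and p = 1.

## Truncation reports

A stop-gain at CDS position c puts the termination codon at amino-acid
index `ceil(c/3)`; the stop codon itself carries that index, so the
translated peptide has `ceil(c/3) − 1` residues. Domains are classified
by interval comparison: *lost* when starting at or after the stop,
*partially lost* when spanning it, *retained* otherwise — the three lists
partition the domain table. Whether the transcript escapes
nonsense-mediated decay is not adjudicated (no 50-nt rule); the report
carries a note stating both outcomes are possible. Domain coordinates are
user-supplied; nothing is fetched from UniProt or Pfam.

## Synthetic cohorts

The generator emulates the study conditions every stage assumes: 20 cases
and 100 controls; per-site control alt-allele probabilities drawn from a
rare-skewed Beta(0.5, 20) spectrum (mean ≈ 0.024 — an exome-like site
frequency distribution that also keeps the pooled odds ratio of a 2-fold
risk factor near 2, since OR ≈ r·(1−p̄)/(1−r·p̄) inflates away from r as
sites become common); case probabilities `min(1, r·p)` for genes with
enrichment r; diploid genotypes binomial per sample; 80 sites per gene by
default (pooled allele totals of the published burden genes imply ~70–90
called sites each); impact mix HIGH 0.02 / MODERATE 0.48 / LOW 0.30 /
MODIFIER 0.20; per-slot genotype missingness 1%.

Annotations are emitted per site: population AFs track the true site
frequency with 5% relative jitter; predictor labels agree with a latent
pathogenicity indicator with probability q = 0.9 per tool (5% abstention),
emitting a concrete raw label from each tool's vocabulary; CADD is drawn
from class-conditional truncated normals — pathogenic N(27, 3) on
[20.5, 45] (the CADD-20 threshold is the top-1% deleteriousness band, and
curated candidate variants typically score in the mid-20s to 30s) and
benign N(8, 5) on [0, 19.5]. Planted candidates are *designed to pass*
the cascade: in-panel, MODERATE/HIGH, rare in both references, pathogenic
CADD, and (for missense) predictor calls drawn conditional on the vote
passing via rejection sampling inside the single seeded stream. Their
genotypes are deterministic heterozygous case carriers (13 candidates
concentrated in 11 of the 20 cases by default).

In the candidate-recovery scenario, non-planted panel-gene sites draw
from a common-variant Beta(5, 45) spectrum with a benign latent class, so
the planted candidates are the only rare MODERATE/HIGH panel variation
and the recovery ground truth is unambiguous for any seed.

One `numpy.random.Generator` stream is seeded from the single config
seed; the draw order (site frequencies → genotypes → annotations) is
fixed so the scenario remains reproducible byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and haplotype structure,
relatedness and population stratification, sequencing error and
coverage-dependent genotype quality, correlated errors between predictors
(tools are conditionally independent given the latent class here, which
overstates the information in a real 18-tool panel), annotation-version
drift, and multi-gene overlapping transcripts.

## Problem sizes in tests and acceptance

The enumeration scan covers all ~164,000 tables with margins ≤ 30. The
recovery study uses 200 replicate cohorts (20/100 samples, one gene of 60
rare sites, r = 2) and checks median pooled OR in [1.8, 2.2] and ≥ 90%
Woolf-interval coverage of the per-replicate truth; the matched null
study (r = 1) checks the α = 0.05 rejection rate within a ~99%
Monte-Carlo band. The pooled null table is a sum over heterogeneous
sites, which slightly under-disperses relative to the test's binomial
assumption, so rejection rates a little below nominal are expected and
observed.

## Known limitations

- Burden p-values for very large pooled tables are exact-test values;
  published analogues may have used approximations, so p-values are
  reported but only odds ratios are compared to printed tables.
- The annotation join is exact string match on (chrom, pos, ref, alt)
  after alt splitting; no normalization of indel representation.
- The CLI consumes GT only; depth/quality fields are ignored by design.
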