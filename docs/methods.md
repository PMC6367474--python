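# Methods

## Setting

A naive B-cell repertoire is a set of V(D)J rearrangements, each transcribed
from one of the two IGH chromosomes and annotated with V/D/J gene and allele
calls. Because the three genes of one rearrangement come from the same
chromosome, co-occurrence statistics across a deep repertoire carry
chromosomal phase information. `ighap` consumes annotated AIRR Rearrangement
TSVs (or Change-O tables via a column map) and never touches reads or
alignments; mutation counts are required input columns, and their absence
disables the mutation filters with a warning.

## Record filtration

Inference-grade records must look germline and unambiguous: at most 3 V
mutations, 0 D mutations, and exactly one V, D and J assignment. Subjects
with fewer than 2,000 retained records are flagged as failing depth QC.
Before that, gene filtration removes ORF and pseudogene calls, drops
IGHV1-69D (indistinguishable from IGHV1-69 for most alleles) and IGHV4-30-1
(no reliable reference), and collapses the sequence-identical pairs
IGHD4-4→IGHD4-11 and IGHD5-5→IGHD5-18. Each retained row counts as one
recombination event; `duplicate_count` is deliberately ignored, since UMI
collapse upstream already removed PCR duplicates and clonal expansion is
minimal in naive cells.

## Haplotype model

Let an anchor gene be heterozygous with allele groups A and B and let
p ∈ (0, 1) be the group-A share of anchor-bearing records. For a target
allele with co-occurrence counts X = (n1, n2), three models are scored with a
binomial likelihood at point hypotheses, where ε is a constant probability
that a record's allele is mis-assigned to the homologous chromosome's allele:

- chrA-only: θ = (1+ε, ε)/(1+2ε)
- chrB-only: θ = (ε, 1+ε)/(1+2ε)
- both:      θ = (p+ε, 1−p+ε)/(1+2ε)

Posterior weight of model m ∝ prior_m · Binomial(n1; n1+n2, θ_m[0]); the
Bayes factor K between the two best models gives the certainty lK = log₁₀ K.
Computation is in log space so ε = 0 is exact (impossible models get −∞);
lK is capped at 300 for reporting (configurable), which also covers a
second-best model of weight exactly zero.

We keep p as the group-A share rather than relabelling groups so that the
label-symmetry property holds exactly: swapping groups A↔B swaps chromosome
columns at identical lK. The likelihood is invariant under the simultaneous
swap (n1, n2, p) → (n2, n1, 1−p), so this is the same model as the
dominant-allele parameterization.

Model priors default to uniform (1/3 each); an `empirical` mode sets the
both-chromosomes prior to the subject-wide fraction of genes with two
observed alleles. The empirical fit used in the original analysis is not
recoverable from its description, so the explicit, reproducible default is
uniform.

### Gene-level calls

Per allele, the best model assigns it to chrA, chrB or both when
lK ≥ `lk_assign` (default 3, i.e. Bayes factor 1000); weaker alleles are
`unknown`. For a chromosome carrying no confidently assigned allele, if every
observed allele of the gene *leans* toward the other chromosome (its
chromosome-only likelihoods favor the other side), the chromosome is called
`deleted` when all those alleles' best models are the other chromosome at
lK > `lk_delete` (default 3), and `suspected_deleted` otherwise. The leaning
criterion matters: with small counts such as (4, 1) the best model is "both"
at low certainty, yet the evidence direction is clear, and this configuration
is reported as a suspected (not confirmed) deletion. Genes never observed
yield NA rows.

### Pooled V anchors (V_pooled)

For D-gene deletions in J6-homozygous subjects, per-anchor evidence is weak
(each heterozygous V gene captures only a few percent of the repertoire), but
the binomial/beta conjugacy lets the posterior of one anchor serve as the
prior of the next. Updates are products, so the result is exactly invariant
to anchor order, and under uniform priors with a consistent best/second model
ranking the pooled lK is the sum of per-anchor lKs.

Chromosome labels are private to each anchor, so before each update the
anchor's contingency is oriented so dominant D alleles share a chromosome:
each gene's most-counted allele votes for an orientation, votes are counted
only when that allele's best model is a chromosome-only one (balanced
both-chromosome alleles carry no signal), and the majority wins. A per-anchor
orientation-consistency score (fraction of votes agreeing with the majority)
is reported rather than any rejection rule, since contradictory orientations
("allele mix") cannot be adjudicated from a single subject. Anchors must pass
the 30% minor-allele screen; D genes under 1.5% usage are excluded; the
deletion cutoff is lK = 12, trading sensitivity for precision against
orientation errors.

## Cohort deletion test

For each gene, subjects with relative usage below the candidate threshold
(0.001 for V; 0.005 for D, whose assignments are less reliable) are tested
with the one-sided binomial tail P(X ≤ x | N, p), where N is the subject's
locus total and the null p is the minimum usage among non-candidate subjects
above a 0.001 floor (applied to both loci; configurable — the D-locus floor
is ambiguous and 0.005 is also supported). Benjamini–Hochberg correction runs
within gene across candidate subjects; q < 0.01 calls the deletion. Genes
below the candidate threshold in >90% of subjects are uninformative (NA), as
is a gene with no non-candidate subject. A gamma-mixture bimodality check
(MLE fits on either side of 0.001; reliable only with ≥3 subjects per side
and a ≥5× mean separation) flags genes whose deletions rest on a unimodal
usage distribution.

## Population statistics

**Sign test.** For each heterozygous allele pair, k of n subjects (depth
>10,000, gene usage ≥1%, ties at 0.5 dropped) have the first allele above
half; the exact two-sided p-value is min(1, 2·min(P(X≤k), P(X≥k))) at
p = 0.5, BH-corrected across pairs. Pairs in fewer than 5 subjects are
reported untested. Two-sided because bias in either direction is of interest.

**Single-deletion thresholds.** Subjects split per gene into 0- vs
1-deletion groups by haplotype calls at lK ≥ 10 (a conservative certainty
floor). Each group's usage is modelled as x ~ μ + σ·t(ν = n−1); a deletion is
called below threshold, so the threshold at FPR α is μ₀ + σ₀·t_ν₀(α), with
model-based sensitivity P(X₁ < t). The ROC sweeps 1,000 evenly spaced
thresholds plus both α-quantiles. Groups need n ≥ 2; σ ≈ 0 fits are skipped
as degenerate.

**Usage ratio CI.** Fieller's theorem for the ratio of two independent group
means with Satterthwaite (Welch) degrees of freedom evaluated at the point
estimate; an unbounded interval (denominator not significantly nonzero) is
reported as NaN limits.

**Jaccard comparison.** Per shared chromosome-resolved gene, distance =
1 − |a∩b|/|a∪b| over chromosome-tagged allele assignments; a deleted
chromosome contributes an empty set, unresolved genes (`unknown`/`NA`/
suspected) are excluded, as are genes with fewer than 5 linking sequences;
the overall distance is the mean over genes, requiring ≥5 comparable genes.
Since chromosome labels from different anchors are arbitrary, the orientation
(identity or global flip) minimizing the mean distance is used — without this
step two identical haplotypes could score 1.0 by label swap alone. The
linkage floor is applied per gene (total anchored counts), with the
per-allele variant available via configuration.

**Anchor screening.** A gene anchors a subject when heterozygous with minor
allele fraction >30%; a Wilcoxon rank-sum test comparing cross-anchor Jaccard
distances above vs below the cutoff is reported (NA under 3 observations per
side).

## Synthetic repertoires

The generator draws a diploid genome — per-gene alleles, heterozygosity,
linked deletion blocks with mutually exclusive alternatives (default:
{V1-8, V3-9} vs {V5-10-1, V3-64D}) — then emits rearrangements by choosing a
chromosome (default 0.5), drawing V, D, J genes independently from that
chromosome's surviving genes by usage weight, and swapping an emitted allele
to the homolog's allele with probability ε. This is exactly the
mis-assignment process the θ hypotheses model, which is the point: recovery
tests validate the inference under its own assumptions. Defaults: ε = 0.005,
10,000 sequences, V/D usage weights log-normal (σ = 1, normalized per locus,
giving a realistic spread with a few dominant genes), and a fixed J
distribution (J4 0.45, J6 0.31, J3 0.10, J5 0.08, J2 0.04, J1 0.02) — human J
usage is stable across individuals and J6's large share is what makes
J6-anchored phasing practical. Per-gene allele bias is available as the
probability a rearrangement of that gene originates from chromosome A.

What the simulator does **not** emulate: somatic hypermutation, clonal
structure, V–D–J pairing biases, sequencing depth heterogeneity within a
subject, multi-gene ambiguous calls, and annotation errors beyond the
symmetric ε swap. Passing recovery tests therefore demonstrate correctness of
the inference machinery under the stated generative model, not robustness to
real-data annotation pathology.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 1,000 random tuples for
the Bayes-factor oracle check (independent lgamma-based pmf evaluation,
agreement to 1e-9 relative); 20 subjects × 10,000 sequences at ε = 0.005 for
single-chromosome deletion recovery (evaluated on genes with usage ≥1%);
100 cohorts × 50 subjects × 5,000 sequences with 10 engineered
two-chromosome deletions each (cohort counts drawn multinomially with
gamma-distributed subject noise, CV ≈ 18%) for the binomial-test calibration;
200 random chains for pooled additivity; 100 replicates of n = 20 groups at
σ/μ = 0.2 and true ratio 2 for the Fieller CI and threshold FPR; and
20 replicates × 50,000 sequences for cross-anchor (J6 vs a D2-21-like
heterozygous D anchor at 10% usage) haplotype agreement. These sizes give
stable pass/fail behaviour across seeds while keeping a full run in the
low tens of seconds.

## Known limitations

- Genotype certainty levels from upstream Bayesian genotyping are consumed,
  not reproduced; zygosity is summarized by allele frequency alone.
- The D-locus null floor ambiguity (0.001 vs 0.005) is resolved by default to
  0.001 and exposed as configuration.
- Pooled inference addresses single-chromosome D deletions only;
  two-chromosome deletions belong to the cohort binomial test.
- Anchors with more than two alleles require user-specified allele groups
  (e.g. grouping \*04 with \*02 against \*03).
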