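"""Bayesian haplotype inference anchored on a heterozygous gene.

A heterozygous anchor gene (classically IGHJ6 with alleles *02/*03) labels
the two chromosomes: every rearrangement carrying anchor allele group A came
from chromosome A, up to a constant allele mis-assignment probability ε.
For each target allele we count its co-occurrences with the two anchor
groups, X = (n1, n2), and compare three generative models by their binomial
likelihood at point hypotheses:

* chrA only:  θ = (1+ε, ε) / (1+2ε)
* chrB only:  θ = (ε, 1+ε) / (1+2ε)
* both:       θ = (p+ε, 1−p+ε) / (1+2ε),  p = anchor group-A fraction

The posterior weight of model m is prior_m × Binomial(n1; n1+n2, θ_m[0]).
Certainty is the Bayes factor K between the best and second-best model,
reported as lK = log10 K.  Alleles are assigned to chromosomes when
lK ≥ lk_assign; a chromosome carrying none of a gene's observed alleles is
called deleted when every allele sits confidently (lK > lk_delete) on the
other chromosome, and suspected_deleted when the same configuration holds
with weaker evidence.

All computation is in log space so ε = 0 (exact co-segregation) is handled;
infinite Bayes factors are capped at a configurable lK for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .airr_io import DELETED_TOKEN, HAPLOTYPE_COLUMNS
from .prep import LOCUS_CALL, _allele_of, _gene_of

MODELS = ("chrA", "chrB", "both")


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor gene with its two allele groups labelling the chromosomes.

    ``p`` is the fraction of anchor-bearing records carrying a group-A allele
    (estimated by :func:`build_contingency` when None).  Groups must be
    disjoint and non-empty; more than one allele per group supports subjects
    such as a J6 *03/*04 heterozygote grouped as {02,04} vs {03}.
    """

    gene: str
    group_a: frozenset
    group_b: frozenset
    p: float | None = None

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError("anchor allele groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError("anchor allele groups must be disjoint")

    @classmethod
    def from_spec(cls, gene: str, spec: str) -> "AnchorConfig":
        """Parse "02:03" or "02,04:03" into an AnchorConfig."""
        a, _, b = spec.partition(":")
        return cls(
            gene=gene,
            group_a=frozenset(x.strip() for x in a.split(",") if x.strip()),
            group_b=frozenset(x.strip() for x in b.split(",") if x.strip()),
        )


@dataclass(frozen=True)
class ModelHypotheses:
    """Point hypotheses θ and model priors for the three-way comparison."""

    epsilon: float = 0.01
    p: float = 0.5
    priors: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if abs(sum(self.priors)) <= 0 or any(w < 0 for w in self.priors):
            raise ValueError("priors must be non-negative and not all zero")

    def theta1(self) -> np.ndarray:
        """First component of θ for (chrA, chrB, both)."""
        e, p = self.epsilon, self.p
        return np.array([(1 + e) / (1 + 2 * e), e / (1 + 2 * e), (p + e) / (1 + 2 * e)])


@dataclass
class HaplotypeParams:
    """Tunable knobs of the inference (defaults follow the standard analysis)."""

    epsilon: float = 0.01
    lk_assign: float = 3.0
    lk_delete: float = 3.0
    priors: str | tuple = "uniform"  # "uniform" | "empirical" | explicit 3-tuple
    lk_cap: float = 300.0


def log_model_weights(n1: int, n2: int, hyp: ModelHypotheses) -> np.ndarray:
    """Unnormalized log posterior weight of each model (−inf where impossible)."""
    n = n1 + n2
    if n < 1:
        raise ValueError("need at least one observation (n1 + n2 >= 1)")
    theta1 = hyp.theta1()
    with np.errstate(divide="ignore"):
        loglik = stats.binom.logpmf(n1, n, theta1)
        logprior = np.log(np.asarray(hyp.priors, dtype=float))
    return logprior + loglik


def score_models(
    n1: int, n2: int, hyp: ModelHypotheses, lk_cap: float = 300.0
) -> tuple[str, str, float]:
    """Rank the three models; return (best, second, lK).

    lK = log10 of the posterior-weight ratio between the two top models,
    capped at ``lk_cap`` (the cap also covers a second-best model of weight
    exactly zero, which occurs with ε = 0 and contradictory counts).
    """
    logw = log_model_weights(n1, n2, hyp)
    order = np.argsort(logw)[::-1]
    best, second = MODELS[order[0]], MODELS[order[1]]
    if np.isinf(logw[order[0]]) and logw[order[0]] < 0:
        # all models impossible: only reachable with zero priors, guarded above
        return best, second, 0.0
    if np.isinf(logw[order[1]]):
        return best, second, float(lk_cap)
    lk = (logw[order[0]] - logw[order[1]]) / np.log(10)
    return best, second, float(min(lk, lk_cap))


# ---------------------------------------------------------------------------
# Contingency construction

@dataclass
class ContingencyResult:
    rows: pd.DataFrame  # gene, allele, n1, n2
    p: float  # anchor group-A fraction after clamping
    excluded_anchor_alleles: int


def build_contingency(
    records: pd.DataFrame, anchor: AnchorConfig, target_locus: str
) -> ContingencyResult:
    """Anchor-conditioned co-occurrence counts for every target (gene, allele).

    Records must be filtered to single assignments.  Each record whose anchor
    allele belongs to group A or B contributes one count to its target allele
    row; records with anchor alleles outside both groups are excluded and
    counted.  p is the group-A share of anchor-bearing records, clamped away
    from {0, 1}.
    """
    anchor_locus = anchor.gene[:4]
    anchor_col = LOCUS_CALL[anchor_locus]
    target_col = LOCUS_CALL[target_locus]

    a_gene = _gene_of(records[anchor_col])
    mask = a_gene == anchor.gene
    if not mask.any():
        raise ValueError(f"anchor gene {anchor.gene} absent from records")
    sub = records[mask]
    a_allele = _allele_of(sub[anchor_col])
    in_a = a_allele.isin(anchor.group_a)
    in_b = a_allele.isin(anchor.group_b)
    excluded = int((~(in_a | in_b)).sum())
    sub = sub[(in_a | in_b) & sub[target_col].notna()]
    grp = np.where(a_allele.loc[sub.index].isin(anchor.group_a), "n1", "n2")

    na, nb = int((grp == "n1").sum()), int((grp == "n2").sum())
    if na + nb == 0:
        raise ValueError("no records carry an anchor-group allele")
    p = na / (na + nb)
    p = float(np.clip(p, 1e-6, 1 - 1e-6))

    tab = pd.DataFrame(
        {
            "gene": _gene_of(sub[target_col]).values,
            "allele": _allele_of(sub[target_col]).fillna("").values,
            "grp": grp,
        }
    )
    counts = (
        tab.groupby(["gene", "allele", "grp"], as_index=False)
        .size()
        .pivot_table(index=["gene", "allele"], columns="grp", values="size", fill_value=0)
        .reindex(columns=["n1", "n2"], fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    counts[["n1", "n2"]] = counts[["n1", "n2"]].astype(int)
    return ContingencyResult(rows=counts, p=p, excluded_anchor_alleles=excluded)


# ---------------------------------------------------------------------------
# Gene-level calls

@dataclass
class HaplotypeCall:
    """Chromosome assignment of one gene's alleles relative to the anchor."""

    gene: str
    alleles_chrA: list = field(default_factory=list)  # (allele, lK)
    alleles_chrB: list = field(default_factory=list)
    state_chrA: str = "unknown"  # alleles | deleted | suspected_deleted | unknown | NA
    state_chrB: str = "unknown"
    counts_chrA: int = 0
    counts_chrB: int = 0
    lK: float = 0.0  # certainty of the weakest decision backing the call
    call_state: str = "unknown"


def call_gene_haplotype(
    rows: pd.DataFrame,
    hyp: ModelHypotheses,
    lk_assign: float = 3.0,
    lk_delete: float = 3.0,
    lk_cap: float = 300.0,
) -> HaplotypeCall:
    """Combine per-allele model scores into a gene-level chromosome call."""
    gene = rows["gene"].iloc[0]
    call = HaplotypeCall(gene=gene)
    scored = []
    for _, r in rows.iterrows():
        n1, n2 = int(r["n1"]), int(r["n2"])
        best, second, lk = score_models(n1, n2, hyp, lk_cap)
        logw = log_model_weights(n1, n2, hyp)
        # which single-chromosome model the counts lean toward (None on a tie)
        if logw[0] > logw[1]:
            lean = "chrA"
        elif logw[1] > logw[0]:
            lean = "chrB"
        else:
            lean = None
        scored.append((r["allele"], n1, n2, best, lk, lean))
    call.counts_chrA = sum(s[1] for s in scored)
    call.counts_chrB = sum(s[2] for s in scored)

    for allele, _, _, best, lk, _ in scored:
        if lk < lk_assign:
            continue
        if best in ("chrA", "both"):
            call.alleles_chrA.append((allele, lk))
        if best in ("chrB", "both"):
            call.alleles_chrB.append((allele, lk))

    lks = []
    for chrom, occupants, other in (
        ("A", call.alleles_chrA, "chrB"),
        ("B", call.alleles_chrB, "chrA"),
    ):
        if occupants:
            state = ",".join(a for a, _ in sorted(occupants))
            lks.extend(lk for _, lk in occupants)
        else:
            # nothing confidently occupies this chromosome: a deletion call
            # needs every observed allele leaning toward the other one
            away = [s for s in scored if s[5] == other]
            if len(away) == len(scored) and scored:
                confident = all(s[3] == other and s[4] > lk_delete for s in away)
                min_lk = min(s[4] for s in away)
                state = DELETED_TOKEN if confident else "suspected_" + DELETED_TOKEN
                lks.append(min_lk)
            else:
                state = "unknown"
        if chrom == "A":
            call.state_chrA = state
        else:
            call.state_chrB = state

    call.lK = float(min(lks)) if lks else 0.0
    del_states = []
    for chrom, state in (("chrA", call.state_chrA), ("chrB", call.state_chrB)):
        if state == DELETED_TOKEN:
            del_states.append(f"deleted_{chrom}")
        elif state == "suspected_" + DELETED_TOKEN:
            del_states.append(f"suspected_deleted_{chrom}")
    if del_states:
        call.call_state = ";".join(del_states)
    elif call.alleles_chrA or call.alleles_chrB:
        call.call_state = "assigned"
    else:
        call.call_state = "unknown"
    return call


def _effective_hypotheses(records, anchor_p, params: HaplotypeParams, rows_by_gene):
    if params.priors == "uniform":
        priors = (1 / 3, 1 / 3, 1 / 3)
    elif params.priors == "empirical":
        n_genes = len(rows_by_gene)
        n_het = sum(len(g) > 1 for g in rows_by_gene.values())
        both = min(max(n_het / n_genes if n_genes else 1 / 3, 1e-3), 1 - 1e-3)
        priors = ((1 - both) / 2, (1 - both) / 2, both)
    else:
        priors = tuple(params.priors)
    return ModelHypotheses(epsilon=params.epsilon, p=anchor_p, priors=priors)


def infer_haplotype(
    records: pd.DataFrame,
    anchor: AnchorConfig,
    params: HaplotypeParams | None = None,
    target_locus: str = "IGHV",
    all_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene haplotype table for one subject (airr_io dialect).

    ``all_genes`` optionally lists every gene of the target locus; genes never
    observed then yield NA rows.  Deterministic given inputs.
    """
    params = params or HaplotypeParams()
    subjects = records["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("infer_haplotype expects records of a single subject")
    subject = subjects[0]

    cont = build_contingency(records, anchor, target_locus)
    rows_by_gene = {g: sub for g, sub in cont.rows.groupby("gene")}
    hyp = _effective_hypotheses(records, cont.p, params, rows_by_gene)

    out = []
    genes = sorted(rows_by_gene)
    for gene in genes:
        call = call_gene_haplotype(
            rows_by_gene[gene], hyp, params.lk_assign, params.lk_delete, params.lk_cap
        )
        out.append(
            {
                "subject": subject,
                "gene": gene,
                "alleles_chrA": call.state_chrA,
                "alleles_chrB": call.state_chrB,
                "counts_chrA": call.counts_chrA,
                "counts_chrB": call.counts_chrB,
                "lK": call.lK,
                "call_state": call.call_state,
            }
        )
    if all_genes:
        for gene in all_genes:
            if gene not in rows_by_gene:
                out.append(
                    {
                        "subject": subject,
                        "gene": gene,
                        "alleles_chrA": "NA",
                        "alleles_chrB": "NA",
                        "counts_chrA": 0,
                        "counts_chrB": 0,
                        "lK": 0.0,
                        "call_state": "NA",
                    }
                )
    df = pd.DataFrame(out, columns=HAPLOTYPE_COLUMNS)
    return df.sort_values("gene").reset_index(drop=True)
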