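"""Cohort-level statistics on genotypes, usage and haplotypes.

Covers the population analyses layered on top of per-subject inference:

* a single-sample sign test for biased usage between the two alleles of a
  heterozygous gene (a special case of the binomial test at p = 0.5);
* per-gene usage thresholds separating subjects with zero vs one chromosomal
  deletion, from location-scale t fits and a model-based ROC;
* Fieller confidence intervals for the ratio of group mean usages (the
  "deleted genes are expressed at half the rate" check);
* Jaccard distances between haplotypes inferred from different anchor genes,
  and the 30% minor-allele screen for anchor candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .airr_io import DELETED_TOKEN
from .prep import UsageTable


# ---------------------------------------------------------------------------
# Sign test

def sign_test_pvalue(k: int, n: int) -> float:
    """Exact two-sided binomial sign test at p = 0.5 (closed form)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2 * min(lower, upper)))


def allele_bias_sign_test(
    usage: UsageTable,
    genotypes: pd.DataFrame,
    min_depth: int = 10_000,
    min_gene_usage: float = 0.01,
    min_individuals: int = 5,
) -> pd.DataFrame:
    """Test each heterozygous allele pair for biased usage across subjects.

    For every (gene, allele pair) carried by enough deeply sequenced subjects,
    count in how many the first allele (alphabetically) exceeds half of the
    gene's sequences; ties at exactly 0.5 are dropped.  Exact two-sided
    binomial p-values at 0.5 are BH-corrected across tested pairs.  Pairs
    observed in fewer than ``min_individuals`` subjects are reported untested.
    """
    depth = usage.locus_totals("IGHV")
    gene_frac = usage.gene_usage.set_index(["subject", "gene"])["fraction"]
    allele_frac = usage.allele_usage.set_index(["subject", "gene", "allele"])["fraction"]

    het = genotypes[genotypes["zygosity"] == "heterozygous"]
    counters: dict[tuple, list[int]] = {}  # (gene, a1, a2) -> [n, k]
    for _, row in het.iterrows():
        subj, gene = row["subject"], row["gene"]
        if depth.get(subj, 0) < min_depth:
            continue
        if gene_frac.get((subj, gene), 0.0) < min_gene_usage:
            continue
        alleles = sorted(row["alleles"].split(","))[:2]
        if len(alleles) < 2:
            continue
        a1, a2 = alleles[0], alleles[1]
        f1 = allele_frac.get((subj, gene, a1), 0.0)
        f2 = allele_frac.get((subj, gene, a2), 0.0)
        pair_total = f1 + f2
        if pair_total == 0:
            continue
        share = f1 / pair_total
        if share == 0.5:  # tie: excluded from n
            continue
        n_k = counters.setdefault((gene, a1, a2), [0, 0])
        n_k[0] += 1
        n_k[1] += int(share > 0.5)

    rows = []
    for (gene, a1, a2), (n, k) in sorted(counters.items()):
        tested = n >= min_individuals
        rows.append(
            {
                "gene": gene,
                "allele_pair": f"{a1}/{a2}",
                "n": n,
                "k": k,
                "tested": tested,
                "p_value": sign_test_pvalue(k, n) if tested else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q_value=pd.Series(dtype=float))
    df["q_value"] = np.nan
    mask = df["tested"]
    if mask.any():
        df.loc[mask, "q_value"] = multipletests(df.loc[mask, "p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Single-chromosome deletion usage thresholds

def _deletion_group(state_a: str, state_b: str, call_state: str) -> int | None:
    """0 = present on both chromosomes, 1 = single-chromosome deletion."""
    deleted = sum(s == DELETED_TOKEN for s in (state_a, state_b))
    if deleted == 1:
        return 1
    if deleted == 0 and call_state == "assigned":
        informative = {"unknown", "NA", "suspected_" + DELETED_TOKEN}
        if state_a not in informative and state_b not in informative:
            return 0
    return None


def estimate_single_deletion_thresholds(
    usage: UsageTable,
    haplotype_calls: pd.DataFrame,
    locus: str = "IGHD",
    min_lk: float = 10.0,
    alphas=(0.01, 0.05),
    min_group: int = 2,
    roc_points: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Usage thresholds calling single-chromosome deletions at fixed FPR.

    Subjects are split per gene into the 0-deletion and 1-deletion groups
    using haplotype calls at certainty lK ≥ ``min_lk``.  Each group's usage is
    modelled as x ~ μ + σ·t(ν = n−1); a deletion is called when usage falls
    below the threshold, so the FPR at threshold t is P(X₀ < t) and the
    threshold for FPR = α is μ₀ + σ₀·t_ν₀(α).  Returns one row per (gene, α)
    plus a per-gene model-based ROC; genes with fewer than ``min_group``
    subjects in either group, or a degenerate (σ = 0) fit, are skipped with a
    reason row.
    """
    frac = usage.fraction_matrix(locus)
    calls = haplotype_calls[haplotype_calls["lK"] >= min_lk]
    groups: dict[str, dict[int, list[float]]] = {}
    for _, r in calls.iterrows():
        g = _deletion_group(str(r["alleles_chrA"]), str(r["alleles_chrB"]), str(r["call_state"]))
        if g is None:
            continue
        subj, gene = r["subject"], r["gene"]
        if subj in frac.index and gene in frac.columns:
            groups.setdefault(gene, {0: [], 1: []})[g].append(float(frac.at[subj, gene]))

    rows, rocs = [], {}
    for gene, grp in sorted(groups.items()):
        x0, x1 = np.asarray(grp[0]), np.asarray(grp[1])
        if len(x0) < min_group or len(x1) < min_group:
            rows.append({"gene": gene, "alpha": np.nan, "skipped": "insufficient_group"})
            continue
        mu0, sd0 = x0.mean(), x0.std(ddof=1)
        mu1, sd1 = x1.mean(), x1.std(ddof=1)
        if sd0 <= 1e-12 * max(abs(mu0), 1e-12) or sd1 <= 1e-12 * max(abs(mu1), 1e-12):
            rows.append({"gene": gene, "alpha": np.nan, "skipped": "degenerate_fit"})
            continue
        nu0, nu1 = len(x0) - 1, len(x1) - 1
        ratio, lo, hi = mean_ratio_ci(x0, x1)
        sweep = np.linspace(min(x0.min(), x1.min()), max(x0.max(), x1.max()), roc_points)
        thr_alpha = {a: mu0 + sd0 * stats.t.ppf(a, nu0) for a in alphas}
        sweep = np.sort(np.concatenate([sweep, list(thr_alpha.values())]))
        fpr = stats.t.cdf((sweep - mu0) / sd0, nu0)
        tpr = stats.t.cdf((sweep - mu1) / sd1, nu1)
        rocs[gene] = pd.DataFrame({"threshold": sweep, "fpr": fpr, "tpr": tpr})
        for a in alphas:
            t_a = thr_alpha[a]
            rows.append(
                {
                    "gene": gene,
                    "alpha": a,
                    "n0": len(x0),
                    "mu0": mu0,
                    "sd0": sd0,
                    "n1": len(x1),
                    "mu1": mu1,
                    "sd1": sd1,
                    "threshold": t_a,
                    "sensitivity": float(stats.t.cdf((t_a - mu1) / sd1, nu1)),
                    "ratio": ratio,
                    "ci_low": lo,
                    "ci_high": hi,
                    "skipped": "",
                }
            )
    return pd.DataFrame(rows), rocs


def mean_ratio_ci(group0, group1, conf: float = 0.95) -> tuple[float, float, float]:
    """Fieller CI for the ratio of two independent group means (Welch df).

    Returns (point estimate mean₀/mean₁, lower, upper).  When the denominator
    mean is not significantly different from zero the interval is unbounded
    and (nan, nan) is returned for the limits.
    """
    x0, x1 = np.asarray(group0, dtype=float), np.asarray(group1, dtype=float)
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("both groups need n >= 2")
    m0, m1 = x0.mean(), x1.mean()
    if m1 <= 0:
        raise ValueError("denominator group mean must be positive")
    v0, v1 = x0.var(ddof=1) / len(x0), x1.var(ddof=1) / len(x1)
    rho = m0 / m1
    # Satterthwaite df evaluated at the point estimate
    num = (v0 + rho**2 * v1) ** 2
    den = v0**2 / (len(x0) - 1) + rho**4 * v1**2 / (len(x1) - 1)
    df = num / den if den > 0 else len(x0) + len(x1) - 2
    tq = stats.t.ppf(1 - (1 - conf) / 2, df)
    a = m1**2 - tq**2 * v1
    b = m0 * m1
    c = m0**2 - tq**2 * v0
    if a <= 0:
        return float(rho), np.nan, np.nan
    disc = b**2 - a * c
    if disc < 0:
        return float(rho), np.nan, np.nan
    root = np.sqrt(disc)
    return float(rho), float((b - root) / a), float((b + root) / a)


# ---------------------------------------------------------------------------
# Haplotype comparison

@dataclass(frozen=True)
class HaplotypeDistance:
    distance: float
    genes_compared: int
    flipped: bool  # whether the second haplotype's chromosome labels were swapped


def _gene_tokens(state_a: str, state_b: str) -> set[str] | None:
    """Chromosome-resolved allele tokens for one gene; None when unresolved."""
    out: set[str] = set()
    for label, state in (("A", state_a), ("B", state_b)):
        if state in ("unknown", "NA", "suspected_" + DELETED_TOKEN):
            return None
        if state == DELETED_TOKEN:
            continue
        out.update(f"{label}:{al}" for al in str(state).split(","))
    return out


def _flip(tokens: set[str]) -> set[str]:
    swap = {"A": "B", "B": "A"}
    return {swap[t[0]] + t[1:] for t in tokens}


def haplotype_jaccard(
    h1: pd.DataFrame,
    h2: pd.DataFrame,
    min_genes: int = 5,
    min_linkages: int = 5,
) -> HaplotypeDistance:
    """Mean per-gene Jaccard distance between two haplotype tables.

    Per shared, chromosome-resolved gene the distance is 1 − |a∩b| / |a∪b|
    over the chromosome-tagged allele assignments; genes appearing in only one
    haplotype, or supported by fewer than ``min_linkages`` sequences in
    either, are excluded.  Chromosome labels from different anchors are
    arbitrary, so the orientation (identity or global flip of the second
    haplotype) minimizing the mean distance is used.  Raises when fewer than
    ``min_genes`` genes remain comparable.
    """
    def collect(df):
        out = {}
        for _, r in df.iterrows():
            if int(r["counts_chrA"]) + int(r["counts_chrB"]) < min_linkages:
                continue
            toks = _gene_tokens(str(r["alleles_chrA"]), str(r["alleles_chrB"]))
            if toks is not None:
                out[r["gene"]] = toks
        return out

    t1, t2 = collect(h1), collect(h2)
    shared = [g for g in t1 if g in t2 and (t1[g] or t2[g])]
    if len(shared) < min_genes:
        raise ValueError(
            f"insufficient overlap: {len(shared)} comparable genes < {min_genes}"
        )

    def mean_distance(flip: bool) -> float:
        ds = []
        for g in shared:
            a, b = t1[g], _flip(t2[g]) if flip else t2[g]
            union = a | b
            ds.append(1 - len(a & b) / len(union) if union else 0.0)
        return float(np.mean(ds))

    d_id, d_fl = mean_distance(False), mean_distance(True)
    if d_fl < d_id:
        return HaplotypeDistance(distance=d_fl, genes_compared=len(shared), flipped=True)
    return HaplotypeDistance(distance=d_id, genes_compared=len(shared), flipped=False)


def screen_anchor_candidates(
    genotypes: pd.DataFrame,
    distances: pd.DataFrame | None = None,
    minor_fraction: float = 0.30,
    min_side: int = 3,
) -> tuple[pd.DataFrame, float | None]:
    """Anchor eligibility by the minor-allele screen, with an optional check.

    A gene is an eligible anchor in a subject when heterozygous with minor
    allele fraction above ``minor_fraction``.  When ``distances`` (columns:
    minor_fraction, distance — cross-anchor Jaccard distances of candidate
    anchors) is given, a two-sided Wilcoxon rank-sum test compares distances
    above vs below the cutoff; returns NA (None) when either side has fewer
    than ``min_side`` observations.
    """
    eligible = genotypes[
        (genotypes["zygosity"] == "heterozygous")
        & (genotypes["minor_fraction"] > minor_fraction)
    ].copy()
    pval: float | None = None
    if distances is not None and not distances.empty:
        above = distances.loc[distances["minor_fraction"] > minor_fraction, "distance"]
        below = distances.loc[distances["minor_fraction"] <= minor_fraction, "distance"]
        if len(above) >= min_side and len(below) >= min_side:
            pval = float(stats.ranksums(above, below).pvalue)
    return eligible, pval
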