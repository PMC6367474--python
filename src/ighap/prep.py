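"""Inference-grade filtering, relative gene/allele usage and genotype summaries.

Haplotype and deletion inference operate on naive-repertoire rearrangements
that are unambiguous and essentially unmutated.  :func:`filter_for_inference`
applies the standard rules — at most three V mutations, no D mutations,
exactly one V, D and J assignment — and flags subjects whose retained depth
is too low for reliable inference.  :func:`compute_usage` turns the retained
records into relative gene usage per locus and within-gene allele fractions,
the quantities every downstream test consumes.  Each retained row counts as
one recombination event regardless of duplicate_count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

LOCUS_CALL = {"IGHV": "v_call", "IGHD": "d_call", "IGHJ": "j_call"}


@dataclass
class QCReport:
    """Per-rule exclusion counts and per-subject depth verdicts."""

    excluded: dict[str, int] = field(default_factory=dict)
    subject_depth: dict[str, int] = field(default_factory=dict)
    failed_subjects: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rule": k, "excluded_count": v} for k, v in self.excluded.items()]
        )


def filter_for_inference(
    records: pd.DataFrame,
    max_v_mut: int = 3,
    max_d_mut: int = 0,
    require_single: bool = True,
    min_depth: int = 2000,
) -> tuple[pd.DataFrame, QCReport]:
    """Retain records suitable for genotype/haplotype inference.

    Rules: V mutation count ≤ ``max_v_mut``; D mutation count ≤ ``max_d_mut``;
    exactly one V, D and J call when ``require_single``.  Subjects with fewer
    than ``min_depth`` retained records are flagged as failing depth QC (their
    records are kept; callers decide whether to drop them).

    Raises ``ValueError`` if a mutation filter is requested but the
    corresponding count column is absent.
    """
    report = QCReport()
    df = records
    keep = pd.Series(True, index=df.index)

    if max_v_mut is not None:
        if "v_mutation_count" not in df.columns:
            raise ValueError("v_mutation_count column required for the V mutation filter")
        rule = df["v_mutation_count"] <= max_v_mut
        report.excluded["v_mutations"] = int((keep & ~rule).sum())
        keep &= rule
    if max_d_mut is not None:
        if "d_mutation_count" not in df.columns:
            raise ValueError("d_mutation_count column required for the D mutation filter")
        rule = df["d_mutation_count"].isna() | (df["d_mutation_count"] <= max_d_mut)
        report.excluded["d_mutations"] = int((keep & ~rule).sum())
        keep &= rule
    if require_single:
        single = pd.Series(True, index=df.index)
        for col in ("v_call", "d_call", "j_call"):
            vals = df[col].astype("string")
            single &= vals.notna() & ~vals.str.contains(",", regex=False)
        report.excluded["multiple_assignment"] = int((keep & ~single).sum())
        keep &= single

    out = df[keep].reset_index(drop=True)
    depths = out.groupby("subject_id").size()
    for subj, n in depths.items():
        report.subject_depth[subj] = int(n)
        if n < min_depth:
            report.failed_subjects.add(subj)
    for subj in records["subject_id"].unique():
        if subj not in report.subject_depth:
            report.subject_depth[subj] = 0
            report.failed_subjects.add(subj)
    return out, report


# ---------------------------------------------------------------------------
# Usage

def _gene_of(calls: pd.Series) -> pd.Series:
    return calls.astype("string").str.split("*").str[0]


def _allele_of(calls: pd.Series) -> pd.Series:
    return calls.astype("string").str.split("*").str[1]


@dataclass
class UsageTable:
    """Relative gene usage per (subject, locus) and allele fractions per gene.

    ``gene_usage`` columns: subject, locus, gene, count, fraction — fractions
    sum to 1 within each (subject, locus).  ``allele_usage`` columns: subject,
    locus, gene, allele, count, fraction — fractions sum to 1 within each
    (subject, gene).  ``totals`` columns: subject, locus, total.
    """

    gene_usage: pd.DataFrame
    allele_usage: pd.DataFrame
    totals: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "UsageTable":
        """Build a usage table from per-(subject, locus, gene[, allele]) counts."""
        c = counts.copy()
        if "allele" not in c.columns:
            c["allele"] = "01"
        gene = (
            c.groupby(["subject", "locus", "gene"], as_index=False)["count"].sum()
        )
        totals = gene.groupby(["subject", "locus"], as_index=False)["count"].sum()
        totals = totals.rename(columns={"count": "total"})
        gene = gene.merge(totals, on=["subject", "locus"])
        gene["fraction"] = gene["count"] / gene["total"]
        allele = c.groupby(["subject", "locus", "gene", "allele"], as_index=False)[
            "count"
        ].sum()
        gtot = gene.rename(columns={"count": "gene_count"})[
            ["subject", "locus", "gene", "gene_count"]
        ]
        allele = allele.merge(gtot, on=["subject", "locus", "gene"])
        allele["fraction"] = allele["count"] / allele["gene_count"]
        return cls(
            gene_usage=gene.drop(columns="total"),
            allele_usage=allele.drop(columns="gene_count"),
            totals=totals,
        )

    def fraction_matrix(self, locus: str) -> pd.DataFrame:
        """Subjects × genes matrix of usage fractions (absent genes → 0)."""
        sub = self.gene_usage[self.gene_usage["locus"] == locus]
        return sub.pivot_table(
            index="subject", columns="gene", values="fraction", fill_value=0.0
        )

    def count_matrix(self, locus: str) -> pd.DataFrame:
        sub = self.gene_usage[self.gene_usage["locus"] == locus]
        return (
            sub.pivot_table(index="subject", columns="gene", values="count", fill_value=0)
            .astype(int)
        )

    def locus_totals(self, locus: str) -> pd.Series:
        sub = self.totals[self.totals["locus"] == locus]
        return sub.set_index("subject")["total"]


def compute_usage(records: pd.DataFrame) -> UsageTable:
    """Relative usage from filtered single-assignment records (one event per row)."""
    if records.empty:
        raise ValueError("cannot compute usage from an empty record set")
    pieces = []
    for locus, col in LOCUS_CALL.items():
        sub = records[records[col].notna()]
        if sub.empty:
            continue
        t = pd.DataFrame(
            {
                "subject": sub["subject_id"],
                "locus": locus,
                "gene": _gene_of(sub[col]),
                "allele": _allele_of(sub[col]).fillna(""),
            }
        )
        pieces.append(t)
    counts = (
        pd.concat(pieces)
        .groupby(["subject", "locus", "gene", "allele"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return UsageTable.from_counts(counts)


# ---------------------------------------------------------------------------
# Genotype summary

def summarize_genotype(
    records: pd.DataFrame,
    min_seqs: int = 10,
    min_allele_fraction: float = 0.0,
    max_alleles: int = 4,
) -> pd.DataFrame:
    """Per-(subject, gene) allele sets with zygosity.

    Alleles with a within-gene fraction below ``min_allele_fraction`` are
    dropped (use 0.30 when screening anchor candidates); at most
    ``max_alleles`` are retained, by descending count with ties broken by
    allele name.  Genes with fewer than ``min_seqs`` supporting records get
    zygosity NA.  ``minor_fraction`` is the within-gene fraction of the
    second most used allele (0 when a single allele is seen).

    Returns columns: subject, locus, gene, alleles (comma-joined), zygosity,
    count, minor_fraction.
    """
    usage = compute_usage(records)
    rows = []
    for (subject, locus, gene), sub in usage.allele_usage.groupby(
        ["subject", "locus", "gene"]
    ):
        sub = sub.sort_values(["count", "allele"], ascending=[False, True])
        total = int(sub["count"].sum())
        retained = sub[sub["fraction"] >= min_allele_fraction].head(max_alleles)
        if retained.empty:  # everything under the fraction floor: keep the top allele
            retained = sub.head(1)
        alleles = list(retained["allele"])
        if total < min_seqs:
            zyg = "NA"
        elif len(alleles) >= 2:
            zyg = "heterozygous"
        else:
            zyg = "homozygous"
        minor = float(sub["fraction"].iloc[1]) if len(sub) > 1 else 0.0
        rows.append(
            {
                "subject": subject,
                "locus": locus,
                "gene": gene,
                "alleles": ",".join(alleles),
                "zygosity": zyg,
                "count": total,
                "minor_fraction": minor,
            }
        )
    return pd.DataFrame(rows)
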