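"""AIRR Rearrangement table I/O, allele-call parsing and gene filtration.

Rearrangement tables are the tab-separated files produced by standard
VDJ-annotation pipelines (one row per sequenced rearrangement, with ``v_call``
/ ``d_call`` / ``j_call`` columns holding IMGT-style allele names such as
``IGHV3-23*01``).  This module loads them into a pandas DataFrame with
normalized column names, parses call strings, applies the functionality-based
gene filtration used before inference, and reads/writes the result tables
(haplotype and deletion TSVs).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .reference import REMOVED_GENES, GeneReference

logger = logging.getLogger(__name__)

#: literal token used in result tables for a chromosome with no gene copy
DELETED_TOKEN = "deleted"

HAPLOTYPE_COLUMNS = [
    "subject",
    "gene",
    "alleles_chrA",
    "alleles_chrB",
    "counts_chrA",
    "counts_chrB",
    "lK",
    "call_state",
]

DELETION_COLUMNS = ["subject", "gene", "state", "statistic", "q_or_lK"]

_CALL_RE = re.compile(
    r"^(?P<gene>(?P<locus>IGH[VDJ])[\w.-]*?)(?:\*(?P<allele>[\w.]+))?$"
)


class SchemaError(ValueError):
    """Input table does not satisfy the AIRR Rearrangement contract."""


class ParseError(ValueError):
    """A call string does not follow IMGT nomenclature."""


@dataclass(frozen=True)
class AlleleCall:
    """One parsed gene*allele token from a v/d/j call string."""

    locus: str
    gene: str
    family: str
    allele: str
    raw: str

    def __str__(self) -> str:  # canonical IMGT rendering
        return f"{self.gene}*{self.allele}" if self.allele else self.gene


def parse_allele_call(raw: str) -> list[AlleleCall]:
    """Parse a call string into one :class:`AlleleCall` per distinct token.

    Multiple assignments may be separated by commas or ``" or "``; square
    brackets around alternative sets are tolerated.  Duplicate tokens collapse
    to one; order is otherwise preserved.
    """
    if not raw or not str(raw).strip():
        raise ParseError("empty call string")
    text = str(raw).strip().strip("[]")
    tokens = [t.strip() for t in re.split(r",|\bor\b", text) if t.strip()]
    out: list[AlleleCall] = []
    seen: set[str] = set()
    for tok in tokens:
        m = _CALL_RE.match(tok)
        if not m:
            raise ParseError(f"malformed allele call token: {tok!r}")
        gene = m.group("gene")
        locus = m.group("locus")
        fam_m = re.match(r"(IGH[VDJ]\d+)", gene)
        family = fam_m.group(1) if fam_m else gene
        allele = m.group("allele") or ""
        key = f"{gene}*{allele}"
        if key not in seen:
            seen.add(key)
            out.append(AlleleCall(locus=locus, gene=gene, family=family, allele=allele, raw=tok))
    return out


# ---------------------------------------------------------------------------
# Rearrangement loading

_MANDATORY = ["sequence_id", "v_call", "d_call", "j_call"]
_OPTIONAL = ["v_mutation_count", "d_mutation_count", "duplicate_count", "subject_id"]


def load_rearrangements(
    path, column_map: dict[str, str] | None = None, subject_id: str | None = None
) -> pd.DataFrame:
    """Load an AIRR Rearrangement TSV into a normalized DataFrame.

    ``column_map`` maps file column names to AIRR names (e.g. Change-O's
    ``SEQUENCE_ID`` → ``sequence_id``).  Missing optional mutation-count
    columns are reported and left absent, which disables mutation filters
    downstream.  ``duplicate_count`` defaults to 1; ``subject_id`` may be
    supplied for single-subject files lacking the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    if df.empty:
        raise SchemaError(f"empty rearrangement file: {path}")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for col in ("v_mutation_count", "d_mutation_count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
        else:
            logger.warning("column %s absent; mutation filter on it will be unavailable", col)
    if "duplicate_count" in df.columns:
        df["duplicate_count"] = pd.to_numeric(df["duplicate_count"]).fillna(1).astype(int)
    else:
        df["duplicate_count"] = 1
    if "subject_id" not in df.columns:
        df["subject_id"] = subject_id if subject_id is not None else "subject"
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene filtration

def _filter_call(raw: str, reference: GeneReference, counts: dict[str, int]) -> str | None:
    """Rewrite one call string under the filtration rules; None drops the call."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or not str(raw).strip():
        return None
    kept: list[str] = []
    for ac in parse_allele_call(raw):
        if ac.gene in REMOVED_GENES:
            counts["removed_indistinguishable"] += 1
            continue
        func = reference.functionality(ac.gene)
        if func is None:
            counts["unknown_gene"] += 1
            kept.append(str(ac))  # unknown genes pass through, logged
            continue
        if func != "functional":
            counts["removed_" + func.lower()] += 1
            continue
        canon = reference.canonical(ac.gene)
        if canon != ac.gene:
            counts["aliased"] += 1
            ac = AlleleCall(ac.locus, canon, ac.family, ac.allele, ac.raw)
        kept.append(str(ac))
    if not kept:
        return None
    # collapse duplicates introduced by aliasing, preserve order
    out: list[str] = []
    for k in kept:
        if k not in out:
            out.append(k)
    return ",".join(out)


def apply_gene_filtration(
    records: pd.DataFrame, reference: GeneReference
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop ORF/pseudo-gene and removed-gene calls; alias indistinguishable genes.

    Records whose V or J call is emptied by the rules are excluded.  D calls may
    be emptied (left as NA) since D assignment is optional in many analyses.
    Returns the filtered table and a per-rule removal report.  Idempotent.
    """
    counts: dict[str, int] = {
        "removed_orf": 0,
        "removed_pseudo": 0,
        "removed_indistinguishable": 0,
        "aliased": 0,
        "unknown_gene": 0,
        "records_excluded": 0,
    }
    df = records.copy()
    for col in ("v_call", "d_call", "j_call"):
        cache: dict[str, str | None] = {}
        new = []
        for raw in df[col]:
            key = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw)
            if key not in cache:
                cache[key] = _filter_call(raw, reference, counts)
            new.append(cache[key])
        df[col] = new
    keep = df["v_call"].notna() & df["j_call"].notna()
    counts["records_excluded"] = int((~keep).sum())
    if counts["unknown_gene"]:
        logger.info("%d calls referenced genes absent from the reference", counts["unknown_gene"])
    return df[keep].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# Result tables

def write_haplotype_table(calls: pd.DataFrame, path) -> None:
    """Write a haplotype table TSV (one row per gene, fixed column dialect)."""
    df = calls.copy()
    missing = [c for c in HAPLOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"haplotype table missing columns: {missing}")
    if df["subject"].nunique() > 1:
        raise ValueError("haplotype table must hold a single subject per file")
    df["lK"] = pd.to_numeric(df["lK"]).map(lambda v: f"{v:.6g}")
    df[HAPLOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_haplotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in HAPLOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"haplotype table missing columns: {missing}")
    df["lK"] = pd.to_numeric(df["lK"])
    for col in ("counts_chrA", "counts_chrB"):
        df[col] = pd.to_numeric(df[col].fillna(0), errors="coerce").fillna(0).astype(int)
    return df


def write_deletion_table(results: pd.DataFrame, path) -> None:
    df = results.copy()
    missing = [c for c in DELETION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"deletion table missing columns: {missing}")
    df[DELETION_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_deletion_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
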