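"""Germline gene reference for the human IGH locus.

The reference lists every gene considered by the toolkit together with its
locus (IGHV / IGHD / IGHJ), IMGT functionality class and position along the
chromosome.  A small alias map collapses gene pairs whose germline sequences
are identical and therefore indistinguishable in repertoire data
(IGHD4-4/IGHD4-11 and IGHD5-5/IGHD5-18).

A default table ships with the package; users may load their own with
:func:`load_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

LOCI = ("IGHV", "IGHD", "IGHJ")

#: Genes excluded from inference outright: IGHV1-69D is indistinguishable from
#: IGHV1-69 for most alleles, and IGHV4-30-1 lacks a reliable reference sequence.
REMOVED_GENES = frozenset({"IGHV1-69D", "IGHV4-30-1"})


@dataclass(frozen=True)
class GeneReference:
    """Germline gene table with locus order and an idempotent alias map."""

    table: pd.DataFrame  # columns: gene, locus, functionality, order, canonical
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, sub in self.table.groupby("locus"):
            if sub["order"].duplicated().any():
                raise ValueError(f"duplicate locus-order index in {locus}")
        for src, dst in self.aliases.items():
            if self.aliases.get(dst, dst) != dst:
                raise ValueError(f"alias map not idempotent: {src} -> {dst}")

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene"])

    def canonical(self, gene: str) -> str:
        """Map a gene to its canonical name (identity for non-aliased genes)."""
        return self.aliases.get(gene, gene)

    def functionality(self, gene: str) -> str | None:
        row = self.table.loc[self.table["gene"] == gene]
        return None if row.empty else row["functionality"].iloc[0]

    def locus_order(self, gene: str) -> int | None:
        row = self.table.loc[self.table["gene"] == gene]
        return None if row.empty else int(row["order"].iloc[0])

    def functional_genes(self, locus: str) -> list[str]:
        """Canonical functional genes of a locus, in chromosomal order."""
        sub = self.table[
            (self.table["locus"] == locus)
            & (self.table["functionality"] == "functional")
            & (~self.table["gene"].isin(REMOVED_GENES))
        ].sort_values("order")
        # alias rows (e.g. IGHD4-4 -> IGHD4-11) are dropped: the canonical gene
        # appears at its own chromosomal position
        return [g for g in sub["gene"] if self.canonical(g) == g]


def _build(table: pd.DataFrame) -> GeneReference:
    required = {"gene", "locus", "functionality", "order"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if "canonical" not in table.columns:
        table = table.assign(canonical=table["gene"])
    aliases = {
        g: c for g, c in zip(table["gene"], table["canonical"], strict=True) if g != c
    }
    return GeneReference(table=table.reset_index(drop=True), aliases=aliases)


def load_reference(path) -> GeneReference:
    """Load a gene reference from a TSV (columns: gene, locus, functionality, order[, canonical])."""
    return _build(pd.read_csv(path, sep="\t", dtype={"order": int}))


def load_default_reference() -> GeneReference:
    """The packaged human IGH reference."""
    with resources.files("ighap.data").joinpath("igh_reference.tsv").open() as fh:
        return _build(pd.read_csv(fh, sep="\t", dtype={"order": int}))
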