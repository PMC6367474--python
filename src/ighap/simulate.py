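"""Synthetic diploid IGH genomes and naive-repertoire generation.

The generator embodies the assumptions of the inference model so that every
stage can be validated against known truth: a diploid genome assigns each
gene one allele per chromosome (or marks it deleted, possibly in linked
blocks, with mutually exclusive alternatives such as {V1-8, V3-9} vs
{V5-10-1, V3-64D}); each rearrangement picks a chromosome, then draws one V,
one D and one J gene from that chromosome's surviving genes by usage weight,
and emits that chromosome's alleles; with probability ε an emitted allele is
swapped to the homologous chromosome's allele of the same gene (the
mis-assignment process the inference's θ hypotheses model).  V–D–J choices
are independent given the chromosome, and mutation counts are zero, matching
a naive repertoire.

All randomness flows through a single integer seed; outputs are
byte-reproducible and load cleanly through :mod:`ighap.airr_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import GeneReference, load_default_reference

ALLELE_POOL = ("01", "02", "03", "04")

DEFAULT_HET_PROB = {"IGHV": 0.30, "IGHD": 0.15, "IGHJ": 0.10}

#: adjacent gene blocks of which exactly one is deleted per chromosome
DEFAULT_EXCLUSIVE_BLOCKS = (
    (frozenset({"IGHV1-8", "IGHV3-9"}), frozenset({"IGHV5-10-1", "IGHV3-64D"})),
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic subject.

    ``usage_weights`` (locus → gene → weight) defaults to log-normal draws
    normalized per locus, giving a realistic spread with a few dominant
    genes.  ``forced_genotype`` pins (alleleA, alleleB) for chosen genes —
    use it to make anchors heterozygous.  ``single_deletions`` lists
    (gene, "A"|"B") pairs, ``double_deletions`` genes missing from both
    chromosomes.  ``allele_bias`` maps a heterozygous gene to the probability
    its rearrangements originate from chromosome A (0.5 = unbiased).
    """

    n_sequences: int = 10_000
    epsilon: float = 0.005
    chromosome_prob: float = 0.5
    het_prob: dict = field(default_factory=lambda: dict(DEFAULT_HET_PROB))
    usage_weights: dict | None = None
    forced_genotype: dict = field(default_factory=dict)
    single_deletions: list = field(default_factory=list)
    double_deletions: list = field(default_factory=list)
    exclusive_blocks: tuple = ()
    allele_bias: dict = field(default_factory=dict)
    subject_id: str = "sim"
    usage_weight_sigma: float = 1.0

    def __post_init__(self):
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")
        if not 0 < self.chromosome_prob < 1:
            raise ValueError("chromosome_prob must lie in (0, 1)")


@dataclass
class SimulatedGenome:
    """Diploid truth: per-chromosome gene → allele maps (None = deleted)."""

    chromosomes: dict  # {"A": {gene: allele|None}, "B": {...}}
    loci: dict  # locus -> ordered gene list
    usage_weights: dict  # locus -> gene -> weight

    def alleles(self, gene: str) -> tuple:
        return (self.chromosomes["A"].get(gene), self.chromosomes["B"].get(gene))

    def zygosity(self, gene: str) -> str:
        a, b = self.alleles(gene)
        if a is None and b is None:
            return "deleted_both"
        if a is None or b is None:
            return "hemizygous"
        return "heterozygous" if a != b else "homozygous"


#: typical human IGHJ usage — J4 dominates, J6 is the second most used.  The
#: J distribution is stable across individuals (unlike V/D), and a realistic
#: J6 share is what makes J6-anchored haplotyping workable in practice.
DEFAULT_J_USAGE = {
    "IGHJ1": 0.02,
    "IGHJ2": 0.04,
    "IGHJ3": 0.10,
    "IGHJ4": 0.45,
    "IGHJ5": 0.08,
    "IGHJ6": 0.31,
}


def default_usage_weights(
    loci: dict, rng: np.random.Generator, sigma: float = 1.0
) -> dict:
    """Per-locus gene-usage weights: log-normal draws for V/D, fixed J usage."""
    out = {}
    for locus, genes in loci.items():
        if locus == "IGHJ" and set(genes) <= set(DEFAULT_J_USAGE):
            w = np.array([DEFAULT_J_USAGE[g] for g in genes])
        else:
            w = rng.lognormal(mean=0.0, sigma=sigma, size=len(genes))
        out[locus] = dict(zip(genes, w / w.sum()))
    return out


def simulate_genome(
    config: SimulationConfig,
    seed: int,
    reference: GeneReference | None = None,
) -> SimulatedGenome:
    """Draw a diploid genome under the configured conditions (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    reference = reference or load_default_reference()
    loci = {loc: reference.functional_genes(loc) for loc in ("IGHV", "IGHD", "IGHJ")}

    for pair in config.exclusive_blocks:
        b1, b2 = pair
        if b1 & b2:
            raise ValueError(f"exclusive blocks overlap: {sorted(b1 & b2)}")

    chrom = {"A": {}, "B": {}}
    for locus, genes in loci.items():
        for gene in genes:
            if gene in config.forced_genotype:
                a, b = config.forced_genotype[gene]
            elif rng.random() < config.het_prob.get(locus, 0.0):
                a, b = rng.choice(ALLELE_POOL, size=2, replace=False)
            else:
                a = b = rng.choice(ALLELE_POOL)
            chrom["A"][gene] = a
            chrom["B"][gene] = b

    for gene in config.double_deletions:
        chrom["A"][gene] = None
        chrom["B"][gene] = None
    for gene, c in config.single_deletions:
        chrom[c][gene] = None
    for b1, b2 in config.exclusive_blocks:
        for c in ("A", "B"):
            doomed = b1 if rng.random() < 0.5 else b2
            for gene in doomed:
                chrom[c][gene] = None

    weights = config.usage_weights or default_usage_weights(
        loci, rng, config.usage_weight_sigma
    )
    return SimulatedGenome(chromosomes=chrom, loci=loci, usage_weights=weights)


def simulate_repertoire(
    genome: SimulatedGenome, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Draw an AIRR-style rearrangement table from a simulated genome."""
    rng = np.random.default_rng(seed)
    n = config.n_sequences
    on_a = rng.random(n) < config.chromosome_prob
    counts = {"A": int(on_a.sum()), "B": int(n - on_a.sum())}

    per_chrom_draws: dict = {}
    for c in ("A", "B"):
        per_chrom_draws[c] = {}
        for locus, genes in genome.loci.items():
            avail = [g for g in genes if genome.chromosomes[c][g] is not None]
            if not avail:
                raise ValueError(f"all {locus} genes deleted on chromosome {c}")
            w = np.array([genome.usage_weights[locus][g] for g in avail])
            bias = np.array(
                [
                    config.allele_bias.get(g, 0.5) if c == "A"
                    else 1 - config.allele_bias.get(g, 0.5)
                    for g in avail
                ]
            )
            w = w * 2 * bias
            w = w / w.sum()
            idx = rng.choice(len(avail), size=counts[c], p=w)
            per_chrom_draws[c][locus] = (np.array(avail, dtype=object), idx)

    cols = {}
    for locus, call_col in (("IGHV", "v_call"), ("IGHD", "d_call"), ("IGHJ", "j_call")):
        gene_arr = np.empty(n, dtype=object)
        allele_arr = np.empty(n, dtype=object)
        for c, mask in (("A", on_a), ("B", ~on_a)):
            avail, idx = per_chrom_draws[c][locus]
            genes = avail[idx]
            own = np.array(
                [genome.chromosomes[c][g] for g in avail], dtype=object
            )[idx]
            other_c = "B" if c == "A" else "A"
            other = np.array(
                [genome.chromosomes[other_c][g] for g in avail], dtype=object
            )[idx]
            # ε mis-assignment: swap to the homolog's allele where it differs
            swap = (rng.random(len(genes)) < config.epsilon) & (other != None)  # noqa: E711
            swap &= other != own
            emitted = np.where(swap, other, own)
            gene_arr[mask] = genes
            allele_arr[mask] = emitted
        cols[call_col] = pd.Series(gene_arr, dtype="string") + "*" + pd.Series(
            allele_arr, dtype="string"
        )

    return pd.DataFrame(
        {
            "sequence_id": [f"{config.subject_id}_seq{i}" for i in range(n)],
            "v_call": cols["v_call"],
            "d_call": cols["d_call"],
            "j_call": cols["j_call"],
            "v_mutation_count": 0,
            "d_mutation_count": 0,
            "duplicate_count": 1,
            "subject_id": config.subject_id,
        }
    )


def emit_truth(genome: SimulatedGenome, subject_id: str = "sim") -> dict:
    """Truth tables keyed like the inference outputs (for direct joins)."""
    zyg_rows, del_rows = [], []
    for locus, genes in genome.loci.items():
        for gene in genes:
            a, b = genome.alleles(gene)
            zyg_rows.append(
                {
                    "subject": subject_id,
                    "locus": locus,
                    "gene": gene,
                    "allele_chrA": a if a is not None else "deleted",
                    "allele_chrB": b if b is not None else "deleted",
                    "zygosity": genome.zygosity(gene),
                }
            )
            for c, al in (("A", a), ("B", b)):
                if al is None:
                    del_rows.append(
                        {"subject": subject_id, "gene": gene, "chromosome": c,
                         "state": "deleted"}
                    )
    return {
        "zygosity": pd.DataFrame(zyg_rows),
        "deletions": pd.DataFrame(
            del_rows, columns=["subject", "gene", "chromosome", "state"]
        ),
    }
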