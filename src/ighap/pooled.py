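"""Pooled-anchor inference of D-gene single-chromosome deletions (V_pooled).

Only about a third of the population is IGHJ6-heterozygous, but essentially
everyone is heterozygous for several V genes.  Each heterozygous V gene links
far fewer sequences to any D allele than J6 does, so no single V anchor is
powerful enough — but the binomial likelihood with a conjugate prior lets the
posterior from one V-based inference serve as the prior of the next.  This
module chains those updates: for every eligible V anchor it builds the V–D
contingency, orients the chromosome labels so the dominant D alleles share a
chromosome, multiplies the running model weights by the anchor's likelihoods
and renormalizes.  The final certainty is lK = log10 of the ratio of the two
top pooled weights; a conservative cutoff (lK = 12 by default) trades
sensitivity for precision because contradictory orientations across anchors
("allele mix") can otherwise accumulate.

Anchors must pass the 30% minor-allele screen; D genes under 1.5% mean usage
are excluded as too rare to pool reliably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotype import (
    MODELS,
    AnchorConfig,
    HaplotypeParams,
    ModelHypotheses,
    build_contingency,
    log_model_weights,
)
from .prep import compute_usage

logger = logging.getLogger(__name__)


@dataclass
class PooledInferenceState:
    """Running pooled weights per (D gene, allele) and per-anchor bookkeeping."""

    log_weights: dict = field(default_factory=dict)  # (gene, allele) -> np.ndarray(3)
    anchor_lk: dict = field(default_factory=dict)  # anchor gene -> {(gene, allele): lK}
    anchors_used: list = field(default_factory=list)
    orientation: dict = field(default_factory=dict)  # anchor gene -> +1 / -1
    orientation_consistency: dict = field(default_factory=dict)  # anchor -> [0, 1]

    def normalized_weights(self, key) -> np.ndarray:
        w = np.exp(self.log_weights[key] - np.max(self.log_weights[key]))
        return w / w.sum()


def _anchor_minor_fraction(records: pd.DataFrame, anchor: AnchorConfig) -> float:
    from .prep import LOCUS_CALL, _allele_of, _gene_of

    col = LOCUS_CALL[anchor.gene[:4]]
    sub = records[_gene_of(records[col]) == anchor.gene]
    alleles = _allele_of(sub[col])
    na = int(alleles.isin(anchor.group_a).sum())
    nb = int(alleles.isin(anchor.group_b).sum())
    if na + nb == 0:
        return 0.0
    return min(na, nb) / (na + nb)


def _orientation_votes(rows: pd.DataFrame, hyp: ModelHypotheses) -> tuple[int, float]:
    """Majority orientation over dominant D alleles; returns (sign, consistency).

    Only informative alleles vote: the gene's dominant (most-counted) allele,
    and only when its best model is a chromosome-only one — balanced
    both-chromosome alleles carry no orientation signal.
    """
    from .haplotype import score_models

    votes = []
    for _, sub in rows.groupby("gene"):
        dom = sub.loc[(sub["n1"] + sub["n2"]).idxmax()]
        best, _, _ = score_models(int(dom["n1"]), int(dom["n2"]), hyp)
        if best == "chrA":
            votes.append(1)
        elif best == "chrB":
            votes.append(-1)
    if not votes:
        return 1, 1.0
    total = sum(votes)
    sign = 1 if total >= 0 else -1
    consistency = sum(v == sign for v in votes) / len(votes)
    return sign, consistency


def pool_inference(
    records: pd.DataFrame,
    v_anchors: list[AnchorConfig],
    params: HaplotypeParams | None = None,
    min_d_usage: float = 0.015,
    lk_cutoff: float = 12.0,
    min_minor_fraction: float = 0.30,
) -> tuple[pd.DataFrame, PooledInferenceState]:
    """Chain V-anchor posteriors into D-gene deletion calls for one subject.

    Returns a per-gene call table (subject, gene, state, lK plus per-allele
    detail columns) and the final :class:`PooledInferenceState`.  The result
    is invariant to anchor ordering since updates are products.
    """
    params = params or HaplotypeParams()
    if not v_anchors:
        raise ValueError("at least one V anchor is required")
    subjects = records["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("pool_inference expects records of a single subject")
    subject = subjects[0]

    usage = compute_usage(records)
    d_usage = usage.gene_usage[usage.gene_usage["locus"] == "IGHD"]
    eligible_genes = set(d_usage.loc[d_usage["fraction"] >= min_d_usage, "gene"])

    if isinstance(params.priors, str):
        logprior = np.log(np.full(3, 1 / 3))
    else:
        logprior = np.log(np.asarray(params.priors, dtype=float))

    state = PooledInferenceState()
    for anchor in v_anchors:
        minor = _anchor_minor_fraction(records, anchor)
        if minor <= min_minor_fraction:
            logger.warning(
                "anchor %s fails the %.0f%% minor-allele screen (%.3f); skipped",
                anchor.gene, 100 * min_minor_fraction, minor,
            )
            continue
        cont = build_contingency(records, anchor, "IGHD")
        rows = cont.rows[cont.rows["gene"].isin(eligible_genes)].copy()
        if rows.empty:
            continue
        hyp0 = ModelHypotheses(
            epsilon=params.epsilon, p=cont.p, priors=(1 / 3, 1 / 3, 1 / 3)
        )
        sign, consistency = _orientation_votes(rows, hyp0)
        p = cont.p
        if sign < 0:
            rows[["n1", "n2"]] = rows[["n2", "n1"]].to_numpy()
            p = 1 - p
        hyp = ModelHypotheses(epsilon=params.epsilon, p=p, priors=(1 / 3, 1 / 3, 1 / 3))
        state.orientation[anchor.gene] = sign
        state.orientation_consistency[anchor.gene] = consistency
        state.anchors_used.append(anchor.gene)
        contrib: dict = {}
        for _, r in rows.iterrows():
            key = (r["gene"], r["allele"])
            loglik = log_model_weights(int(r["n1"]), int(r["n2"]), hyp) - np.log(
                np.asarray(hyp.priors)
            )
            if key not in state.log_weights:
                state.log_weights[key] = logprior.copy()
            state.log_weights[key] = state.log_weights[key] + loglik
            srt = np.sort(loglik)[::-1]
            contrib[key] = float(
                min((srt[0] - srt[1]) / np.log(10), params.lk_cap)
            ) if np.isfinite(srt[1]) else params.lk_cap
        state.anchor_lk[anchor.gene] = contrib

    if not state.anchors_used:
        raise ValueError("no anchor passed the minor-allele screen")

    out = []
    by_gene: dict[str, list] = {}
    for (gene, allele), logw in state.log_weights.items():
        order = np.argsort(logw)[::-1]
        if np.isinf(logw[order[1]]):
            lk = params.lk_cap
        else:
            lk = float(min((logw[order[0]] - logw[order[1]]) / np.log(10), params.lk_cap))
        by_gene.setdefault(gene, []).append((allele, MODELS[order[0]], lk))

    for gene, alleles in sorted(by_gene.items()):
        best_models = {m for _, m, _ in alleles}
        min_lk = min(lk for _, _, lk in alleles)
        if best_models == {"chrA"}:
            state_str = "deleted_chrB" if min_lk >= lk_cutoff else "suspected_chrB"
        elif best_models == {"chrB"}:
            state_str = "deleted_chrA" if min_lk >= lk_cutoff else "suspected_chrA"
        else:
            state_str = "present"
        out.append(
            {
                "subject": subject,
                "gene": gene,
                "state": state_str,
                "lK": min_lk,
                "alleles": ",".join(a for a, _, _ in sorted(alleles)),
                "best_models": ",".join(m for _, m, _ in sorted(alleles)),
            }
        )
    return pd.DataFrame(out), state


@dataclass
class EvaluationResult:
    lk_cutoff: float
    tp: int
    fp: int
    fn: int
    precision: float | None
    sensitivity: float | None


def evaluate_against_reference(
    pooled_calls: pd.DataFrame,
    reference_calls: pd.DataFrame,
    lk_grid,
) -> pd.DataFrame:
    """Precision/sensitivity of pooled deletion calls against a reference set.

    Chromosome labels are not comparable across anchors, so agreement is
    scored at the (subject, gene) level: does each call set report a
    single-chromosome deletion for that gene?  ``reference_calls`` rows whose
    ``state`` contains "deleted" define the truth; pooled rows are positive
    when their state contains "deleted" or "suspected" and their lK clears the
    grid cutoff.
    """
    ref_keys = set(
        zip(reference_calls["subject"], reference_calls["gene"])
    )
    pool_keys = set(zip(pooled_calls["subject"], pooled_calls["gene"]))
    shared = ref_keys & pool_keys
    if not shared:
        raise ValueError("no shared (subject, gene) keys between call sets")

    ref_del = {
        (s, g)
        for s, g, st in zip(
            reference_calls["subject"], reference_calls["gene"], reference_calls["state"]
        )
        if (s, g) in shared and "deleted" in str(st)
    }
    rows = []
    for cutoff in lk_grid:
        pred = {
            (s, g)
            for s, g, st, lk in zip(
                pooled_calls["subject"],
                pooled_calls["gene"],
                pooled_calls["state"],
                pooled_calls["lK"],
            )
            if (s, g) in shared
            and ("deleted" in str(st) or "suspected" in str(st))
            and lk >= cutoff
        }
        tp = len(pred & ref_del)
        fp = len(pred - ref_del)
        fn = len(ref_del - pred)
        rows.append(
            {
                "lk_cutoff": float(cutoff),
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "sensitivity": tp / (tp + fn) if tp + fn else (np.nan if ref_del else np.nan),
            }
        )
    return pd.DataFrame(rows)
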