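"""Two-chromosome gene deletion detection from cohort-wide relative usage.

A gene deleted from both chromosomes can only acquire reads through
mis-assignment, so its relative usage collapses far below the population's
range.  For each gene, subjects whose usage falls below a locus-specific
candidate threshold (0.001 for V, 0.005 for D — the D assignments being less
reliable) are tested with a one-sided binomial test: with N total sequences
and x mapped to the gene, how surprising is x under the null rate p, taken as
the lowest usage among non-candidate subjects (above a 0.001 floor)?
Benjamini-Hochberg correction is applied per gene across its candidate
subjects, and q < 0.01 marks a deletion.  Genes essentially unexpressed
across the cohort (below the candidate threshold in more than 90% of
subjects) are uninformative and reported NA.

A gamma-mixture bimodality check flags genes whose usage does not separate
into a clear low/high pattern, indicating the deletion call is less reliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .prep import UsageTable

DEFAULT_CANDIDATE_THRESH = {"IGHV": 0.001, "IGHD": 0.005, "IGHJ": 0.001}


def detect_double_deletions(
    usage: UsageTable,
    locus: str,
    candidate_thresh: float | None = None,
    q_cutoff: float = 0.01,
    na_fraction: float = 0.90,
    null_floor: float = 0.001,
) -> pd.DataFrame:
    """Binomial test for genes deleted on both chromosomes, per subject.

    Returns one row per (subject, gene) with columns: subject, gene, x, N, p,
    p_value, q_value, call ∈ {deleted_both, present, not_candidate, NA} and a
    ``reason`` column for NA rows.
    """
    if candidate_thresh is None:
        candidate_thresh = DEFAULT_CANDIDATE_THRESH[locus]
    frac = usage.fraction_matrix(locus)
    if frac.shape[0] < 2:
        raise ValueError("double-deletion detection needs at least 2 subjects")
    cnt = usage.count_matrix(locus).reindex_like(frac).fillna(0).astype(int)
    totals = usage.locus_totals(locus).reindex(frac.index)

    rows = []
    for gene in frac.columns:
        f = frac[gene]
        candidates = f < candidate_thresh
        if candidates.mean() > na_fraction:
            for subj in f.index:
                rows.append(
                    _row(subj, gene, cnt.at[subj, gene], totals[subj], np.nan,
                         np.nan, np.nan, "NA", "rare_across_cohort")
                )
            continue
        null_pool = f[(~candidates) & (f > null_floor)]
        if null_pool.empty:
            for subj in f.index:
                rows.append(
                    _row(subj, gene, cnt.at[subj, gene], totals[subj], np.nan,
                         np.nan, np.nan, "NA", "no null estimate")
                )
            continue
        p_null = float(null_pool.min())
        cand_subjects = list(f.index[candidates])
        pvals = [
            stats.binom.cdf(int(cnt.at[s, gene]), int(totals[s]), p_null)
            for s in cand_subjects
        ]
        if pvals:
            qvals = multipletests(pvals, method="fdr_bh")[1]
        else:
            qvals = []
        qmap = dict(zip(cand_subjects, zip(pvals, qvals)))
        for subj in f.index:
            if subj in qmap:
                pv, qv = qmap[subj]
                call = "deleted_both" if qv < q_cutoff else "present"
                rows.append(
                    _row(subj, gene, cnt.at[subj, gene], totals[subj], p_null,
                         pv, qv, call, "")
                )
            else:
                rows.append(
                    _row(subj, gene, cnt.at[subj, gene], totals[subj], p_null,
                         np.nan, np.nan, "not_candidate", "")
                )
    return pd.DataFrame(rows)


def _row(subject, gene, x, N, p, pv, qv, call, reason):
    return {
        "subject": subject,
        "gene": gene,
        "x": int(x),
        "N": int(N),
        "p": p,
        "p_value": pv,
        "q_value": qv,
        "call": call,
        "reason": reason,
    }


@dataclass
class BimodalityResult:
    reliable: bool
    reason: str
    low_mean: float | None = None
    high_mean: float | None = None
    low_shape: float | None = None
    high_shape: float | None = None
    ecdf_x: np.ndarray | None = None
    ecdf_y: np.ndarray | None = None


def assess_usage_bimodality(
    values, split: float = 0.001, min_side: int = 3, mean_ratio: float = 5.0
) -> BimodalityResult:
    """Check that a gene's cohort usage is bimodal around ``split``.

    Gamma distributions are fitted by maximum likelihood to the values on each
    side of the split.  The verdict is "reliable" only when both sides hold at
    least ``min_side`` subjects and the fitted means differ by at least a
    factor of ``mean_ratio``.  Degenerate inputs (all zero, constant) are
    unreliable.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(v == 0):
        return BimodalityResult(False, "all_zero")
    xs = np.sort(v)
    ecdf_y = np.arange(1, v.size + 1) / v.size
    low = v[(v < split) & (v > 0)]
    high = v[v >= split]
    if low.size < min_side or high.size < min_side:
        return BimodalityResult(
            False, "insufficient_side", ecdf_x=xs, ecdf_y=ecdf_y
        )
    if np.ptp(low) == 0 or np.ptp(high) == 0:
        return BimodalityResult(False, "degenerate_fit", ecdf_x=xs, ecdf_y=ecdf_y)
    lo_a, _, lo_scale = stats.gamma.fit(low, floc=0)
    hi_a, _, hi_scale = stats.gamma.fit(high, floc=0)
    lo_mean, hi_mean = lo_a * lo_scale, hi_a * hi_scale
    ok = hi_mean >= mean_ratio * lo_mean
    return BimodalityResult(
        reliable=bool(ok),
        reason="" if ok else "means_too_close",
        low_mean=float(lo_mean),
        high_mean=float(hi_mean),
        low_shape=float(lo_a),
        high_shape=float(hi_a),
        ecdf_x=xs,
        ecdf_y=ecdf_y,
    )
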