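"""Sign test, deletion-usage thresholds, ratio CIs and Jaccard comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ighap import (
    estimate_single_deletion_thresholds,
    haplotype_jaccard,
    mean_ratio_ci,
    screen_anchor_candidates,
    sign_test_pvalue,
)
from ighap.popstats import allele_bias_sign_test
from ighap.prep import UsageTable


class TestSignTest:
    def test_all_same_direction(self):
        assert sign_test_pvalue(10, 10) == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_symmetric_case(self):
        assert sign_test_pvalue(3, 6) == pytest.approx(1.0, abs=1e-12)

    def test_partial_skew_matches_enumeration(self):
        # 2 * P(Bin(20, 0.5) >= 15) by direct enumeration
        expected = 2 * sum(math.comb(20, i) for i in range(15, 21)) / 2**20
        assert sign_test_pvalue(15, 20) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0414, abs=2e-4)

    def test_exhaustive_against_enumeration(self):
        """Closed form equals the enumerated two-sided tail for all n <= 30."""
        for n in range(1, 31):
            pmf = [math.comb(n, i) / 2**n for i in range(n + 1)]
            for k in range(n + 1):
                lower = sum(pmf[: k + 1])
                upper = sum(pmf[k:])
                expected = min(1.0, 2 * min(lower, upper))
                assert sign_test_pvalue(k, n) == pytest.approx(expected, rel=1e-10)


class TestAlleleBiasSignTest:
    def _cohort(self, n_subj=8, frac1=0.8, depth=20_000):
        rows, grows = [], []
        for i in range(n_subj):
            k1 = int(depth * 0.05 * frac1)
            k2 = int(depth * 0.05) - k1
            rows += [
                {"subject": f"S{i}", "locus": "IGHV", "gene": "IGHV3-23",
                 "allele": "01", "count": k1},
                {"subject": f"S{i}", "locus": "IGHV", "gene": "IGHV3-23",
                 "allele": "02", "count": k2},
                {"subject": f"S{i}", "locus": "IGHV", "gene": "IGHV1-2",
                 "allele": "01", "count": depth - k1 - k2},
            ]
            grows.append(
                {"subject": f"S{i}", "locus": "IGHV", "gene": "IGHV3-23",
                 "alleles": "01,02", "zygosity": "heterozygous",
                 "count": k1 + k2, "minor_fraction": min(frac1, 1 - frac1)}
            )
        return UsageTable.from_counts(pd.DataFrame(rows)), pd.DataFrame(grows)

    def test_consistent_bias_detected(self):
        usage, geno = self._cohort(n_subj=8, frac1=0.8)
        res = allele_bias_sign_test(usage, geno)
        row = res.iloc[0]
        assert (row["n"], row["k"]) == (8, 8)
        assert row["p_value"] == pytest.approx(2 * 0.5**8, abs=1e-12)

    def test_shallow_subjects_excluded(self):
        usage, geno = self._cohort(n_subj=8, depth=5000)
        res = allele_bias_sign_test(usage, geno, min_depth=10_000)
        assert res.empty

    def test_undersized_pair_untested(self):
        usage, geno = self._cohort(n_subj=3)
        res = allele_bias_sign_test(usage, geno, min_individuals=5)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p_value"].iloc[0])


def _haplotype_frame(assignments, subject="S1", counts=50):
    rows = []
    for gene, (a, b) in assignments.items():
        rows.append(
            {
                "subject": subject,
                "gene": gene,
                "alleles_chrA": a,
                "alleles_chrB": b,
                "counts_chrA": counts,
                "counts_chrB": counts,
                "lK": 20.0,
                "call_state": "assigned" if "deleted" not in (a, b) else "deleted",
            }
        )
    return pd.DataFrame(rows)


class TestHaplotypeJaccard:
    BASE = {f"G{i}": ("01", "02") for i in range(6)}

    def test_identical_haplotypes_zero(self):
        h = _haplotype_frame(self.BASE)
        d = haplotype_jaccard(h, h.copy())
        assert d.distance == 0.0
        assert d.genes_compared == 6

    def test_one_partial_gene(self):
        a = dict(self.BASE, G0=("01", "deleted"))
        b = dict(self.BASE, G0=("01,04", "deleted"))
        del a["G5"], b["G5"]  # 5 genes total
        d = haplotype_jaccard(_haplotype_frame(a), _haplotype_frame(b))
        assert d.distance == pytest.approx(0.1)

    def test_fully_disjoint_assignments(self):
        a = {f"G{i}": ("01", "01") for i in range(5)}
        b = {f"G{i}": ("03", "03") for i in range(5)}
        d = haplotype_jaccard(_haplotype_frame(a), _haplotype_frame(b))
        assert d.distance == 1.0

    def test_orientation_flip_recovered(self):
        """Swapped chromosome labels from a different anchor do not inflate distance."""
        a = {f"G{i}": ("01", "02") for i in range(6)}
        b = {f"G{i}": ("02", "01") for i in range(6)}
        d = haplotype_jaccard(_haplotype_frame(a), _haplotype_frame(b))
        assert d.distance == 0.0
        assert d.flipped

    def test_symmetry(self):
        a = _haplotype_frame(dict(self.BASE, G0=("01", "03")))
        b = _haplotype_frame(dict(self.BASE, G1=("04", "02")))
        assert haplotype_jaccard(a, b).distance == pytest.approx(
            haplotype_jaccard(b, a).distance
        )

    def test_low_linkage_genes_excluded(self):
        a = _haplotype_frame(self.BASE)
        b = _haplotype_frame(self.BASE, counts=1)  # 2 < min_linkages
        with pytest.raises(ValueError, match="insufficient overlap"):
            haplotype_jaccard(a, b)

    def test_insufficient_genes_error(self):
        small = {f"G{i}": ("01", "02") for i in range(3)}
        with pytest.raises(ValueError, match="insufficient overlap"):
            haplotype_jaccard(_haplotype_frame(small), _haplotype_frame(small))


class TestThresholds:
    def _usage_and_calls(self, mu0=0.02, mu1=0.01, sd=0.002, n=20, seed=3):
        rng = np.random.default_rng(seed)
        x0 = rng.normal(mu0, sd, n)
        x1 = rng.normal(mu1, sd, n)
        rows, calls = [], []
        for i, v in enumerate(np.concatenate([x0, x1])):
            subj = f"S{i}"
            c = max(1, int(v * 100_000))
            rows += [
                {"subject": subj, "locus": "IGHD", "gene": "IGHD3-10", "count": c},
                {"subject": subj, "locus": "IGHD", "gene": "IGHD1-1",
                 "count": 100_000 - c},
            ]
            deleted = i >= n
            calls.append(
                {
                    "subject": subj,
                    "gene": "IGHD3-10",
                    "alleles_chrA": "01",
                    "alleles_chrB": "deleted" if deleted else "02",
                    "counts_chrA": c,
                    "counts_chrB": 0 if deleted else c,
                    "lK": 15.0,
                    "call_state": "deleted_chrB" if deleted else "assigned",
                }
            )
        return UsageTable.from_counts(pd.DataFrame(rows)), pd.DataFrame(calls)

    def test_threshold_between_means_with_exact_model_fpr(self):
        usage, calls = self._usage_and_calls()
        models, rocs = estimate_single_deletion_thresholds(usage, calls)
        row = models[(models["gene"] == "IGHD3-10") & (models["alpha"] == 0.05)].iloc[0]
        assert 0.01 < row["threshold"] < 0.02
        # model-based FPR at the reported threshold is alpha by construction
        fpr = stats.t.cdf((row["threshold"] - row["mu0"]) / row["sd0"], row["n0"] - 1)
        assert fpr == pytest.approx(0.05, abs=1e-9)
        assert row["sensitivity"] > 0.9
        assert "IGHD3-10" in rocs

    def test_alpha_ordering(self):
        """The α=0.01 threshold is never more permissive than α=0.05."""
        usage, calls = self._usage_and_calls(seed=9)
        models, _ = estimate_single_deletion_thresholds(usage, calls)
        t01 = models[models["alpha"] == 0.01]["threshold"].iloc[0]
        t05 = models[models["alpha"] == 0.05]["threshold"].iloc[0]
        assert t01 <= t05

    def test_identical_groups_sensitivity_near_alpha(self):
        usage, calls = self._usage_and_calls(mu0=0.015, mu1=0.015, seed=5)
        models, _ = estimate_single_deletion_thresholds(usage, calls)
        row = models[models["alpha"] == 0.05].iloc[0]
        assert row["sensitivity"] == pytest.approx(0.05, abs=0.06)

    def test_degenerate_group_skipped(self):
        usage, calls = self._usage_and_calls()
        # force one group constant
        frac = usage.gene_usage
        mask = frac["gene"] == "IGHD3-10"
        first_subjects = [f"S{i}" for i in range(20)]
        frac.loc[mask & frac["subject"].isin(first_subjects), "fraction"] = 0.02
        models, _ = estimate_single_deletion_thresholds(usage, calls)
        assert (models["skipped"] == "degenerate_fit").any()

    def test_insufficient_group_skipped(self):
        usage, calls = self._usage_and_calls()
        calls = calls[calls["call_state"] == "assigned"]  # no 1-deletion group
        models, _ = estimate_single_deletion_thresholds(usage, calls)
        assert (models["skipped"] == "insufficient_group").any()


class TestMeanRatioCI:
    def test_point_estimate(self):
        r, lo, hi = mean_ratio_ci([0.02] * 5 + [0.021] * 5, [0.01] * 5 + [0.0105] * 5)
        assert r == pytest.approx(2.0, rel=1e-3)

    def test_identical_groups_ci_contains_one(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0.02, 0.002, 20)
        y = rng.normal(0.02, 0.002, 20)
        r, lo, hi = mean_ratio_ci(x, y)
        assert lo < 1 < hi

    def test_coverage_under_true_ratio_two(self):
        """95% CI covers the true ratio 2 in ≥90/100 seeded replicates."""
        rng = np.random.default_rng(42)
        covered = 0
        for _ in range(100):
            x0 = rng.normal(0.02, 0.004, 20)
            x1 = rng.normal(0.01, 0.002, 20)
            _, lo, hi = mean_ratio_ci(x0, x1)
            covered += lo <= 2.0 <= hi
        assert covered >= 90

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mean_ratio_ci([1.0, 2.0], [-1.0, 0.5])


class TestScreenAnchors:
    def _genotypes(self):
        return pd.DataFrame(
            [
                {"subject": "S1", "locus": "IGHD", "gene": "IGHD2-21",
                 "alleles": "01,02", "zygosity": "heterozygous", "count": 200,
                 "minor_fraction": 0.35},
                {"subject": "S2", "locus": "IGHD", "gene": "IGHD2-21",
                 "alleles": "01,02", "zygosity": "heterozygous", "count": 200,
                 "minor_fraction": 0.20},
                {"subject": "S3", "locus": "IGHD", "gene": "IGHD2-2",
                 "alleles": "01", "zygosity": "homozygous", "count": 200,
                 "minor_fraction": 0.0},
            ]
        )

    def test_minor_fraction_screen(self):
        eligible, _ = screen_anchor_candidates(self._genotypes())
        assert list(eligible["subject"]) == ["S1"]

    def test_wilcoxon_comparison(self):
        rng = np.random.default_rng(8)
        dist = pd.DataFrame(
            {
                "minor_fraction": [0.4] * 10 + [0.1] * 10,
                "distance": np.concatenate(
                    [rng.uniform(0, 0.1, 10), rng.uniform(0.3, 0.8, 10)]
                ),
            }
        )
        _, p = screen_anchor_candidates(self._genotypes(), dist)
        assert p is not None and p < 0.01

    def test_undersized_comparison_is_na(self):
        dist = pd.DataFrame({"minor_fraction": [0.4, 0.4, 0.1], "distance": [0.1] * 3})
        _, p = screen_anchor_candidates(self._genotypes(), dist)
        assert p is None
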