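"""Rank-sum test, group selection, and boxplot summaries."""

import io
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from bifscan.expression_compare import (
    boxplot_summary,
    mann_whitney,
    read_expression_tsv,
    select_groups,
)
from bifscan.locus_partition import partition_loci
from bifscan.probe_mapping import match_probes
from bifscan.synthetic_data import SynthConfig, generate


def oracle_exact_p(a, b):
    """Brute-force two-sided p: U via pairwise comparisons, enumerated over
    every assignment of the pooled values to the first group."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group1, group2):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in group1 for y in group2
        )

    u_obs = u_stat(a, b)
    idx_all = set(range(len(pooled)))
    le = ge = total = 0
    for idx in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in idx_all - set(idx)]
        u = u_stat(g1, g2)
        le += u <= u_obs + 1e-9
        ge += u >= u_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


class TestMannWhitney:
    def test_identical_groups_symmetric(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.U == 4.5
        assert r.p_two_sided == 1.0

    def test_interleaved_exact_matches_enumeration(self):
        a, b = [1, 3, 5], [2, 4, 6]
        r = mann_whitney(a, b)
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(oracle_exact_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 4), (4, 4), (5, 3), (6, 2)])
    def test_exact_equals_oracle_random_with_ties(self, rng, n1, n2):
        for _ in range(5):
            a = rng.integers(0, 4, size=n1).astype(float)  # heavy ties
            b = rng.integers(0, 4, size=n2).astype(float)
            r = mann_whitney(list(a), list(b))
            assert r.method == "exact"
            assert r.p_two_sided == pytest.approx(oracle_exact_p(a, b), abs=1e-12)

    def test_complement_identity(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=7)
        assert mann_whitney(a, b).U + mann_whitney(b, a).U == pytest.approx(9 * 7)

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=25) + 0.5
        p1 = mann_whitney(a, b).p_two_sided
        p2 = mann_whitney(np.exp(a), np.exp(b)).p_two_sided
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_all_tied(self):
        r = mann_whitney([2.0] * 5, [2.0] * 4)
        assert r.degenerate and r.p_two_sided == 1.0

    def test_normal_approx_agrees_with_scipy(self, rng):
        """Cross-check the tie-corrected normal path against an independent
        implementation on data with and without ties."""
        for data in (rng.normal(size=(2, 60)), rng.integers(0, 8, size=(2, 60))):
            a, b = data[0], data[1].astype(float) + 0.3
            ours = mann_whitney(a, b, exact_cap=1)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_close_to_normal_approx_n8(self, rng):
        # near p ~ 0.5 the discrete point mass P(U = u) itself is ~0.01, so
        # agreement is to 0.02 overall and to 0.01 where decisions are made
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(size=8)
            exact = mann_whitney(a, b).p_two_sided
            approx = mann_whitney(a, b, exact_cap=1).p_two_sided
            assert abs(exact - approx) < 0.02
            if exact < 0.3:
                assert abs(exact - approx) < 0.01

    def test_u_bounds_and_rank_definition(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=15)
        r = mann_whitney(a, b)
        assert 0 <= r.U <= 12 * 15
        ranks = rankdata(np.concatenate([a, b]))
        assert r.U == pytest.approx(ranks[:12].sum() - 12 * 13 / 2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_type_one_error_rate(self, rng):
        """Null rejection rate at alpha=0.05 over identically distributed groups."""
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            rejections += mann_whitney(a, b).p_two_sided < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se

    def test_power_under_one_sd_shift(self, rng):
        """A one-pooled-SD shift at n=100 per group is detected essentially always."""
        hits = sum(
            mann_whitney(rng.normal(size=100), rng.normal(size=100) + 1.0).p_two_sided
            < 0.05
            for _ in range(50)
        )
        assert hits >= 50 * 0.99


class TestBoxplotSummary:
    def test_simple_quartiles(self):
        s = boxplot_summary([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)

    def test_constant_vector_no_outliers(self):
        s = boxplot_summary([7.0] * 10)
        assert s.q3 - s.q1 == 0 and s.outliers == ()

    def test_against_sort_based_oracle(self, rng):
        x = rng.normal(size=101)
        s = boxplot_summary(x)
        xs = np.sort(x)
        assert s.minimum == xs[0] and s.maximum == xs[-1]
        assert s.median == pytest.approx(xs[50])
        assert s.q1 == pytest.approx(np.percentile(x, 25))
        iqr = s.q3 - s.q1
        expected_out = xs[(xs < s.q1 - 1.5 * iqr) | (xs > s.q3 + 1.5 * iqr)]
        assert np.allclose(s.outliers, expected_out)


class TestSelectGroups:
    def test_planted_membership_recovered(self):
        """Group membership from the matrix equals the generator's plan."""
        bundle = generate(SynthConfig(n_genes=60, rng_seed=21, delta=0.0))
        reports = match_probes(bundle.probes, bundle.transcripts, bundle.genome)
        part = partition_loci(bundle.transcripts)
        probe_gene = {p.probe_id: p.declared_gene for p in bundle.probes}
        a, b = select_groups(bundle.expression, reports, part, probe_gene,
                             rule="locus_class")
        from bifscan.locus_partition import LocusClass

        truth_a = [p for p, t in bundle.truth.probes.items()
                   if bundle.truth.gene_class[t.gene] is LocusClass.CODING_ONLY]
        truth_b = [p for p, t in bundle.truth.probes.items()
                   if bundle.truth.gene_class[t.gene] is LocusClass.NONCODING_ONLY]
        assert a.size == len(truth_a)
        assert b.size == len(truth_b)

    def test_missing_probe_rows_dropped(self):
        bundle = generate(SynthConfig(n_genes=40, rng_seed=22))
        reports = match_probes(bundle.probes, bundle.transcripts, bundle.genome)
        part = partition_loci(bundle.transcripts)
        probe_gene = {p.probe_id: p.declared_gene for p in bundle.probes}
        full_a, full_b = select_groups(bundle.expression, reports, part, probe_gene,
                                       rule="locus_class")
        trimmed = bundle.expression.iloc[5:]
        a, b = select_groups(trimmed, reports, part, probe_gene, rule="locus_class")
        assert a.size + b.size >= full_a.size + full_b.size - 5

    def test_empty_group_raises_actionable_error(self):
        bundle = generate(SynthConfig(n_genes=30, rng_seed=23,
                                      frac_bifunctional=0.0, frac_coding_only=0.7,
                                      frac_noncoding_only=0.3))
        reports = match_probes(bundle.probes, bundle.transcripts, bundle.genome)
        part = partition_loci(bundle.transcripts)
        probe_gene = {p.probe_id: p.declared_gene for p in bundle.probes}
        with pytest.raises(ValueError, match="relax"):
            select_groups(bundle.expression, reports, part, probe_gene)


def test_read_expression_tsv_na_and_duplicates():
    good = "probe_id\tS1\tS2\np1\t1.0\tNA\np2\t2.0\t3.0\n"
    df = read_expression_tsv(io.StringIO(good))
    assert np.isnan(df.loc["p1", "S2"])
    dup = "probe_id\tS1\np1\t1.0\np1\t2.0\n"
    with pytest.raises(ValueError, match="duplicate"):
        read_expression_tsv(io.StringIO(dup))
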