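import math

import numpy as np
import pytest
from scipy import stats

from poolseq import PoolDesign, SiteEvidence, call_variants, cross_pool_test, pool_error_pvalue
from poolseq.caller import DataIntegrityError
from poolseq.pileup import RawSiteObservations, filter_read_evidence
from poolseq.simulate import null_truth, simulate_site_counts


def direct_binomial_tail(k: int, n: int, p: float) -> float:
    """Oracle: P(X >= k) by explicit summation of the binomial pmf."""
    terms = []
    logp, log1p = math.log(p), math.log1p(-p)
    for i in range(k, n + 1):
        lg = (
            math.lgamma(n + 1)
            - math.lgamma(i + 1)
            - math.lgamma(n - i + 1)
            + i * logp
            + (n - i) * log1p
        )
        terms.append(math.exp(lg))
    return math.fsum(sorted(terms))


class TestPoolErrorPvalue:
    def test_zero_alt_reads(self):
        assert pool_error_pvalue(0, 400, 0.01) == 1.0

    def test_full_depth_vanishes_with_error(self):
        p = pool_error_pvalue(100, 100, 1e-4)
        assert p < 1e-300 or p == 0.0

    @pytest.mark.parametrize("k,n,e", [(10, 400, 0.01), (4, 600, 0.005), (25, 683, 0.0075)])
    def test_matches_direct_summation(self, k, n, e):
        """The tail routine agrees with explicit pmf summation to 1e-12
        relative (SNV per-alternative-base rate e/3)."""
        got = pool_error_pvalue(k, n, e, var_type="SNV")
        want = direct_binomial_tail(k, n, e / 3.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_indel_uses_indel_error_rate(self):
        got = pool_error_pvalue(5, 500, 0.01, var_type="deletion", indel_error_rate=1e-4)
        want = direct_binomial_tail(5, 500, 1e-4)
        assert got == pytest.approx(want, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            pool_error_pvalue(10, 5, 0.01)


class TestCrossPoolTest:
    def test_homogeneous_fractions_give_large_p(self):
        p = cross_pool_test([40, 40, 40, 40, 40], [400] * 5)
        assert p > 0.5

    def test_concentrated_alt_reads_give_tiny_p(self):
        """All 20 alt reads in one of five equal-depth pools; the exact
        multivariate hypergeometric probability of so extreme a table is
        far below 1e-6 (independent oracle: the most-extreme-table bound)."""
        p = cross_pool_test([20, 0, 0, 0, 0], [400] * 5)
        assert p < 1e-6
        # oracle bound: p >= probability of the observed table itself
        obs = math.comb(400, 20) / math.comb(2000, 20)
        assert p >= obs

    def test_two_pool_case_matches_fisher_exact(self):
        """With two pools the exact branch is Fisher's exact test."""
        for alts, deps in [([8, 1], [200, 220]), ([3, 5], [100, 100])]:
            table = [[alts[0], deps[0] - alts[0]], [alts[1], deps[1] - alts[1]]]
            _, want = stats.fisher_exact(table, alternative="two-sided")
            got = cross_pool_test(alts, deps)
            assert got == pytest.approx(want, rel=1e-9)

    def test_degenerate_tables(self):
        assert cross_pool_test([0, 0, 0], [400, 400, 400]) == 1.0
        assert math.isnan(cross_pool_test([5], [400]))
        assert math.isnan(cross_pool_test([5, 0], [400, 0]))

    def test_pool_permutation_invariance(self):
        alts = [50, 3, 7, 2, 1]
        deps = [600, 650, 700, 550, 620]
        p0 = cross_pool_test(alts, deps, seed=3)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(5)
            assert cross_pool_test(
                [alts[i] for i in perm], [deps[i] for i in perm], seed=3
            ) == pytest.approx(p0)

    def test_permutation_branch_deterministic(self):
        alts = [60, 5, 4, 6, 5]  # total > exact threshold
        deps = [600] * 5
        assert cross_pool_test(alts, deps, seed=9) == cross_pool_test(alts, deps, seed=9)

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(DataIntegrityError):
            cross_pool_test([10, 500], [400, 400])


def _evidence(alts, depths, err=0.0075, pos=100, var_type="SNV"):
    return SiteEvidence(
        contig="t",
        position=pos,
        ref_allele="A",
        alt_allele="C",
        depths=tuple(depths),
        alt_counts=tuple(alts),
        mean_error_probs=tuple([err] * len(depths)),
        var_type=var_type,
    )


class TestCallVariants:
    def test_three_alt_reads_everywhere_fails_support_floor(self, design):
        """Fewer than 4 alt reads in every pool can never be called."""
        ev = _evidence([3, 3, 3, 3, 3], [600] * 5)
        (call,) = call_variants([ev], design)
        assert call.filter_status == "min_alt_fail"
        assert not call.passed

    def test_no_alt_reads_is_not_a_candidate(self, design):
        ev = _evidence([0, 0, 0, 0, 0], [600] * 5)
        assert call_variants([ev], design) == []

    def test_strong_singleton_passes(self, design):
        ev = _evidence([15, 1, 0, 2, 1], [600] * 5)
        (call,) = call_variants([ev], design)
        assert call.passed
        assert call.p_error < 1e-4
        assert call.p_pool < 1e-3

    def test_dispersed_error_like_site_fails(self, design):
        """Alt reads spread evenly at error-rate levels fail the caller."""
        ev = _evidence([5, 4, 5, 4, 5], [600] * 5, err=0.02)
        (call,) = call_variants([ev], design)
        assert not call.passed

    def test_common_variant_rescued_despite_homogeneity(self, design):
        """A variant at similar high frequency in all pools is homogeneous
        across pools but must still be called."""
        ev = _evidence([120, 130, 118, 125, 122], [600] * 5)
        (call,) = call_variants([ev], design)
        assert call.passed

    def test_alt_above_depth_rejected(self, design):
        with pytest.raises(DataIntegrityError):
            _evidence([700, 0, 0, 0, 0], [600] * 5)

    def test_every_candidate_reported_once_with_definite_status(self, design):
        t = simulate_site_counts(null_truth(design, 2000), design, seed=3)
        calls = call_variants(t, design, seed=3)
        candidates = int((t.alt.sum(axis=1) > 0).sum())
        assert len(calls) == candidates
        assert {c.filter_status for c in calls} <= {"PASS", "min_alt_fail", "stat_fail"}
        keys = [c.key for c in calls]
        assert len(keys) == len(set(keys))

    def test_null_error_pvalues_are_superuniform(self, design):
        """On monomorphic sites, P(p_error <= a) <= a (discreteness makes
        the binomial tail conservative)."""
        t = simulate_site_counts(
            null_truth(design, 20_000), design, error_rate=0.0075, seed=5
        )
        calls = call_variants(t, design, seed=5)
        pvals = np.array([p for c in calls for p in c.p_error_per_pool])
        for a in (0.1, 0.01):
            assert (pvals <= a).mean() <= a * 1.3 + 1e-3

    def test_monotone_power_in_depth_and_copies(self, design):
        """PASS probability rises with depth and with carrier copies."""
        from poolseq.simulate import TruthVariant

        def power(copies, depth, seed=11):
            truth = [
                TruthVariant("t", 10 * (i + 1), "A", "C", "SNV",
                             (copies, 0, 0, 0, 0), copies / 200)
                for i in range(300)
            ]
            t = simulate_site_counts(
                truth, design, mean_coverage_per_pool=depth,
                coverage_dispersion=None, error_rate=0.0075, seed=seed,
            )
            calls = call_variants(t, design, seed=seed)
            passed = {c.evidence.position for c in calls if c.passed}
            return len(passed) / len(truth)

        assert power(1, 200) <= power(1, 600) + 0.05
        assert power(1, 600) <= power(3, 600) + 0.05
        assert power(3, 600) > 0.95

    def test_pool_order_symmetry(self, design):
        ev = _evidence([15, 1, 0, 2, 1], [600, 650, 700, 550, 620])
        ev_perm = _evidence([1, 15, 1, 2, 0], [650, 600, 620, 550, 700])
        (c1,) = call_variants([ev], design)
        (c2,) = call_variants([ev_perm], design)
        assert c1.filter_status == c2.filter_status
        assert c1.p_pool == pytest.approx(c2.p_pool)


class TestFilterReadEvidence:
    def _obs(self, bases, bqs, mqs):
        return RawSiteObservations(
            contig="t", position=10, ref_allele="A",
            bases=[bases], base_quals=[bqs], map_quals=[mqs],
        )

    def test_all_low_mapq_leaves_site_unevaluable(self):
        obs = self._obs(list("ACAC"), [30] * 4, [19] * 4)
        assert filter_read_evidence(obs) == []

    def test_boundary_qualities_retained(self):
        """MAPQ 20 and BQ 10 are kept: the cut is strictly less-than."""
        obs = self._obs(list("AACC"), [10, 10, 10, 10], [20, 20, 20, 20])
        (ev,) = filter_read_evidence(obs)
        assert ev.depths == (4,)
        assert ev.alt_counts == (2,)
        assert ev.discarded == (0,)
        assert ev.mean_error_probs[0] == pytest.approx(0.1)

    def test_mixed_qualities_counted(self):
        bases = list("AAAAAAACCC")
        mqs = [5, 5, 5] + [60] * 7
        obs = self._obs(bases, [35] * 10, mqs)
        (ev,) = filter_read_evidence(obs)
        assert ev.depths == (7,)
        assert ev.discarded == (3,)

    def test_multiallelic_sites_ranked_by_support(self):
        obs = self._obs(list("AAAACCCG"), [35] * 8, [60] * 8)
        evs = filter_read_evidence(obs)
        assert [e.alt_allele for e in evs] == ["C", "G"]
        assert evs[0].alt_counts == (3,)
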