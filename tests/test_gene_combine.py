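"""SNP filters, gene assignment, and the dependence-corrected Lancaster
combination."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from asepop import (
    PermutationConfig,
    ScoreTestEngine,
    SimConfig,
    combine_gene,
    fdr_correct,
    hwe_test,
    lancaster_statistic,
    lancaster_weights,
    permutation_covariance,
    resolve_gene_assignment,
    simulate_snp,
)
from asepop.dad_tests import fit_and_test
from asepop.gene_combine import FilterThresholds, apply_snp_filters
from asepop.mixture_em import putative_het_mask


class TestHwe:
    def test_exact_proportions_pass(self):
        stat, p = hwe_test([25, 50, 25], f_inbr=0.0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_no_heterozygotes_fails_hard(self):
        stat, p = hwe_test([50, 0, 50], f_inbr=0.0)
        # chi-square oracle: expected (25, 50, 25) -> stat = 100
        assert stat == pytest.approx(100.0, abs=1e-9)
        assert p < 0.001

    def test_inbreeding_adjustment_rescues_deficit(self):
        # a moderate het deficit matches expectations once F > 0
        counts = [30, 40, 30]
        _, p_panmictic = hwe_test(counts, f_inbr=0.0)
        _, p_inbred = hwe_test(counts, f_inbr=0.2)
        assert p_inbred > p_panmictic


class TestSnpFilters:
    @staticmethod
    def _result(**kw):
        from asepop.dad_tests import SnpDadResult

        base = dict(lambda_lrt=1.0, p_dad=0.3, rho_control=0.02,
                    rho_case=0.03, pi_het=0.5, n_het_control=20,
                    n_het_case=40, median_n_control=30, median_n_case=30,
                    filter_flags=[])
        base.update(kw)
        return SnpDadResult(**base)

    def test_extreme_pi_fails_regardless(self):
        status = apply_snp_filters(self._result(pi_het=0.97),
                                   [25, 50, 25], [25, 50, 25], 0.0)
        assert not status.pass_pi_bounds
        assert not status.overall

    def test_overall_is_conjunction(self):
        status = apply_snp_filters(self._result(), [25, 50, 25],
                                   [25, 50, 25], 0.0)
        assert status.overall == (status.pass_median_count
                                  and status.pass_n_het
                                  and status.pass_pi_bounds
                                  and status.pass_hwe)
        assert status.overall

    def test_x_stratum_relaxes_het_threshold(self):
        res = self._result(n_het_control=9, n_het_case=40)
        auto = apply_snp_filters(res, [25, 50, 25], [25, 50, 25], 0.0,
                                 stratum="autosomal")
        x = apply_snp_filters(res, [25, 50, 25], [25, 50, 25], 0.0,
                              stratum="X")
        assert not auto.pass_n_het and x.pass_n_het

    def test_hwe_failure_blocks(self):
        status = apply_snp_filters(self._result(), [50, 0, 50],
                                   [25, 50, 25], 0.0)
        assert not status.pass_hwe and not status.overall


class TestGeneAssignment:
    def test_hierarchy_and_ties(self):
        ann = pd.DataFrame({
            "snp_id": ["s1", "s1", "s2", "s2", "s3"],
            "gene_id": ["geneA", "geneB", "geneA", "geneB", "geneC"],
            "category": ["exonic", "intronic_splice", "exonic", "exonic",
                         "up_downstream"],
        })
        out = resolve_gene_assignment(ann)
        assigned = dict(zip(out["snp_id"], out["gene_id"]))
        assert assigned == {"s1": "geneA", "s3": "geneC"}  # s2 tied: dropped

    def test_unknown_category_rejected(self):
        ann = pd.DataFrame({"snp_id": ["s"], "gene_id": ["g"],
                            "category": ["weird"]})
        with pytest.raises(ValueError):
            resolve_gene_assignment(ann)


class TestWeights:
    def test_equal_raw_weights_normalize_to_two(self):
        w = lancaster_weights([10, 10], [20, 20], [30, 30], [30, 30])
        np.testing.assert_allclose(w, [2.0, 2.0])

    def test_singleton_weight_is_two(self):
        np.testing.assert_allclose(
            lancaster_weights([10], [20], [30], [30]), [2.0])

    def test_proportional_rescale(self):
        # limiting-group raw weights 10 and 30 -> rescaled (1, 3)
        w = lancaster_weights([1, 3], [100, 100], [10, 10], [50, 50])
        np.testing.assert_allclose(w, [1.0, 3.0])

    def test_zero_weight_signaled(self):
        with pytest.raises(ValueError):
            lancaster_weights([0, 1], [1, 1], [10, 10], [10, 10])


class TestLancasterStatistic:
    def test_all_null_pvalues_give_zero(self):
        assert lancaster_statistic([1.0, 1.0], [2.0, 2.0]) == pytest.approx(
            0.0, abs=1e-12)

    def test_fisher_special_case(self):
        t = lancaster_statistic([0.5, 0.5], [2.0, 2.0])
        assert t == pytest.approx(-2 * np.log(0.25), abs=1e-10)

    def test_weighted_quantile_oracle(self):
        from scipy.stats import gamma

        p, w = [0.01, 0.2], [3.0, 1.0]
        expected = sum(gamma.isf(pi, a=wi / 2, scale=2.0)
                       for pi, wi in zip(p, w))
        assert lancaster_statistic(p, w) == pytest.approx(expected, rel=1e-12)


class TestCombine:
    def test_independence_reduces_to_fisher(self):
        p, w = [0.03, 0.4, 0.7], [2.0, 2.0, 2.0]
        res = combine_gene("g", list("abc"), p, w, covar_sum=0.0)
        fisher_stat = -2 * np.sum(np.log(p))
        assert res.v == pytest.approx(6.0)
        assert res.c == pytest.approx(1.0)
        assert res.p_gene == pytest.approx(chi2.sf(fisher_stat, 6), abs=1e-10)

    def test_covariance_strictly_weakens_evidence(self):
        p, w = [0.01, 0.02], [2.0, 2.0]
        prev = 0.0
        last = combine_gene("g", list("ab"), p, w, 0.0).p_gene
        for cs in (1.0, 2.0, 4.0):
            cur = combine_gene("g", list("ab"), p, w, cs).p_gene
            assert cur > last
            last = cur

    def test_negative_variance_signaled(self):
        with pytest.raises(ValueError):
            combine_gene("g", ["a"], [0.5], [2.0], covar_sum=-10.0)


@pytest.fixture(scope="module")
def fitted_snp():
    cfg = SimConfig(n_control=150, n_case=150, rho_het_control=0.05,
                    rho_het_case=0.05, allele_freq=0.4, seed=21)
    frame, _ = simulate_snp(cfg)
    x_r = frame["ref_count"].to_numpy()
    x_v = frame["var_count"].to_numpy()
    case = (frame["group"] == "case").to_numpy()
    fit_null, fit_alt, res = fit_and_test(x_r, x_v, case, se=0.002)
    return fit_null, res, case


class TestPermutationCovariance:
    def test_single_snp_has_no_pairs(self, fitted_snp):
        fit_null, res, case = fitted_snp
        engine = ScoreTestEngine.from_fit(fit_null)
        het = putative_het_mask(fit_null)
        cs, transformed = permutation_covariance(
            [engine], [het], [2.0], PermutationConfig(n_iter=100, seed=1),
            case)
        assert cs == 0.0
        assert transformed.shape == (100, 1)

    def test_seeded_reproducibility(self, fitted_snp):
        fit_null, res, case = fitted_snp
        engine = ScoreTestEngine.from_fit(fit_null)
        het = putative_het_mask(fit_null)
        args = ([engine, engine], [het, het], [2.0, 2.0],
                PermutationConfig(n_iter=150, seed=42), case)
        cs1, t1 = permutation_covariance(*args)
        cs2, t2 = permutation_covariance(*args)
        assert cs1 == cs2
        np.testing.assert_array_equal(t1, t2)

    def test_duplicated_snp_fully_correlated(self, fitted_snp):
        fit_null, res, case = fitted_snp
        engine = ScoreTestEngine.from_fit(fit_null)
        het = putative_het_mask(fit_null)
        cs, _ = permutation_covariance(
            [engine, engine], [het, het], [2.0, 2.0],
            PermutationConfig(n_iter=500, seed=7), case)
        # identical counts: covariance equals the transform variance (~4)
        assert 2.0 < cs < 7.0
        res_g = combine_gene("g", ["a", "a2"], [res.p_dad] * 2,
                             [2.0, 2.0], cs)
        assert 1.5 < res_g.v < 2.7
        # evidence is not double-counted relative to the single SNP
        assert res_g.p_gene == pytest.approx(res.p_dad, abs=0.12)

    def test_independent_snps_near_zero_covariance(self, fitted_snp):
        fit_null, res, case = fitted_snp
        cfg2 = SimConfig(n_control=150, n_case=150, rho_het_control=0.05,
                         rho_het_case=0.05, allele_freq=0.4, seed=22)
        frame2, _ = simulate_snp(cfg2)
        fit2, _, _ = fit_and_test(frame2["ref_count"].to_numpy(),
                                  frame2["var_count"].to_numpy(),
                                  case, se=0.002)
        engines = [ScoreTestEngine.from_fit(fit_null),
                   ScoreTestEngine.from_fit(fit2)]
        hets = [putative_het_mask(fit_null), putative_het_mask(fit2)]
        _, transformed = permutation_covariance(
            engines, hets, [2.0, 2.0],
            PermutationConfig(n_iter=500, seed=3), case)
        cov = np.cov(transformed, rowvar=False)[0, 1]
        se_cov = np.std(transformed[:, 0] * transformed[:, 1]) / np.sqrt(500)
        assert abs(cov) < 3 * se_cov + 0.5


class TestFdr:
    def test_single_gene_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_bh_hand_computation(self):
        adj = fdr_correct([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_strata_are_independent(self):
        p = [0.01, 0.02, 0.03, 0.01, 0.02, 0.03]
        strata = ["a", "a", "a", "x", "x", "x"]
        adj = fdr_correct(p, strata)
        np.testing.assert_allclose(adj[:3], adj[3:])
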