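"""Genotype-mixture EM: recovery, constraints, degeneracies, outliers."""

import numpy as np
import pytest

from asepop import SimConfig, detect_outliers, fit_mixture, simulate_snp
from asepop.mixture_em import putative_het_mask


def _sim_counts(seed, **kw):
    cfg = SimConfig(seed=seed, **kw)
    frame, truth = simulate_snp(cfg)
    return (frame["ref_count"].to_numpy(), frame["var_count"].to_numpy(),
            (frame["group"] == "case").to_numpy(), truth)


class TestFit:
    def test_parameter_recovery(self):
        x_r, x_v, case, _ = _sim_counts(
            42, n_control=200, n_case=200, allele_freq=0.5, se=0.002,
            pi_het=0.5, rho_het_control=0.02, rho_het_case=0.02)
        fit = fit_mixture(x_r, x_v, case_mask=case, se=0.002)
        assert fit.pi_het == pytest.approx(0.5, abs=0.02)
        assert fit.rho_het_control == pytest.approx(0.02, rel=0.5)
        assert fit.phi_rr == pytest.approx(0.25, abs=0.05)
        assert fit.phi_rv == pytest.approx(0.5, abs=0.05)
        assert fit.converged

    def test_all_reference_homozygous_is_unidentifiable(self):
        n = np.full(20, 30)
        fit = fit_mixture(n, np.zeros(20), se=0.002)
        assert fit.phi_rr > 0.95
        assert fit.unidentifiable

    def test_label_swap_symmetry(self):
        x_r, x_v, case, _ = _sim_counts(
            7, n_control=100, n_case=100, pi_het=0.4)
        fit = fit_mixture(x_r, x_v, case_mask=case, se=0.002)
        mirrored = fit_mixture(x_v, x_r, case_mask=case, se=0.002)
        assert mirrored.pi_het == pytest.approx(1.0 - fit.pi_het, abs=1e-3)
        assert mirrored.rho_het_control == pytest.approx(
            fit.rho_het_control, abs=1e-3)
        assert mirrored.phi_rr == pytest.approx(fit.phi_vv, abs=1e-6)
        assert mirrored.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_responsibilities_are_proper(self):
        x_r, x_v, case, _ = _sim_counts(9, n_control=80, n_case=80)
        fit = fit_mixture(x_r, x_v, case_mask=case, se=0.002)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert fit.phi_rr + fit.phi_rv + fit.phi_vv == pytest.approx(
            1.0, abs=1e-9)

    def test_constrained_equal_dispersion_matches_shared_fit(self):
        x_r, x_v, case, _ = _sim_counts(13, n_control=120, n_case=120)
        shared = fit_mixture(x_r, x_v, case_mask=case, se=0.002)
        warm = (shared.phi, shared.pi_het, shared.theta_het_control,
                shared.theta_het_control, shared.theta_hom)
        split = fit_mixture(x_r, x_v, case_mask=case, se=0.002,
                            group_specific_rho=True, init=warm)
        # the group-specific optimum can only improve on the shared one
        assert split.loglik >= shared.loglik - 1e-6

    def test_accepted_fits_are_unimodal(self):
        # strongly bimodal heterozygote data (near-monoallelic either way)
        rng = np.random.default_rng(3)
        n = np.full(60, 40)
        skew = rng.random(60) < 0.5
        x = np.where(skew, rng.binomial(n, 0.95), rng.binomial(n, 0.05))
        fit = fit_mixture(x, n - x, se=0.002)
        cap = max(fit.pi_het, 1.0 - fit.pi_het)
        assert fit.theta_het_control <= cap * (1 + 1e-6)

    def test_requires_labels_for_group_specific(self):
        with pytest.raises(ValueError):
            fit_mixture([5, 6], [5, 4], group_specific_rho=True)


class TestHetCounts:
    def test_het_responsibility_sums_per_group(self):
        x_r, x_v, case, truth = _sim_counts(
            21, n_control=150, n_case=150, allele_freq=0.5)
        fit = fit_mixture(x_r, x_v, case_mask=case, se=0.002)
        true_het = truth["genotypes"] == 1
        assert fit.n_het_control == pytest.approx(
            true_het[~case].sum(), rel=0.15)
        assert fit.n_het_case == pytest.approx(true_het[case].sum(), rel=0.15)
        het = putative_het_mask(fit)
        assert het.sum() == pytest.approx(true_het.sum(), rel=0.15)


class TestOutliers:
    def test_planted_influential_sample_is_flagged(self):
        # a deep, strongly skewed sample still inside the heterozygote
        # component dominates the dispersion estimate and must be flagged
        rng = np.random.default_rng(17)
        n = np.full(60, 40)
        x = rng.binomial(n, rng.beta(24.5, 24.5, 60))  # balanced hets
        x_r = np.append(x, 170)
        x_v = np.append(n - x, 30)
        report = detect_outliers(x_r, x_v, se=0.002)
        assert 60 in report.flagged

    def test_clean_homozygote_absorbed_not_flagged(self):
        # a pure-homozygote sample is explained by the homozygote mixture
        # component and leaves the heterozygote parameters untouched
        rng = np.random.default_rng(17)
        n = np.full(60, 40)
        x = rng.binomial(n, rng.beta(24.5, 24.5, 60))
        report = detect_outliers(np.append(x, 200), np.append(n - x, 0),
                                 se=0.002)
        assert report.flagged == []

    def test_exchangeable_samples_not_flagged(self):
        x_r = np.tile([20, 5, 35], 5)
        x_v = np.tile([20, 35, 5], 5)
        report = detect_outliers(x_r, x_v, se=0.002)
        assert report.flagged == []

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            detect_outliers([5, 5], [5, 5], se=0.002)
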