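"""Canonical differential allelic dispersion: does a case sample's
contribution to increased dispersion track its expression level?

For each heterozygous case sample, "extremity" is quantified as the
inverse of its minimal tail area under the fitted heterozygote
beta-binomial component: the smaller of the lower tail ``CMF(x_r)`` and
the upper tail ``1 - CMF(x_r) + PMF(x_r)`` (the PMF term makes the two
discrete tails comparable — the observed count is included in the lower
tail by convention but would otherwise be missing from the upper one).
Canonical dAD — e.g. silencing of one allele that also lowers a gene's
output — predicts a *negative* Spearman correlation between this
extremity and the sample's total allelic count; copy-number-gain-driven
dAD predicts a positive one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .distributions import BetaBinParams, betabin_cmf, betabin_logpmf
from .mixture_em import MixtureFit

__all__ = ["CanonResult", "minimal_tail_contribution", "canonical_test",
           "gene_canonical_summary"]

EXACT_P_MAX_N = 9
MIN_TOTAL_COUNT = 20


@dataclass
class CanonResult:
    corr_canon: float
    p_canon: float
    n_samples_used: int
    snp_id: str | None = None
    missing: bool = False


def minimal_tail_contribution(x_r: int, n: int, het_params: BetaBinParams) -> float:
    """Inverse minimal tail area of one observation under the heterozygote fit."""
    if n < 1:
        raise ValueError("total count must be >= 1")
    cmf = betabin_cmf(x_r, n, het_params)
    pmf = float(np.exp(betabin_logpmf(x_r, n, het_params)))
    tail = min(cmf, 1.0 - cmf + pmf)
    if tail <= 0.0:
        raise ValueError("tail area must be positive for a proper PMF")
    return 1.0 / tail


def _spearman(contrib, totals):
    """Spearman correlation with midranks; exact P for tiny sample counts."""
    n = len(contrib)
    rho, p = spearmanr(contrib, totals)
    if n <= EXACT_P_MAX_N:
        # exact permutation null of the rank correlation
        from scipy.stats import rankdata

        ra = rankdata(contrib)
        rb = rankdata(totals)
        ra = ra - ra.mean()
        rb = rb - rb.mean()
        denom = np.sqrt(np.sum(ra ** 2) * np.sum(rb ** 2))
        if denom == 0:
            return np.nan, np.nan
        obs = float(ra @ rb / denom)
        perms = np.array(list(_permutations(rb)))
        null = perms @ ra / denom
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        rho = obs
    return float(rho), float(p)


def canonical_test(fit: MixtureFit, snp_id: str | None = None,
                   min_total: int = MIN_TOTAL_COUNT) -> CanonResult:
    """Canonical-dAD correlation for one SNP from its group-specific fit.

    Uses only case samples classified heterozygous (highest
    responsibility) with total count above ``min_total``; correlates their
    inverse minimal tail areas (under the case heterozygote component)
    with their total counts.
    """
    case = fit.case_mask
    resp = fit.responsibilities
    het = np.argmax(resp, axis=1) == 1
    use = case & het & (fit.totals > min_total)
    n_used = int(use.sum())
    if n_used < 3:
        return CanonResult(np.nan, np.nan, n_used, snp_id, missing=True)
    params = BetaBinParams(pi=fit.pi_het, theta=fit.theta_het_case)
    contrib = np.array([
        minimal_tail_contribution(int(x), int(n), params)
        for x, n in zip(fit.x_ref[use], fit.totals[use])
    ])
    totals = fit.totals[use]
    if np.all(totals == totals[0]) or np.all(contrib == contrib[0]):
        return CanonResult(np.nan, np.nan, n_used, snp_id, missing=True)
    rho, p = _spearman(contrib, totals)
    if not np.isfinite(rho):
        return CanonResult(np.nan, np.nan, n_used, snp_id, missing=True)
    return CanonResult(float(rho), float(p), n_used, snp_id)


def gene_canonical_summary(results: list, weights=None) -> CanonResult:
    """Most significant per-SNP canonical correlation for a gene.

    P values are family-wise corrected across the gene's SNPs with Holm's
    method; the SNP with the smallest adjusted P is reported.  Ties go to
    the SNP with the larger combination weight, then the lexicographically
    smaller id.
    """
    usable = [r for r in results if not r.missing]
    if not usable:
        return CanonResult(np.nan, np.nan, 0, None, missing=True)
    p_adj = multipletests([r.p_canon for r in usable], method="holm")[1]
    if weights is None:
        weights = [0.0] * len(results)
    wmap = {id(r): w for r, w in zip(results, weights)}
    order = sorted(
        zip(usable, p_adj),
        key=lambda t: (t[1], -wmap.get(id(t[0]), 0.0), str(t[0].snp_id)),
    )
    best, best_p = order[0]
    return CanonResult(best.corr_canon, float(best_p), best.n_samples_used,
                       best.snp_id)
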