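"""SNP filtering, SNP-to-gene assignment, and dependence-corrected
Lancaster combination of per-SNP dAD P values.

Allele counts of nearby SNPs can derive from the same RNA-seq read or mRNA
molecule, so their per-SNP test P values are positively dependent and
plain Fisher/Lancaster combination would be anti-conservative.  The
combined statistic

    T_Lan = sum_i  G^{-1}_{w_i/2, 2}(1 - p_i)

(inverse gamma CDF with shape w_i/2 and scale 2, i.e. a chi-square
quantile with w_i degrees of freedom) is therefore rescaled: with
E[T] = sum w_i and var(T) = 2 sum w_i + 2 sum_{i<j} Covar_ij, the
corrected statistic c * T_Lan with c = v / E[T] and effective degrees of
freedom v = 2 E[T]^2 / var(T) is approximately chi-square(v) under the
null.  The inter-SNP covariances are estimated empirically from label
permutations shared across the gene's SNPs, with the score test supplying
each permutation's P values so that only one (null) model fit per SNP is
ever needed.  Negative covariance estimates are biologically implausible
for co-transcribed SNPs and truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, gamma
from statsmodels.stats.multitest import multipletests

from .dad_tests import ScoreTestEngine, SingularHessianError

__all__ = [
    "SnpFilterStatus",
    "FilterThresholds",
    "GeneResult",
    "PermutationConfig",
    "hwe_test",
    "apply_snp_filters",
    "resolve_gene_assignment",
    "lancaster_weights",
    "lancaster_statistic",
    "permutation_covariance",
    "combine_gene",
    "fdr_correct",
    "CATEGORY_PRIORITY",
]

P_MIN = 1e-15

# variant-category hierarchy: a SNP is assigned to the gene for which it
# most plausibly sits in processed mRNA
CATEGORY_PRIORITY = {
    "exonic": 0,
    "utr_noncoding": 1,
    "intronic_splice": 2,
    "up_downstream": 3,
}


@dataclass
class FilterThresholds:
    min_median_count: float = 4.0
    min_n_het_autosomal: float = 12.0
    min_n_het_x: float = 8.0
    pi_lo: float = 0.05
    pi_hi: float = 0.95
    hwe_alpha: float = 0.001


@dataclass
class SnpFilterStatus:
    pass_median_count: bool
    pass_n_het: bool
    pass_pi_bounds: bool
    pass_hwe: bool

    @property
    def overall(self) -> bool:
        return (self.pass_median_count and self.pass_n_het
                and self.pass_pi_bounds and self.pass_hwe)


@dataclass
class PermutationConfig:
    n_iter: int = 10_000
    seed: int = 0
    min_het_per_group: int = 6     # redo a permutation with <= this many hets
    max_redos: int = 50_000

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")


@dataclass
class GeneResult:
    gene_id: str
    snp_ids: list
    weights: np.ndarray
    t_lan: float
    c: float
    v: float
    covar_sum: float
    p_gene: float
    p_gene_fdr: float = np.nan
    summaries: dict = field(default_factory=dict)


def hwe_test(genotype_counts, f_inbr: float = 0.0):
    """Chi-square goodness-of-fit of genotype counts to inbreeding-adjusted
    Hardy-Weinberg proportions.

    ``genotype_counts`` are (rr, rv, vv) counts — here EM responsibility
    sums, so they need not be integers.  The allele frequency is estimated
    from the counts (one estimated parameter, so 1 df remains).
    """
    obs = np.asarray(genotype_counts, dtype=float)
    total = obs.sum()
    if total <= 0:
        return 0.0, 1.0
    p = (obs[0] + obs[1] / 2.0) / total
    q = 1.0 - p
    probs = np.array([
        p * p + f_inbr * p * q,
        2.0 * p * q * (1.0 - f_inbr),
        q * q + f_inbr * p * q,
    ])
    probs = np.clip(probs, 0.0, None)
    s = probs.sum()
    if s <= 0:
        return 0.0, 1.0
    probs /= s
    exp = total * probs
    mask = exp > 0
    stat = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    return stat, float(chi2.sf(stat, df=1))


def apply_snp_filters(
    snp_result,
    control_genotype_counts,
    case_genotype_counts,
    f_inbr: float,
    stratum: str = "autosomal",
    thresholds: FilterThresholds | None = None,
) -> SnpFilterStatus:
    """Evaluate the four per-SNP quality criteria ahead of gene combination.

    Genotype counts are the per-group EM responsibility sums *including*
    outlying samples (outliers are heterozygote-enriched, so dropping them
    would bias the HWE assessment); everything else in ``snp_result`` was
    computed on non-outliers.
    """
    th = thresholds or FilterThresholds()
    if stratum not in ("autosomal", "X"):
        raise ValueError(f"unknown stratum {stratum!r}")
    min_het = th.min_n_het_autosomal if stratum == "autosomal" else th.min_n_het_x
    pass_median = (snp_result.median_n_control >= th.min_median_count
                   and snp_result.median_n_case >= th.min_median_count)
    pass_n_het = (snp_result.n_het_control >= min_het
                  and snp_result.n_het_case >= min_het)
    pass_pi = th.pi_lo <= snp_result.pi_het <= th.pi_hi
    _, p_ctrl = hwe_test(control_genotype_counts, f_inbr)
    _, p_case = hwe_test(case_genotype_counts, f_inbr)
    pass_hwe = p_ctrl > th.hwe_alpha and p_case > th.hwe_alpha
    return SnpFilterStatus(
        pass_median_count=bool(pass_median),
        pass_n_het=bool(pass_n_het),
        pass_pi_bounds=bool(pass_pi),
        pass_hwe=bool(pass_hwe),
    )


def resolve_gene_assignment(annotations: pd.DataFrame) -> pd.DataFrame:
    """Resolve each SNP to a single gene via the variant-category hierarchy.

    ``annotations`` has columns (snp_id, gene_id, category).  Per SNP the
    highest-priority category wins; SNPs tied between multiple genes at
    their best level are dropped, as are unannotated SNPs.
    """
    ann = annotations.copy()
    unknown = set(ann["category"]) - set(CATEGORY_PRIORITY)
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
    ann["priority"] = ann["category"].map(CATEGORY_PRIORITY)
    rows = []
    for snp_id, grp in ann.groupby("snp_id", sort=True):
        best = grp[grp["priority"] == grp["priority"].min()]
        genes = best["gene_id"].unique()
        if len(genes) == 1:
            rows.append({"snp_id": snp_id, "gene_id": genes[0],
                         "category": best["category"].iloc[0]})
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "category"])


def lancaster_weights(n_het_control, n_het_case, median_n_control,
                      median_n_case) -> np.ndarray:
    """Per-SNP combination weights for one gene.

    Raw weight: the limiting group's (estimated heterozygote count x median
    total count), i.e. the minimum over groups.  Rescaled so the weights
    sum to twice the number of SNPs, which makes equally weighted SNPs
    reduce to Fisher's method.
    """
    raw = np.minimum(
        np.asarray(n_het_control, float) * np.asarray(median_n_control, float),
        np.asarray(n_het_case, float) * np.asarray(median_n_case, float),
    )
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise ValueError("raw Lancaster weights must be positive and finite")
    return raw * (2.0 * len(raw) / raw.sum())


def _gamma_transform(p, w):
    p = np.clip(np.asarray(p, dtype=float), P_MIN, 1.0)
    return gamma.isf(p, a=np.asarray(w, float) / 2.0, scale=2.0)


def lancaster_statistic(p_values, weights) -> float:
    """Weighted Lancaster combination statistic (Fisher when all w = 2)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(_gamma_transform(p_values, w)))


def permutation_covariance(
    engines: list,
    het_masks: list,
    weights,
    config: PermutationConfig,
    case_labels,
    sample_indices: list | None = None,
):
    """Estimate the summed inter-SNP covariance by shared label permutation.

    Each iteration reassigns control/case labels once over the gene's
    sample roster (preserving the real group sizes) and that single
    reassignment is shared by all of the gene's SNPs, so biological label
    effects are destroyed while inter-SNP dependence survives.  A
    permutation is redone when it leaves any SNP with too few putative
    heterozygotes in either group, or when any SNP's negative Hessian is
    numerically singular.

    Parameters
    ----------
    engines
        One :class:`ScoreTestEngine` per SNP (built from the null fits).
    het_masks
        Per SNP, boolean putative-heterozygote flags (from the per-group
        fits) aligned with the engine's samples.
    weights
        Lancaster weights per SNP (for the gamma transforms).
    case_labels
        Real roster-level case indicator; only its length and case count
        are used (to size the shuffled groups).
    sample_indices
        Per SNP, positions of the engine's samples in the roster; default
        is the identity (all SNPs cover the full roster).

    Returns ``(covar_sum, transformed)`` where ``transformed`` is the
    (n_iter, n_snps) matrix of gamma-transformed permutation P values.
    """
    n_snps = len(engines)
    w = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(config.seed)
    case_labels = np.asarray(case_labels, dtype=bool)
    n_samples = len(case_labels)
    n_case = int(case_labels.sum())
    if sample_indices is None:
        sample_indices = [np.arange(n_samples)] * n_snps

    transformed = np.empty((config.n_iter, n_snps))
    redos = 0
    it = 0
    while it < config.n_iter:
        perm = np.zeros(n_samples, dtype=bool)
        perm[rng.choice(n_samples, size=n_case, replace=False)] = True
        ok = True
        for het, idx in zip(het_masks, sample_indices):
            sub = perm[idx]
            n_het_case = int(np.sum(het & sub))
            n_het_ctrl = int(np.sum(het & ~sub))
            if min(n_het_case, n_het_ctrl) <= config.min_het_per_group:
                ok = False
                break
        if ok:
            ps = np.empty(n_snps)
            try:
                for i, (eng, idx) in enumerate(zip(engines, sample_indices)):
                    ps[i] = eng.evaluate(perm[idx]).p_value
            except SingularHessianError:
                ok = False
        if not ok:
            redos += 1
            if redos > config.max_redos:
                raise RuntimeError(
                    f"exceeded {config.max_redos} permutation redos")
            continue
        transformed[it] = _gamma_transform(ps, w)
        it += 1

    if n_snps == 1:
        return 0.0, transformed
    cov = np.cov(transformed, rowvar=False)
    iu = np.triu_indices(n_snps, k=1)
    covar_sum = float(np.sum(np.clip(cov[iu], 0.0, None)))
    return covar_sum, transformed


def combine_gene(gene_id, snp_ids, p_values, weights, covar_sum: float) -> GeneResult:
    """Dependence-corrected Lancaster combination for one gene."""
    w = np.asarray(weights, dtype=float)
    t_lan = lancaster_statistic(p_values, w)
    e_t = float(w.sum())
    var_t = 2.0 * e_t + 2.0 * covar_sum
    if var_t <= 0:
        raise ValueError("variance of the combined statistic must be positive")
    v = 2.0 * e_t ** 2 / var_t
    c = v / e_t
    p_gene = float(chi2.sf(c * t_lan, df=v))
    return GeneResult(
        gene_id=gene_id,
        snp_ids=list(snp_ids),
        weights=w,
        t_lan=t_lan,
        c=c,
        v=v,
        covar_sum=float(covar_sum),
        p_gene=p_gene,
    )


def fdr_correct(p_values, strata=None) -> np.ndarray:
    """Benjamini-Hochberg adjustment, applied within each stratum separately."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    strata = np.zeros(len(p), dtype=int) if strata is None else np.asarray(strata)
    for s in np.unique(strata):
        idx = np.where((strata == s) & np.isfinite(p))[0]
        if len(idx):
            out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out
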