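"""Synthetic allele-count cohorts with the full generative structure the
models assume.

Per sample: a genotype drawn from inbreeding-adjusted Hardy-Weinberg
proportions; a total allelic count from a negative-binomial coverage model
(floored at 1, emulating RNA-seq coverage heterogeneity); and a
reference-allele count that is beta-binomial — sequencing error governs
homozygotes, while heterozygotes draw a latent allelic fraction around
``pi_het`` with group-specific dispersion.  A "loss-type" mechanism
couples allelic skew to reduced coverage in case heterozygotes (one
allele's silencing lowers output), which is what the canonical-dAD
statistic is designed to detect; "gain-type" differential dispersion is
expressed simply through a larger case dispersion.

Multi-SNP genes share genotypes across SNPs (perfect linkage within the
short span of a gene) and mix per-SNP latent fractions with a shared
per-sample draw, reproducing the inter-SNP dependence that the corrected
Lancaster combination must absorb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import rho_to_theta

__all__ = ["SimConfig", "simulate_snp", "simulate_gene", "simulate_cohort"]


@dataclass
class SimConfig:
    """Generative parameters for one synthetic SNP.

    Defaults emulate a bulk RNA-seq case/control cohort: 72 controls vs
    268 cases, a common variant at reference-allele frequency 0.3 in a
    panmictic population, sequencing error 0.002, balanced heterozygote
    expression with moderate allelic dispersion, and median coverage
    around 50.
    """

    n_control: int = 72
    n_case: int = 268
    allele_freq: float = 0.3
    f_inbr: float = 0.0
    se: float = 0.002
    pi_het: float = 0.5
    rho_het_control: float = 0.03
    rho_het_case: float = 0.03
    rho_hom: float = 0.001
    coverage_mean: float = 50.0
    coverage_dispersion: float = 2.0   # negative-binomial shape; lower = noisier
    dad_mechanism: str = "none"        # none | loss | gain
    loss_factor: float = 0.5           # coverage multiplier for skewed case hets
    skew_threshold: float = 0.25       # |fraction - pi_het| beyond which skewed
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.allele_freq, self.se, self.pi_het, self.rho_het_control,
                 self.rho_het_case, self.rho_hom]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.dad_mechanism not in ("none", "loss", "gain"):
            raise ValueError(f"unknown dAD mechanism {self.dad_mechanism!r}")

    @property
    def genotype_probs(self) -> np.ndarray:
        p, f = self.allele_freq, self.f_inbr
        q = 1.0 - p
        return np.array([p * p + f * p * q, 2 * p * q * (1 - f),
                         q * q + f * p * q])


def _latent_fractions(rng, size, pi, rho):
    if rho <= 0.0:
        return np.full(size, pi)
    theta = rho_to_theta(rho)
    return rng.beta(pi / theta, (1.0 - pi) / theta, size=size)


def _coverage(rng, size, mean, dispersion, depth_factor=None):
    # negative binomial as a gamma-Poisson mixture with mean m and shape k;
    # a caller-supplied per-sample gamma factor shares depth across SNPs
    k = dispersion
    if depth_factor is None:
        depth_factor = rng.gamma(k, 1.0 / k, size=size)
    return np.maximum(rng.poisson(depth_factor * mean), 1)


def simulate_snp(config: SimConfig, rng=None, snp_id: str = "snp1",
                 genotypes=None, fractions=None, depth_factor=None):
    """Simulate one SNP's allele-count slice plus its latent truth record.

    ``genotypes``/``fractions``/``depth_factor`` allow a caller (gene
    simulation) to inject shared latent draws; by default they are drawn
    fresh.  Returns ``(DataFrame, truth)`` where the frame has columns
    (sample_id, snp_id, ref_count, var_count, group).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    S = config.n_control + config.n_case
    case = np.zeros(S, dtype=bool)
    case[config.n_control:] = True

    if genotypes is None:
        genotypes = rng.choice(3, size=S, p=config.genotype_probs)
    totals = _coverage(rng, S, config.coverage_mean,
                       config.coverage_dispersion, depth_factor)

    het = genotypes == 1
    if fractions is None:
        fractions = np.empty(S)
        for grp_mask, rho in ((~case, config.rho_het_control),
                              (case, config.rho_het_case)):
            m = het & grp_mask
            fractions[m] = _latent_fractions(rng, int(m.sum()),
                                             config.pi_het, rho)
    fractions = np.where(het, fractions, np.nan)

    if config.dad_mechanism == "loss":
        skewed = het & case & (np.abs(fractions - config.pi_het)
                               > config.skew_threshold)
        totals = np.where(
            skewed, np.maximum((totals * config.loss_factor).astype(int), 1),
            totals)

    hom_fracs = _latent_fractions(rng, S, 1.0 - config.se, config.rho_hom)
    p_ref = np.where(genotypes == 0, hom_fracs,
                     np.where(genotypes == 2, 1.0 - hom_fracs, 0.5))
    p_ref = np.where(het, np.nan_to_num(fractions, nan=0.5), p_ref)
    x_r = rng.binomial(totals, p_ref)

    frame = pd.DataFrame({
        "sample_id": [f"s{i:04d}" for i in range(S)],
        "snp_id": snp_id,
        "ref_count": x_r,
        "var_count": totals - x_r,
        "group": np.where(case, "case", "control"),
    })
    truth = {
        "snp_id": snp_id,
        "genotypes": genotypes,
        "fractions": fractions,
        "totals": totals,
        "case_mask": case,
        "config": config,
    }
    return frame, truth


def simulate_gene(configs: list, correlation: float = 0.0, rng=None,
                  gene_id: str = "gene1"):
    """Simulate a multi-SNP gene with tunable inter-SNP dependence.

    All SNPs share one genotype vector (SNPs within a gene are in tight
    linkage for this purpose) and one per-sample expression-depth factor
    (coverage at nearby SNPs derives from the same reads).  Allele counts
    of a heterozygous sample are *coupled* across SNPs with probability
    ``correlation``: coupled SNPs reuse one shared latent
    allelic-fraction draw and sample their reference reads from one
    shared read pool (a binomial pool, with each SNP's counts a
    hypergeometric subset), so with ``correlation`` 1 and equal totals
    the SNPs' observed counts are identical; with 0 everything but
    genotype and depth is independent.
    """
    if not 0.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [0, 1]")
    base = configs[0]
    rng = np.random.default_rng(base.seed) if rng is None else rng
    S = base.n_control + base.n_case
    N = len(configs)
    case = np.zeros(S, dtype=bool)
    case[base.n_control:] = True
    genotypes = rng.choice(3, size=S, p=base.genotype_probs)
    het = genotypes == 1
    depth = rng.gamma(base.coverage_dispersion,
                      1.0 / base.coverage_dispersion, size=S)

    shared = np.full(S, np.nan)
    for grp_mask, rho in ((~case, base.rho_het_control),
                          (case, base.rho_het_case)):
        m = het & grp_mask
        shared[m] = _latent_fractions(rng, int(m.sum()), base.pi_het, rho)
    coupled = rng.random((N, S)) < correlation

    frames, truths = [], []
    for i, cfg in enumerate(configs):
        own = np.empty(S)
        for grp_mask, rho in ((~case, cfg.rho_het_control),
                              (case, cfg.rho_het_case)):
            m = het & grp_mask
            own[m] = _latent_fractions(rng, int(m.sum()), cfg.pi_het, rho)
        fractions = np.where(coupled[i], shared, own)
        frame, truth = simulate_snp(
            cfg, rng=rng, snp_id=f"{gene_id}_snp{i + 1}",
            genotypes=genotypes, fractions=fractions, depth_factor=depth)
        truth["gene_id"] = gene_id
        frames.append(frame)
        truths.append(truth)

    # redraw coupled heterozygote counts from one shared read pool per
    # sample so the binomial sampling noise itself is shared
    totals = np.array([t["totals"] for t in truths])        # (N, S)
    x_ref = np.array([f["ref_count"].to_numpy() for f in frames])
    for s in np.where(het)[0]:
        snps = np.where(coupled[:, s])[0]
        if len(snps) < 2:
            continue
        pool = int(totals[snps, s].max())
        k_pool = rng.binomial(pool, shared[s])
        for i in snps:
            x_ref[i, s] = rng.hypergeometric(k_pool, pool - k_pool,
                                             int(totals[i, s]))
    for i, frame in enumerate(frames):
        frame["ref_count"] = x_ref[i]
        frame["var_count"] = totals[i] - x_ref[i]
    return pd.concat(frames, ignore_index=True), truths


def simulate_cohort(gene_specs: list, seed: int = 0):
    """Simulate a cohort of genes.

    ``gene_specs`` is a list of ``(gene_id, [SimConfig, ...], correlation)``
    triples.  Returns ``(counts, annotations, truths)``: a long-format
    allele-count table, a SNP-to-gene annotation table (all exonic), and
    the truth records.
    """
    rng = np.random.default_rng(seed)
    frames, ann_rows, truths = [], [], []
    for gene_id, configs, corr in gene_specs:
        frame, truth = simulate_gene(configs, corr, rng=rng, gene_id=gene_id)
        frames.append(frame)
        truths.extend(truth)
        for snp_id in frame["snp_id"].unique():
            ann_rows.append({"snp_id": snp_id, "gene_id": gene_id,
                             "category": "exonic"})
    counts = pd.concat(frames, ignore_index=True)
    annotations = pd.DataFrame(ann_rows)
    return counts, annotations, truths
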