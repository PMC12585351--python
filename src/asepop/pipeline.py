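"""End-to-end differential allelic dispersion pipeline.

Stages: metaparameter estimation (or user-supplied values) -> per-SNP
mixture fits and LRT (with optional leave-one-out outlier exclusion) ->
per-SNP quality/HWE filters -> SNP-to-gene assignment -> permutation-based
dependence-corrected Lancaster combination -> canonical-dAD correlation ->
stratified Benjamini-Hochberg correction.  Every input SNP appears in the
SNP-level output with an explicit disposition.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canonical_dad import canonical_test, gene_canonical_summary
from .dad_tests import ScoreTestEngine, fit_and_test
from .gene_combine import (
    FilterThresholds,
    PermutationConfig,
    apply_snp_filters,
    combine_gene,
    fdr_correct,
    lancaster_weights,
    permutation_covariance,
    resolve_gene_assignment,
)
from .metaparameters import MetaFilterConfig, estimate_metaparameters
from .mixture_em import detect_outliers, fit_mixture, putative_het_mask

logger = logging.getLogger("asepop")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``se``/``f_inbr`` left as None are estimated from the data.  X-stratum
    handling is by explicit gene list plus a user-declared female sample
    subset; the tool never infers sex.
    """

    se: float | None = None
    f_inbr: float | None = None
    meta_filters: MetaFilterConfig = field(default_factory=MetaFilterConfig)
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    permutations: PermutationConfig = field(default_factory=PermutationConfig)
    outlier_detection: bool = True
    min_prevalence: int = 10
    x_genes: frozenset = frozenset()
    female_samples: frozenset = frozenset()
    seed: int = 0


def _gene_seed(master_seed: int, gene_id: str) -> int:
    return (int(master_seed) + zlib.crc32(gene_id.encode())) % (2 ** 31)


def _weighted_mean(values, weights):
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if weights.sum() <= 0:
        return np.nan
    return float(np.sum(values * weights) / weights.sum())


def _process_snp(snp_id, grp, config: RunConfig, se: float):
    """Per-SNP fits, outlier handling and the LRT; returns a record dict."""
    grp = grp[(grp["ref_count"] + grp["var_count"]) > 0]
    x_r = grp["ref_count"].to_numpy(float)
    x_v = grp["var_count"].to_numpy(float)
    case = (grp["group"] == "case").to_numpy()
    sample_ids = grp["sample_id"].to_numpy()
    rec = {"snp_id": snp_id, "disposition": "analyzed"}
    if case.sum() < 2 or (~case).sum() < 2:
        rec["disposition"] = "insufficient_group_samples"
        return rec

    group_fits = {}
    outlier_ids: set = set()
    for label, mask in (("control", ~case), ("case", case)):
        gfit = fit_mixture(x_r[mask], x_v[mask], se=se)
        group_fits[label] = (gfit, sample_ids[mask])
        if config.outlier_detection and mask.sum() >= 3:
            report = detect_outliers(x_r[mask], x_v[mask],
                                     sample_ids=list(sample_ids[mask]), se=se)
            outlier_ids.update(report.flagged)

    keep = ~np.isin(sample_ids, list(outlier_ids))
    if case[keep].sum() < 2 or (~case[keep]).sum() < 2:
        rec["disposition"] = "insufficient_after_outliers"
        return rec

    fit_null, fit_alt, result = fit_and_test(
        x_r[keep], x_v[keep], case[keep], se=se)
    rec.update(
        result=result,
        fit_null=fit_null,
        fit_alt=fit_alt,
        group_fits=group_fits,
        outliers=sorted(outlier_ids),
        kept_sample_ids=sample_ids[keep],
        case_mask=case[keep],
    )
    return rec


def run_pipeline(counts: pd.DataFrame, annotations: pd.DataFrame,
                 config: RunConfig | None = None):
    """Run the full dAD analysis; returns (snp_table, gene_table)."""
    from .io import prevalence_filter, validate_counts

    config = config or RunConfig()
    validate_counts(counts)
    if not (counts["group"] == "case").any():
        raise ValueError("case group is empty")
    if not (counts["group"] == "control").any():
        raise ValueError("control group is empty")

    all_snps = sorted(counts["snp_id"].unique())
    counts, dropped = prevalence_filter(counts, config.min_prevalence)
    logger.info("prevalence filter: %d SNPs dropped, %d retained",
                len(dropped), counts["snp_id"].nunique())

    if config.se is None or config.f_inbr is None:
        meta = estimate_metaparameters(counts, config.meta_filters)
        se = meta.se_global if config.se is None else config.se
        f_inbr = meta.f_inbr if config.f_inbr is None else config.f_inbr
        logger.info("metaparameters: SE=%.5f F_inbr=%.4f (from %d loci)",
                    se, f_inbr, meta.n_loci_used)
    else:
        se, f_inbr = config.se, config.f_inbr

    assignment = resolve_gene_assignment(annotations)
    gene_of = dict(zip(assignment["snp_id"], assignment["gene_id"]))

    snp_rows = []
    records = {}
    for snp_id, grp in counts.groupby("snp_id", sort=True):
        gene_id = gene_of.get(snp_id)
        stratum = "X" if gene_id in config.x_genes else "autosomal"
        if gene_id is None:
            snp_rows.append({"snp_id": snp_id,
                             "disposition": "unannotated_or_ambiguous"})
            continue
        if stratum == "X" and config.female_samples:
            grp = grp[grp["sample_id"].isin(config.female_samples)]
        rec = _process_snp(snp_id, grp, config, se)
        rec["gene_id"] = gene_id
        rec["stratum"] = stratum
        if "result" not in rec:
            snp_rows.append({k: rec[k] for k in
                             ("snp_id", "gene_id", "stratum", "disposition")})
            continue

        res = rec["result"]
        ctrl_fit = rec["group_fits"]["control"][0]
        case_fit = rec["group_fits"]["case"][0]
        status = apply_snp_filters(
            res,
            ctrl_fit.responsibilities.sum(axis=0),
            case_fit.responsibilities.sum(axis=0),
            f_inbr,
            stratum=stratum,
            thresholds=config.filter_thresholds,
        )
        rec["status"] = status
        canon = canonical_test(rec["fit_alt"], snp_id=snp_id)
        rec["canon"] = canon
        records[snp_id] = rec
        snp_rows.append({
            "snp_id": snp_id,
            "gene_id": gene_id,
            "stratum": stratum,
            "disposition": "analyzed" if status.overall else "filtered",
            "lambda_lrt": res.lambda_lrt,
            "p_dad": res.p_dad,
            "rho_control": res.rho_control,
            "rho_case": res.rho_case,
            "pi_het": res.pi_het,
            "n_het_control": res.n_het_control,
            "n_het_case": res.n_het_case,
            "median_n_control": res.median_n_control,
            "median_n_case": res.median_n_case,
            "pass_median_count": status.pass_median_count,
            "pass_n_het": status.pass_n_het,
            "pass_pi_bounds": status.pass_pi_bounds,
            "pass_hwe": status.pass_hwe,
            "n_outliers": len(rec["outliers"]),
            "fit_flags": ";".join(res.filter_flags),
            "corr_canon": canon.corr_canon,
            "p_canon": canon.p_canon,
        })

    snp_table = pd.DataFrame(snp_rows)
    # SNP-level FDR among analyzed SNPs, stratified autosomal/X
    if "p_dad" in snp_table.columns:
        analyzed = snp_table["disposition"] == "analyzed"
        snp_table["p_dad_fdr"] = np.nan
        if analyzed.any():
            sub = snp_table[analyzed]
            snp_table.loc[analyzed, "p_dad_fdr"] = fdr_correct(
                sub["p_dad"].to_numpy(), sub["stratum"].to_numpy())

    gene_rows = []
    passing = [r for r in records.values()
               if r.get("status") is not None and r["status"].overall]
    by_gene: dict = {}
    for rec in passing:
        by_gene.setdefault(rec["gene_id"], []).append(rec)

    for gene_id in sorted(by_gene):
        recs = sorted(by_gene[gene_id], key=lambda r: r["snp_id"])
        results = [r["result"] for r in recs]
        try:
            w = lancaster_weights(
                [t.n_het_control for t in results],
                [t.n_het_case for t in results],
                [t.median_n_control for t in results],
                [t.median_n_case for t in results],
            )
        except ValueError:
            logger.warning("gene %s: zero Lancaster weight, skipped", gene_id)
            continue

        roster = sorted({sid for r in recs for sid in r["kept_sample_ids"]})
        roster_pos = {sid: i for i, sid in enumerate(roster)}
        case_labels = np.zeros(len(roster), dtype=bool)
        for r in recs:
            for sid, is_case in zip(r["kept_sample_ids"], r["case_mask"]):
                if is_case:
                    case_labels[roster_pos[sid]] = True
        engines, het_masks, indices = [], [], []
        for r in recs:
            engines.append(ScoreTestEngine.from_fit(r["fit_null"]))
            # putative hets from the separate per-group fits
            het = np.zeros(len(r["kept_sample_ids"]), dtype=bool)
            for gfit, gids in r["group_fits"].values():
                ghet = dict(zip(gids, putative_het_mask(gfit)))
                for i, sid in enumerate(r["kept_sample_ids"]):
                    if ghet.get(sid, False):
                        het[i] = True
            het_masks.append(het)
            indices.append(np.array([roster_pos[s]
                                     for s in r["kept_sample_ids"]]))

        perm_cfg = PermutationConfig(
            n_iter=config.permutations.n_iter,
            seed=_gene_seed(config.seed, gene_id),
            min_het_per_group=config.permutations.min_het_per_group,
            max_redos=config.permutations.max_redos,
        )
        try:
            covar_sum, _ = permutation_covariance(
                engines, het_masks, w, perm_cfg, case_labels, indices)
        except RuntimeError as err:
            logger.warning("gene %s: %s; combination skipped", gene_id, err)
            continue

        gres = combine_gene(gene_id, [r["snp_id"] for r in recs],
                            [t.p_dad for t in results], w, covar_sum)
        w_ctrl = np.sqrt([t.n_het_control * t.median_n_control
                          for t in results])
        w_case = np.sqrt([t.n_het_case * t.median_n_case for t in results])
        canon = gene_canonical_summary([r["canon"] for r in recs], weights=w)
        gene_rows.append({
            "gene_id": gene_id,
            "stratum": recs[0]["stratum"],
            "n_snps": len(recs),
            "rho_control": _weighted_mean([t.rho_control for t in results],
                                          w_ctrl),
            "rho_case": _weighted_mean([t.rho_case for t in results], w_case),
            "n_het_control": _weighted_mean([t.n_het_control for t in results],
                                            w_ctrl),
            "n_het_case": _weighted_mean([t.n_het_case for t in results],
                                         w_case),
            "median_n_control": _weighted_mean(
                [t.median_n_control for t in results], w_ctrl),
            "median_n_case": _weighted_mean(
                [t.median_n_case for t in results], w_case),
            "t_lan": gres.t_lan,
            "c": gres.c,
            "v": gres.v,
            "covar_sum": gres.covar_sum,
            "p_dad": gres.p_gene,
            "corr_canon": canon.corr_canon,
            "p_canon": canon.p_canon,
        })

    gene_table = pd.DataFrame(gene_rows)
    if not gene_table.empty:
        gene_table["p_dad_fdr"] = fdr_correct(
            gene_table["p_dad"].to_numpy(), gene_table["stratum"].to_numpy())
    logger.info("pipeline: %d/%d SNPs analyzed, %d genes combined",
                len(records), len(all_snps), len(gene_table))
    return snp_table, gene_table
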