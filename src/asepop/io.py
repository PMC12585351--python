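"""Long-format allele-count tables and related input handling.

The canonical input is a tab-separated table with one row per
(sample, SNP): ``sample_id  snp_id  ref_count  var_count  group`` with
``group`` in {control, case} (an optional ``chrom`` column is carried
through).  Helpers cover reduction of raw 4-nucleotide counts to a
biallelic (reference, variant) designation and the SNP prevalence filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotations",
    "validate_counts",
    "select_biallelic",
    "select_biallelic_table",
    "prevalence_filter",
]

REQUIRED_COLUMNS = ["sample_id", "snp_id", "ref_count", "var_count", "group"]
NUCLEOTIDES = ["A", "C", "G", "T"]


def validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    bad_groups = set(table["group"]) - {"control", "case"}
    if bad_groups:
        raise ValueError(f"group labels must be control/case, got {bad_groups}")
    for col in ("ref_count", "var_count"):
        vals = table[col]
        if (vals < 0).any() or not np.array_equal(vals, vals.astype(int)):
            raise ValueError(f"{col} must contain non-negative integers")
    if table.duplicated(["sample_id", "snp_id"]).any():
        raise ValueError("(sample_id, snp_id) pairs must be unique")
    return table


def read_counts(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t",
                        dtype={"sample_id": str, "snp_id": str})
    return validate_counts(table)


def write_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("snp_id", "gene_id", "category")
               if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return ann


class MonomorphicSnpError(ValueError):
    """No second allele observed: the SNP cannot be analyzed."""


def select_biallelic(nuc_totals: dict, allowed_alleles=None, rng=None):
    """Designate (reference, variant) alleles from summed nucleotide counts.

    The most abundant allele becomes the reference and the second most
    abundant the variant; candidates can be restricted to
    ``allowed_alleles`` (e.g. the two annotated alleles of a known
    variant).  Ties are broken by the supplied seeded generator.
    """
    rng = np.random.default_rng() if rng is None else rng
    alleles = [a for a in NUCLEOTIDES
               if allowed_alleles is None or a in allowed_alleles]
    totals = np.array([float(nuc_totals.get(a, 0)) for a in alleles])
    if totals.sum() <= 0:
        raise MonomorphicSnpError("no counts observed")
    order = np.lexsort((rng.random(len(alleles)), -totals))
    ref, var = alleles[order[0]], alleles[order[1]]
    if nuc_totals.get(var, 0) <= 0:
        raise MonomorphicSnpError("no second allele observed")
    return ref, var


def select_biallelic_table(nuc_table: pd.DataFrame, allowed=None,
                           seed: int = 0) -> pd.DataFrame:
    """Reduce a per-sample 4-nucleotide count table to biallelic counts.

    ``nuc_table`` columns: sample_id, snp_id, group, A, C, G, T.
    ``allowed`` optionally maps snp_id -> iterable of permitted alleles.
    Monomorphic SNPs are dropped.  Counts of the non-designated
    nucleotides are discarded.
    """
    rng = np.random.default_rng(seed)
    out = []
    for snp_id, grp in nuc_table.groupby("snp_id", sort=True):
        totals = {a: grp[a].sum() for a in NUCLEOTIDES}
        try:
            ref, var = select_biallelic(
                totals, None if allowed is None else allowed.get(snp_id), rng)
        except MonomorphicSnpError:
            continue
        sub = grp[["sample_id", "snp_id", "group"]].copy()
        sub["ref_count"] = grp[ref].to_numpy()
        sub["var_count"] = grp[var].to_numpy()
        sub["ref_allele"] = ref
        sub["var_allele"] = var
        out.append(sub)
    if not out:
        return pd.DataFrame(columns=REQUIRED_COLUMNS + ["ref_allele",
                                                        "var_allele"])
    return pd.concat(out, ignore_index=True)


def prevalence_filter(table: pd.DataFrame, min_samples: int = 10):
    """Retain SNPs with nonzero total counts in at least ``min_samples``
    samples; returns ``(filtered_table, dropped_snp_ids)``."""
    totals = table["ref_count"] + table["var_count"]
    covered = table.loc[totals > 0].groupby("snp_id")["sample_id"].nunique()
    keep = set(covered[covered >= min_samples].index)
    dropped = sorted(set(table["snp_id"]) - keep)
    return table[table["snp_id"].isin(keep)].copy(), dropped
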