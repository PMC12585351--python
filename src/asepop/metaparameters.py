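"""Cohort-level metaparameters: sequencing error and inbreeding coefficient.

A simplified three-component *binomial* genotype mixture is fit per SNP by
EM, assuming perfectly balanced heterozygote expression (p = 0.5) and no
overdispersion.  This crude model is fast (closed-form M-steps) and its
sequencing-error parameter — the probability of observing the wrong allele
in a homozygote — is robust to the model's oversimplifications.  Loci with
implausible fits are filtered out, and the cohort sequencing error ``SE``
is the median of the retained per-locus estimates.  The same retained fits
yield the cohort inbreeding coefficient ``F_inbr`` as the median of

    F = 1 - phi_rv / (2 * (phi_rr + phi_rv/2) * (phi_vv + phi_rv/2))

i.e. one minus the ratio of observed to panmictic-expected heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "BinomMixtureFit",
    "MetaParams",
    "MetaFilterConfig",
    "fit_binomial_mixture",
    "estimate_metaparameters",
    "inbreeding_coefficient",
]

SE_FLOOR = 1e-6


@dataclass
class BinomMixtureFit:
    phi_rr: float
    phi_rv: float
    phi_vv: float
    se: float
    loglik: float
    n_iter: int
    converged: bool


@dataclass
class MetaFilterConfig:
    """Locus retention rules for metaparameter estimation."""

    max_se: float = 0.035
    min_samples: int = 41          # locus must be covered by more than 40 samples
    min_median_coverage: float = 10.0
    min_mac_fraction: float = 0.15


@dataclass
class MetaParams:
    se_global: float
    f_inbr: float
    n_loci_used: int
    per_locus: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def inbreeding_coefficient(phi_rr: float, phi_rv: float, phi_vv: float) -> float:
    """Per-locus inbreeding coefficient from genotype mixture frequencies."""
    p = phi_rr + phi_rv / 2.0
    q = phi_vv + phi_rv / 2.0
    expected = 2.0 * p * q
    if expected <= 0.0:
        return np.nan
    return 1.0 - phi_rv / expected


def fit_binomial_mixture(
    x_r,
    x_v,
    se_floor: float = SE_FLOOR,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> BinomMixtureFit:
    """EM fit of the balanced binomial genotype mixture to one SNP.

    Components: reference homozygotes (p = 1 - SE), heterozygotes
    (p = 0.5, fixed), variant homozygotes (p = SE).  Both mixture weights
    and SE have closed-form M-steps (responsibility-weighted averages).
    """
    x_r = np.asarray(x_r, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    n = x_r + x_v
    keep = n > 0
    x_r, x_v, n = x_r[keep], x_v[keep], n[keep]
    if len(n) < 2:
        raise ValueError("need >= 2 samples with nonzero totals")

    logc = gammaln(n + 1) - gammaln(x_r + 1) - gammaln(x_v + 1)

    frac = x_r / n
    hard = np.select([frac > 0.85, frac < 0.15], [0, 2], default=1)
    phi = np.clip(np.bincount(hard, minlength=3) / len(n), 1e-6, None)
    phi = phi / phi.sum()
    se = 0.01

    def comp_logpmf(se_):
        with np.errstate(divide="ignore"):
            l_rr = logc + x_r * np.log1p(-se_) + x_v * np.log(se_)
            l_rv = logc + n * np.log(0.5)
            l_vv = logc + x_r * np.log(se_) + x_v * np.log1p(-se_)
        return np.column_stack([l_rr, l_rv, l_vv])

    loglik = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        lp = comp_logpmf(se) + np.log(phi)
        norm = logsumexp(lp, axis=1)
        new_loglik = float(norm.sum())
        resp = np.exp(lp - norm[:, None])
        phi = resp.mean(axis=0)
        hom_wrong = resp[:, 0] * x_v + resp[:, 2] * x_r
        hom_total = (resp[:, 0] + resp[:, 2]) * n
        if hom_total.sum() > 0:
            se = float(np.clip(hom_wrong.sum() / hom_total.sum(), se_floor, 0.5))
        if abs(new_loglik - loglik) <= tol * (abs(new_loglik) + 1.0):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return BinomMixtureFit(
        phi_rr=float(phi[0]),
        phi_rv=float(phi[1]),
        phi_vv=float(phi[2]),
        se=se,
        loglik=loglik,
        n_iter=it,
        converged=converged,
    )


def estimate_metaparameters(
    table: pd.DataFrame,
    filters: MetaFilterConfig | None = None,
) -> MetaParams:
    """Estimate cohort SE and F_inbr from all SNPs of an allele-count table.

    ``table`` is long-format with columns ``snp_id``, ``ref_count``,
    ``var_count`` (control and case samples pooled; the mixture has no
    group structure).
    """
    filters = filters or MetaFilterConfig()
    rows = []
    for snp_id, grp in table.groupby("snp_id", sort=True):
        x_r = grp["ref_count"].to_numpy(dtype=float)
        x_v = grp["var_count"].to_numpy(dtype=float)
        n = x_r + x_v
        covered = int((n > 0).sum())
        if covered < 2:
            continue
        fit = fit_binomial_mixture(x_r, x_v)
        mac = min(x_r.sum(), x_v.sum())
        mac_frac = mac / n.sum() if n.sum() > 0 else 0.0
        rows.append(
            {
                "snp_id": snp_id,
                "se": fit.se,
                "f_inbr": inbreeding_coefficient(fit.phi_rr, fit.phi_rv, fit.phi_vv),
                "phi_rr": fit.phi_rr,
                "phi_rv": fit.phi_rv,
                "phi_vv": fit.phi_vv,
                "n_covered": covered,
                "median_coverage": float(np.median(n[n > 0])),
                "mac_fraction": mac_frac,
            }
        )
    per_locus = pd.DataFrame(rows)
    if per_locus.empty:
        raise ValueError("no SNP could be fit")
    keep = (
        (per_locus["se"] < filters.max_se)
        & (per_locus["n_covered"] >= filters.min_samples)
        & (per_locus["median_coverage"] >= filters.min_median_coverage)
        & (per_locus["mac_fraction"] >= filters.min_mac_fraction)
    )
    per_locus["retained"] = keep
    retained = per_locus[keep]
    if retained.empty:
        raise ValueError("no locus passed the metaparameter filters")
    return MetaParams(
        se_global=float(retained["se"].median()),
        f_inbr=float(retained["f_inbr"].median()),
        n_loci_used=int(keep.sum()),
        per_locus=per_locus,
    )
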