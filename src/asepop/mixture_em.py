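"""EM fitting of the three-component beta-binomial genotype mixture.

Per SNP, each sample's reference-allele count is modeled as a mixture over
latent genotypes:

* reference homozygotes: ``BetaBin(n, 1 - SE, theta_hom)``
* heterozygotes:         ``BetaBin(n, pi_het, theta_het)``
* variant homozygotes:   ``BetaBin(n, SE, theta_hom)``

with mixture weights ``(phi_rr, phi_rv, phi_vv)`` playing the role of
genotype frequencies and the cohort sequencing error ``SE`` held fixed.
The heterozygote dispersion ``theta_het`` is either shared across the
cohort (null model) or split into control- and case-specific values
(group-specific model) — the parameter whose difference constitutes
differential allelic dispersion.

The E-step computes genotype responsibilities; the M-step updates the
mixture weights in closed form and the continuous parameters by
quasi-Newton ascent on transformed coordinates (logit pi, log theta),
which avoids bounded optimization.  Heterozygote components are kept
unimodal: a beta-binomial is bimodal when ``theta > max(pi, 1 - pi)``,
which in practice means the heterozygote component is being abused to fit
homozygote data, so fits violating the constraint are rerun with the
constraint imposed.

Leave-one-out outlier detection refits the mixture without each sample in
turn and flags samples whose deletion shifts the heterozygote estimates by
more than five standard deviations of the deletion-delta series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .distributions import _grad_single, betabin_logpmf_vec, theta_to_rho
from .moment_init import kleinman_estimate

__all__ = ["MixtureFit", "OutlierReport", "fit_mixture", "detect_outliers",
           "putative_het_mask"]

_LOGIT_CAP = 12.0
_LOG_THETA_MIN, _LOG_THETA_MAX = np.log(1e-8), np.log(50.0)
_HET_FRAC_LO, _HET_FRAC_HI = 0.15, 0.85   # putative-heterozygote seeding rule


@dataclass
class MixtureFit:
    phi_rr: float
    phi_rv: float
    phi_vv: float
    pi_het: float
    theta_het_control: float
    theta_het_case: float
    theta_hom: float
    se: float
    group_specific: bool
    loglik: float
    n_iter: int
    converged: bool
    constrained_refit: bool
    unidentifiable: bool
    responsibilities: np.ndarray = field(repr=False)
    case_mask: np.ndarray = field(repr=False)
    x_ref: np.ndarray = field(repr=False, default=None)
    totals: np.ndarray = field(repr=False, default=None)
    n_het_control: float = 0.0
    n_het_case: float = 0.0

    @property
    def rho_het_control(self) -> float:
        return theta_to_rho(self.theta_het_control)

    @property
    def rho_het_case(self) -> float:
        return theta_to_rho(self.theta_het_case)

    @property
    def rho_hom(self) -> float:
        return theta_to_rho(self.theta_hom)

    @property
    def theta_het(self) -> float:
        """Shared heterozygote dispersion (meaningful for null-model fits)."""
        return self.theta_het_control

    @property
    def phi(self) -> np.ndarray:
        return np.array([self.phi_rr, self.phi_rv, self.phi_vv])


@dataclass
class OutlierReport:
    sample_ids: list
    flagged: list
    delta_pi: np.ndarray
    delta_theta: np.ndarray
    threshold: float = 5.0


def putative_het_mask(fit: MixtureFit) -> np.ndarray:
    """Samples more likely heterozygous than either homozygote."""
    r = fit.responsibilities
    return (r[:, 1] > r[:, 0]) & (r[:, 1] > r[:, 2])


def _component_logliks(x_r, n, se, pi_het, th_c, th_v, th_hom, case_mask):
    l_rr = betabin_logpmf_vec(x_r, n, 1.0 - se, th_hom)
    l_vv = betabin_logpmf_vec(x_r, n, se, th_hom)
    if th_c == th_v:
        l_het = betabin_logpmf_vec(x_r, n, pi_het, th_c)
    else:
        l_het = np.empty_like(l_rr)
        ctrl = ~case_mask
        l_het[ctrl] = betabin_logpmf_vec(x_r[ctrl], n[ctrl], pi_het, th_c)
        l_het[case_mask] = betabin_logpmf_vec(x_r[case_mask], n[case_mask], pi_het, th_v)
    return np.column_stack([l_rr, l_het, l_vv])


def _unpack(psi, group_specific):
    pi = float(expit(np.clip(psi[0], -_LOGIT_CAP, _LOGIT_CAP)))
    th_c = float(np.exp(np.clip(psi[1], _LOG_THETA_MIN, _LOG_THETA_MAX)))
    if group_specific:
        th_v = float(np.exp(np.clip(psi[2], _LOG_THETA_MIN, _LOG_THETA_MAX)))
        th_hom = float(np.exp(np.clip(psi[3], _LOG_THETA_MIN, _LOG_THETA_MAX)))
    else:
        th_v = th_c
        th_hom = float(np.exp(np.clip(psi[2], _LOG_THETA_MIN, _LOG_THETA_MAX)))
    return pi, th_c, th_v, th_hom


def _make_mstep_objective(x_r, n, se, resp, case_mask, group_specific):
    ctrl = ~case_mask
    r_rr, r_het, r_vv = resp[:, 0], resp[:, 1], resp[:, 2]

    def neg_q_and_grad(psi):
        pi, th_c, th_v, th_hom = _unpack(psi, group_specific)
        comp = _component_logliks(x_r, n, se, pi, th_c, th_v, th_hom, case_mask)
        q = float(np.sum(resp * comp))

        # heterozygote gradients (pi and per-group theta)
        dpi_c, dth_c = _grad_single(x_r[ctrl], n[ctrl], pi, th_c)
        dpi_v, dth_v = _grad_single(x_r[case_mask], n[case_mask], pi, th_v)
        g_pi = np.sum(r_het[ctrl] * dpi_c) + np.sum(r_het[case_mask] * dpi_v)
        g_thc = np.sum(r_het[ctrl] * dth_c)
        g_thv = np.sum(r_het[case_mask] * dth_v)
        # homozygote theta gradient through both components
        _, dth_rr = _grad_single(x_r, n, 1.0 - se, th_hom)
        _, dth_vv = _grad_single(x_r, n, se, th_hom)
        g_thom = np.sum(r_rr * dth_rr) + np.sum(r_vv * dth_vv)

        # chain rule through the transforms
        grad = np.empty_like(psi)
        grad[0] = pi * (1.0 - pi) * g_pi
        if group_specific:
            grad[1] = th_c * g_thc
            grad[2] = th_v * g_thv
            grad[3] = th_hom * g_thom
        else:
            grad[1] = th_c * g_thc + th_v * g_thv
            grad[2] = th_hom * g_thom
        return -q, -grad

    return neg_q_and_grad


def _mstep_continuous(psi0, objective, group_specific, constrained):
    if not constrained:
        res = minimize(objective, psi0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 40})
        return res.x if np.isfinite(res.fun) else psi0

    # unimodality: theta_het <= max(pi, 1 - pi) for every heterozygote theta
    def cons(psi):
        pi, th_c, th_v, _ = _unpack(psi, group_specific)
        cap = np.log(max(pi, 1.0 - pi))
        vals = [cap - np.log(th_c)]
        if group_specific:
            vals.append(cap - np.log(th_v))
        return np.array(vals)

    res = minimize(lambda p: objective(p)[0], psi0, method="SLSQP",
                   constraints=[{"type": "ineq", "fun": cons}],
                   options={"maxiter": 60, "ftol": 1e-12})
    return res.x if res.success or np.isfinite(res.fun) else psi0


def _init_params(x_r, n, case_mask):
    frac = np.where(n > 0, x_r / np.maximum(n, 1), 0.5)
    hard = np.select([frac > _HET_FRAC_HI, frac < _HET_FRAC_LO], [0, 2], default=1)
    phi = np.clip(np.bincount(hard, minlength=3) / len(n), 1e-4, None)
    phi = phi / phi.sum()
    het = (frac >= _HET_FRAC_LO) & (frac <= _HET_FRAC_HI) & (n > 0)
    if het.sum() >= 2:
        est = kleinman_estimate(np.column_stack([x_r[het], n[het]]))
        pi0 = float(np.clip(est.pi_hat, 0.05, 0.95))
        th0 = float(np.clip(est.theta_hat, 1e-6, 10.0))
    else:
        pi0, th0 = 0.5, 0.01
    return phi, pi0, th0, 1e-3


def fit_mixture(
    x_r,
    x_v,
    case_mask=None,
    se: float = 0.002,
    group_specific_rho: bool = False,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MixtureFit:
    """Fit the genotype mixture to one SNP's allele counts by EM.

    Parameters
    ----------
    x_r, x_v
        Reference and variant allele counts per sample.
    case_mask
        Boolean case indicator per sample; required when
        ``group_specific_rho`` is set, otherwise optional (used only to
        report per-group heterozygote counts).
    se
        Fixed cohort sequencing error (from metaparameter estimation).
    group_specific_rho
        Fit separate control/case heterozygote dispersions (the
        differential model) instead of a single shared one.
    init
        Optional warm start ``(phi, pi_het, theta_het_control,
        theta_het_case, theta_hom)``.
    """
    x_r = np.asarray(x_r, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    n = x_r + x_v
    S = len(n)
    if S < 2:
        raise ValueError("need at least 2 samples")
    if case_mask is None:
        if group_specific_rho:
            raise ValueError("group_specific_rho requires case_mask")
        case_mask = np.zeros(S, dtype=bool)
    case_mask = np.asarray(case_mask, dtype=bool)
    se = float(np.clip(se, 1e-6, 0.5))

    if init is not None:
        phi, pi0, th_c0, th_v0, th_hom0 = init
        phi = np.clip(np.asarray(phi, dtype=float), 1e-8, None)
        phi = phi / phi.sum()
    else:
        phi, pi0, th_c0, th_hom0 = _init_params(x_r, n, case_mask)
        th_v0 = th_c0

    def run_em(phi, pi0, th_c0, th_v0, th_hom0, constrained):
        psi = [logit(np.clip(pi0, 1e-6, 1 - 1e-6)),
               np.log(np.clip(th_c0, 1e-8, 50.0))]
        if group_specific_rho:
            psi.append(np.log(np.clip(th_v0, 1e-8, 50.0)))
        psi.append(np.log(np.clip(th_hom0, 1e-8, 50.0)))
        psi = np.array(psi, dtype=float)
        phi = phi.copy()

        loglik = -np.inf
        converged = False
        resp = None
        for it in range(1, max_iter + 1):
            pi, th_c, th_v, th_hom = _unpack(psi, group_specific_rho)
            comp = _component_logliks(x_r, n, se, pi, th_c, th_v, th_hom, case_mask)
            with np.errstate(divide="ignore"):
                joint = comp + np.log(phi)
            norm = logsumexp(joint, axis=1)
            new_loglik = float(norm.sum())
            # EM guarantees monotone ascent; numerical slack for fp round-off
            if new_loglik < loglik - 1e-6 * (abs(loglik) + 1.0):
                break
            resp = np.exp(joint - norm[:, None])
            if abs(new_loglik - loglik) <= tol * (abs(new_loglik) + 1.0):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
            phi = np.clip(resp.mean(axis=0), 1e-10, None)
            phi = phi / phi.sum()
            objective = _make_mstep_objective(
                x_r, n, se, resp, case_mask, group_specific_rho)
            psi = _mstep_continuous(psi, objective, group_specific_rho, constrained)
        pi, th_c, th_v, th_hom = _unpack(psi, group_specific_rho)
        return phi, pi, th_c, th_v, th_hom, loglik, it, converged, resp

    phi_f, pi, th_c, th_v, th_hom, ll, n_iter, conv, resp = run_em(
        phi, pi0, th_c0, th_v0, th_hom0, constrained=False)

    constrained_refit = False
    cap = max(pi, 1.0 - pi)
    if th_c > cap * (1 + 1e-9) or th_v > cap * (1 + 1e-9):
        constrained_refit = True
        phi_f, pi, th_c, th_v, th_hom, ll, n_iter, conv, resp = run_em(
            phi, pi0, min(th_c0, 0.5), min(th_v0, 0.5), th_hom0, constrained=True)
        cap = max(pi, 1.0 - pi)
        th_c = min(th_c, cap)
        th_v = min(th_v, cap)

    if resp is None:  # first E-step failed to improve -inf (pathological)
        resp = np.full((S, 3), 1.0 / 3.0)
    n_het_c = float(resp[~case_mask, 1].sum())
    n_het_v = float(resp[case_mask, 1].sum())
    unidentifiable = (n_het_c + n_het_v) < 1.0 or phi_f[1] < 1e-4

    return MixtureFit(
        phi_rr=float(phi_f[0]),
        phi_rv=float(phi_f[1]),
        phi_vv=float(phi_f[2]),
        pi_het=pi,
        theta_het_control=th_c,
        theta_het_case=th_v,
        theta_hom=th_hom,
        se=se,
        group_specific=group_specific_rho,
        loglik=ll,
        n_iter=n_iter,
        converged=conv,
        constrained_refit=constrained_refit,
        unidentifiable=unidentifiable,
        responsibilities=resp,
        case_mask=case_mask,
        x_ref=x_r,
        totals=n,
        n_het_control=n_het_c,
        n_het_case=n_het_v,
    )


def detect_outliers(
    x_r,
    x_v,
    sample_ids=None,
    se: float = 0.002,
    threshold: float = 5.0,
    max_iter: int = 60,
) -> OutlierReport:
    """Leave-one-out influence-based outlier flagging for one group's samples.

    The mixture is fit on the full group, then refit leaving out each
    sample in turn (warm-started from the full fit).  A sample is flagged
    when its deletion shifts ``pi_het`` or ``theta_het`` by more than
    ``threshold`` standard deviations of that delta series.  A zero
    standard deviation (exchangeable samples) flags nothing.
    """
    x_r = np.asarray(x_r, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    S = len(x_r)
    if S < 3:
        raise ValueError("need at least 3 samples for leave-one-out deltas")
    if sample_ids is None:
        sample_ids = list(range(S))
    full = fit_mixture(x_r, x_v, se=se, max_iter=max_iter)
    warm = (full.phi, full.pi_het, full.theta_het_control,
            full.theta_het_case, full.theta_hom)

    delta_pi = np.empty(S)
    delta_th = np.empty(S)
    for j in range(S):
        keep = np.ones(S, dtype=bool)
        keep[j] = False
        sub = fit_mixture(x_r[keep], x_v[keep], se=se, init=warm,
                          max_iter=max_iter)
        delta_pi[j] = full.pi_het - sub.pi_het
        delta_th[j] = full.theta_het - sub.theta_het

    flagged = np.zeros(S, dtype=bool)
    for deltas in (delta_pi, delta_th):
        sd = float(np.std(deltas, ddof=1))
        if sd > 0.0:
            flagged |= np.abs(deltas) > threshold * sd
    return OutlierReport(
        sample_ids=list(sample_ids),
        flagged=[sid for sid, f in zip(sample_ids, flagged) if f],
        delta_pi=delta_pi,
        delta_theta=delta_th,
        threshold=threshold,
    )
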