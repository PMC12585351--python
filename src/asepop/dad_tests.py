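"""Per-SNP differential allelic dispersion (dAD) tests.

Two asymptotically equivalent tests of the null hypothesis that the
heterozygote dispersion is shared between controls and cases:

* the likelihood-ratio test between the shared-dispersion and
  group-specific-dispersion mixture fits (one degree of freedom), used for
  the reported per-SNP P values;
* a score test that needs only the null-model fit, used inside label
  permutations: the null fit has no group-specific parameter, so it is
  identical under every relabeling and can be computed once, while the
  score vector and information matrix — which do depend on the labels —
  are cheap to re-evaluate.

The score statistic is the quadratic form of the log-likelihood gradient
in the inverse information matrix, both taken at the null estimate with
the control and case dispersions treated as separate parameters sitting
at the shared fitted value, over
``tau = (pi_het, rho_hom, rho_het_control, rho_het_case, phi_rr, phi_rv)``
(``phi_vv`` is determined by the simplex constraint).  Derivatives are
central finite differences of the mixture log-likelihood on the natural
parameter scale.  The information matrix is the expected (Fisher)
information, accumulated per sample by enumerating the count support
under the fitted null model; unlike the observed Hessian it is positive
semidefinite by construction, which keeps the quadratic form from
exploding when the likelihood is locally non-quadratic in nuisance
directions.  A stencil engine precomputes every per-sample quantity the
permutations can touch, reducing each permutation's score test to a few
matrix-vector products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .distributions import betabin_logpmf_vec, rho_to_theta
from .mixture_em import MixtureFit

__all__ = [
    "SnpDadResult",
    "ScoreTestResult",
    "SingularHessianError",
    "lrt_dad",
    "score_test_dad",
    "ScoreTestEngine",
]

COND_LIMIT = 1e12


class SingularHessianError(np.linalg.LinAlgError):
    """Information matrix numerically singular; score statistic unavailable."""


@dataclass
class SnpDadResult:
    lambda_lrt: float
    p_dad: float
    rho_control: float
    rho_case: float
    pi_het: float
    n_het_control: float
    n_het_case: float
    median_n_control: float
    median_n_case: float
    filter_flags: list = field(default_factory=list)


@dataclass
class ScoreTestResult:
    lambda_st: float
    p_value: float
    score_vector: np.ndarray = field(repr=False)
    information: np.ndarray = field(repr=False)

    @property
    def hessian(self) -> np.ndarray:
        """Expected curvature of the log-likelihood (minus the information)."""
        return -self.information


def _fit_flags(fit: MixtureFit) -> list:
    flags = []
    if not fit.converged:
        flags.append("not_converged")
    if fit.unidentifiable:
        flags.append("unidentifiable")
    if fit.constrained_refit:
        flags.append("constrained_refit")
    if min(fit.theta_het_control, fit.theta_het_case) <= 1.1e-6:
        flags.append("theta_at_floor")
    return flags


def lrt_dad(fit_null: MixtureFit, fit_alt: MixtureFit) -> SnpDadResult:
    """Likelihood-ratio test for dAD between nested mixture fits.

    ``fit_null`` shares one heterozygote dispersion across groups;
    ``fit_alt`` fits control- and case-specific dispersions on the same
    samples.  The statistic ``2 * (l_alt - l_null)`` is referred to a
    chi-square with one degree of freedom (clipped at zero against
    numerical slack).
    """
    if fit_null.totals.shape != fit_alt.totals.shape or not (
        np.array_equal(fit_null.totals, fit_alt.totals)
        and np.array_equal(fit_null.case_mask, fit_alt.case_mask)
    ):
        raise ValueError("null and alternative fits must use identical samples")
    lam = 2.0 * (fit_alt.loglik - fit_null.loglik)
    flags = ["lrt_negative"] if lam < -1e-6 * (abs(fit_null.loglik) + 1.0) else []
    lam = max(lam, 0.0)
    n = fit_alt.totals
    case = fit_alt.case_mask
    return SnpDadResult(
        lambda_lrt=float(lam),
        p_dad=float(chi2.sf(lam, df=1)),
        rho_control=fit_alt.rho_het_control,
        rho_case=fit_alt.rho_het_case,
        pi_het=fit_alt.pi_het,
        n_het_control=fit_alt.n_het_control,
        n_het_case=fit_alt.n_het_case,
        median_n_control=float(np.median(n[~case])) if (~case).any() else np.nan,
        median_n_case=float(np.median(n[case])) if case.any() else np.nan,
        filter_flags=sorted(set(flags + _fit_flags(fit_alt)
                                + _fit_flags(fit_null))),
    )


def _steps(tau: np.ndarray, rel: float = 0.01, floor: float = 0.05) -> np.ndarray:
    """Per-parameter finite-difference steps, clipped to the domain."""
    h = rel * np.maximum(np.abs(tau), floor)
    pi, rho_hom, rho_c, rho_v, phi_rr, phi_rv = tau
    phi_vv = 1.0 - phi_rr - phi_rv
    h[0] = min(h[0], 0.5 * pi, 0.5 * (1.0 - pi))
    for i, rho in ((1, rho_hom), (2, rho_c), (3, rho_v)):
        h[i] = min(h[i], 0.5 * rho if rho > 0 else h[i], 0.5 * (1.0 - rho))
    h[4] = min(h[4], 0.5 * phi_rr, 0.25 * phi_vv) if phi_rr > 0 else h[4]
    h[5] = min(h[5], 0.5 * phi_rv, 0.25 * phi_vv) if phi_rv > 0 else h[5]
    return np.maximum(h, 1e-12)


def _mixture_logpmf(x, n, tau, se, is_case):
    """Log of the group-specific mixture PMF at parameter vector ``tau``."""
    pi, rho_hom, rho_c, rho_v, phi_rr, phi_rv = tau
    phi_vv = 1.0 - phi_rr - phi_rv
    th_hom = rho_to_theta(rho_hom)
    th_het = rho_to_theta(rho_v if is_case else rho_c)
    rr = np.exp(betabin_logpmf_vec(x, n, 1.0 - se, th_hom))
    vv = np.exp(betabin_logpmf_vec(x, n, se, th_hom))
    het = np.exp(betabin_logpmf_vec(x, n, pi, th_het))
    return np.log(phi_rr * rr + phi_rv * het + phi_vv * vv + 1e-300)


class ScoreTestEngine:
    """Precomputed stencil for the dAD score test.

    Built once per SNP from the null fit.  Per-sample gradient stencils
    and per-sample Fisher-information blocks (for either group role) are
    cached, so evaluating one permutation costs a handful of
    matrix-vector products plus a 6x6 solve.
    """

    N_PARAMS = 6

    def __init__(self, x_r, n, tau0, se: float, steps=None):
        x_r = np.asarray(x_r, dtype=float)
        n = np.asarray(n, dtype=float)
        self.tau0 = np.asarray(tau0, dtype=float)
        self.se = float(se)
        self.h = _steps(self.tau0) if steps is None else np.asarray(steps, float)
        self.S = len(n)
        T = self.N_PARAMS

        pi0, rho_hom0, rho_c0, rho_v0 = self.tau0[:4]
        if not np.isclose(rho_c0, rho_v0):
            raise ValueError("score test expects both group dispersions at the "
                             "shared null value")

        # per-sample log-mixture values on the gradient stencil (center and
        # +-h for each parameter), for both group roles
        def stencil_matrices(role_case):
            rows = [_mixture_logpmf(x_r, n, self.tau0, self.se, role_case)]
            for t in range(T):
                for s in (1, -1):
                    tau = self.tau0.copy()
                    tau[t] += s * self.h[t]
                    rows.append(_mixture_logpmf(x_r, n, tau, self.se, role_case))
            return np.asarray(rows)                     # (1 + 2T, S)

        M_ctrl = stencil_matrices(False)
        M_case = stencil_matrices(True)
        self._base = M_ctrl.sum(axis=1)
        self._diff = M_case - M_ctrl

        # per-sample expected information for either role, from enumerating
        # the count support under the fitted null mixture
        uniq = np.unique(n).astype(int)
        info_ctrl = {}
        for nv in uniq:
            xs = np.arange(nv + 1, dtype=float)
            ns = np.full(nv + 1, float(nv))
            logp0 = _mixture_logpmf(xs, ns, self.tau0, self.se, False)
            G = np.empty((T, nv + 1))
            for t in range(T):
                tp = self.tau0.copy()
                tp[t] += self.h[t]
                tm = self.tau0.copy()
                tm[t] -= self.h[t]
                G[t] = (_mixture_logpmf(xs, ns, tp, self.se, False)
                        - _mixture_logpmf(xs, ns, tm, self.se, False)) \
                    / (2.0 * self.h[t])
            info_ctrl[nv] = (G * np.exp(logp0)) @ G.T
        # the case role swaps the two dispersion coordinates
        swap = np.arange(T)
        swap[2], swap[3] = 3, 2
        I_ctrl_flat = np.empty((self.S, T * T))
        I_case_flat = np.empty((self.S, T * T))
        for s in range(self.S):
            blk = info_ctrl[int(n[s])]
            I_ctrl_flat[s] = blk.ravel()
            I_case_flat[s] = blk[np.ix_(swap, swap)].ravel()
        self._info_base = I_ctrl_flat.sum(axis=0)
        self._info_diff = I_case_flat - I_ctrl_flat

    @classmethod
    def from_fit(cls, fit_null: MixtureFit) -> "ScoreTestEngine":
        tau0 = np.array([
            fit_null.pi_het,
            fit_null.rho_hom,
            fit_null.rho_het_control,
            fit_null.rho_het_control,
            fit_null.phi_rr,
            fit_null.phi_rv,
        ])
        return cls(fit_null.x_ref, fit_null.totals, tau0, fit_null.se)

    def evaluate(self, case_mask) -> ScoreTestResult:
        """Score statistic for one control/case labeling of the samples."""
        m = np.asarray(case_mask, dtype=float)
        T = self.N_PARAMS
        ell = self._base + self._diff @ m
        grad = (ell[1:1 + 2 * T:2] - ell[2:2 + 2 * T:2]) / (2.0 * self.h)
        info = (self._info_base + m @ self._info_diff).reshape(T, T)
        info = 0.5 * (info + info.T)
        if not np.all(np.isfinite(info)) or np.linalg.cond(info) > COND_LIMIT:
            raise SingularHessianError("information matrix numerically singular")
        # At the exact restricted MLE every score component vanishes except
        # the antisymmetric dispersion contrast (the shared-dispersion
        # direction is profiled out by the fit); imposing that structure
        # keeps optimizer convergence noise in the nuisance coordinates
        # from leaking into the quadratic form.
        v = np.zeros(T)
        v[2] = 0.5 * (grad[2] - grad[3])
        v[3] = -v[2]
        lam = float(v @ np.linalg.solve(info, v))
        lam = max(lam, 0.0)
        return ScoreTestResult(
            lambda_st=lam,
            p_value=float(chi2.sf(lam, df=1)),
            score_vector=grad / np.sqrt(self.S),
            information=info,
        )


def fit_and_test(x_r, x_v, case_mask, se: float = 0.002):
    """Fit the null and alternative mixtures and run the LRT for one SNP.

    The alternative fit is warm-started from the null fit; if that lands
    below the null likelihood (optimizer failure — the models are nested)
    a cold restart is attempted.  Returns ``(fit_null, fit_alt, result)``.
    """
    from .mixture_em import fit_mixture

    fit_null = fit_mixture(x_r, x_v, case_mask=case_mask, se=se)
    warm = (fit_null.phi, fit_null.pi_het, fit_null.theta_het_control,
            fit_null.theta_het_case, fit_null.theta_hom)
    fit_alt = fit_mixture(x_r, x_v, case_mask=case_mask, se=se,
                          group_specific_rho=True, init=warm)
    if fit_alt.loglik < fit_null.loglik - 1e-9:
        retry = fit_mixture(x_r, x_v, case_mask=case_mask, se=se,
                            group_specific_rho=True)
        if retry.loglik > fit_alt.loglik:
            fit_alt = retry
    return fit_null, fit_alt, lrt_dad(fit_null, fit_alt)


def score_test_dad(fit_null: MixtureFit, case_mask) -> ScoreTestResult:
    """Score test for dAD given the shared-dispersion null fit and labels.

    The null fit is never modified: permuting ``case_mask`` changes only
    the score vector and information matrix.
    """
    return ScoreTestEngine.from_fit(fit_null).evaluate(case_mask)
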