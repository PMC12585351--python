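"""Numerically robust beta-binomial kernel.

The beta-binomial distribution is the workhorse of population-level
allele-specific expression modeling: for a heterozygous sample with total
allelic coverage ``n``, the reference-allele count follows
``BetaBin(n, pi, theta)`` where ``pi`` is the mean allelic fraction
(allelic bias) and ``theta`` (equivalently ``rho = theta / (1 + theta)``)
captures the population-level overdispersion of allelic fractions
(allelic dispersion).

Two algebraically equivalent PMF evaluations are provided:

* a beta-function form, fast and vectorizable via ``betaln``/``gammaln``,
  but subject to catastrophic cancellation when ``theta`` is tiny (the two
  log-beta terms grow while their difference stays moderate);
* an exact log-space product form, slower (O(n)) but free of cancellation.

A precision policy arbitrates between them and, as a last resort, escalates
the beta-function form to extended precision (mpmath) before defaulting to
the plain binomial PMF.  Policy escalations are counted, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp

__all__ = [
    "BetaBinParams",
    "PrecisionPolicy",
    "betabin_logpmf",
    "betabin_logpmf_vec",
    "betabin_cmf",
    "betabin_loglik_grad",
    "rho_theta_transform",
    "rho_to_theta",
    "theta_to_rho",
]


def theta_to_rho(theta: float) -> float:
    """Map overdispersion theta in [0, inf) to rho = theta/(1+theta) in [0, 1)."""
    theta = float(theta)
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if np.isinf(theta):
        return 1.0
    return theta / (1.0 + theta)


def rho_to_theta(rho: float) -> float:
    """Inverse of :func:`theta_to_rho`; rho == 1 (infinite theta) is rejected."""
    rho = float(rho)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    return rho / (1.0 - rho)


def rho_theta_transform(value: float, direction: str) -> float:
    """Transform between the two overdispersion parameterizations.

    Parameters
    ----------
    value
        The parameter value to transform.
    direction
        ``"theta_to_rho"`` or ``"rho_to_theta"``.
    """
    if direction == "theta_to_rho":
        return theta_to_rho(value)
    if direction == "rho_to_theta":
        return rho_to_theta(value)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class BetaBinParams:
    """Beta-binomial parameters (mean fraction ``pi``, overdispersion ``theta``)."""

    pi: float
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if not self.theta >= 0.0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")

    @property
    def rho(self) -> float:
        return theta_to_rho(self.theta)

    @classmethod
    def from_rho(cls, pi: float, rho: float) -> "BetaBinParams":
        return cls(pi=pi, theta=rho_to_theta(rho))


@dataclass
class PrecisionPolicy:
    """Arbitration policy for PMF evaluation.

    cancel_rel_gap: the beta-function form is distrusted when its two
        log-beta terms agree to within this relative gap (catastrophic
        cancellation of leading digits).
    product_max_n: maximum total count for which the exact log-space
        product form is attempted.
    max_bits: precision cap for the mpmath escalation stage; beyond it the
        evaluation falls back to the binomial PMF and the fallback counter
        is incremented.
    """

    cancel_rel_gap: float = 1e-8
    product_max_n: int = 100_000
    max_bits: int = 2048
    counters: dict = field(
        default_factory=lambda: {"cancellation": 0, "mpmath": 0, "binomial_fallback": 0}
    )


_DEFAULT_POLICY = PrecisionPolicy()


def _validate_xn(x: int, n: int) -> None:
    if n < 0 or x < 0 or x > n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")


def _binom_logpmf(x, n, p):
    """Binomial log PMF; handles p in {0, 1} exactly."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    logc = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = logc + np.where(x > 0, x * np.log(p), 0.0) + np.where(
            n - x > 0, (n - x) * np.log1p(-p), 0.0
        )
    return out


def _logpmf_beta_terms(x, n, pi, theta):
    """Beta-function form; returns (logpmf, t_plus, t_minus) for cancellation checks."""
    a = pi / theta
    b = (1.0 - pi) / theta
    t_plus = betaln(x + a, n - x + b)
    t_minus = betaln(a, b)
    logc = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return logc + t_plus - t_minus, t_plus, t_minus


def _logpmf_product(x: int, n: int, pi: float, theta: float) -> float:
    """Exact log-space evaluation of the rising-product PMF form."""
    logc = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    ks = np.arange(max(x, n - x, n), dtype=float)
    num1 = np.log(pi + ks[:x] * theta).sum() if x > 0 else 0.0
    num2 = np.log((1.0 - pi) + ks[: n - x] * theta).sum() if n - x > 0 else 0.0
    den = np.log1p(ks[1:n] * theta).sum() if n > 1 else 0.0
    return float(logc + num1 + num2 - den)


def _logpmf_mpmath(x: int, n: int, pi: float, theta: float, bits: int) -> float:
    import mpmath as mp

    with mp.workprec(bits):
        a = mp.mpf(pi) / mp.mpf(theta)
        b = (1 - mp.mpf(pi)) / mp.mpf(theta)
        val = (
            mp.loggamma(n + 1)
            - mp.loggamma(x + 1)
            - mp.loggamma(n - x + 1)
            + mp.loggamma(x + a)
            + mp.loggamma(n - x + b)
            - mp.loggamma(n + a + b)
            - mp.loggamma(a)
            - mp.loggamma(b)
            + mp.loggamma(a + b)
        )
        return float(val)


def betabin_logpmf(
    x: int,
    n: int,
    params: BetaBinParams,
    policy: PrecisionPolicy | None = None,
) -> float:
    """Log PMF of the beta-binomial distribution at a single count.

    ``theta == 0`` returns the binomial log PMF exactly.  Otherwise the
    beta-function form is used unless cancellation is detected, in which
    case the policy escalates (product form, extended precision, binomial
    fallback).
    """
    policy = policy or _DEFAULT_POLICY
    _validate_xn(x, n)
    pi, theta = params.pi, params.theta
    if theta == 0.0 or pi == 0.0 or pi == 1.0:
        # degenerate beta components collapse to a binomial point mass in p
        return float(_binom_logpmf(x, n, pi))
    if n == 0:
        return 0.0
    val, t_plus, t_minus = _logpmf_beta_terms(
        float(x), float(n), pi, theta
    )
    gap = abs(t_plus - t_minus)
    scale = max(abs(t_plus), abs(t_minus), 1.0)
    if np.isfinite(val) and gap / scale > policy.cancel_rel_gap:
        return float(val)
    policy.counters["cancellation"] += 1
    if n <= policy.product_max_n:
        return _logpmf_product(x, n, pi, theta)
    for bits in (128, 256, 512, 1024, 2048):
        if bits > policy.max_bits:
            break
        policy.counters["mpmath"] += 1
        val = _logpmf_mpmath(x, n, pi, theta, bits)
        if np.isfinite(val):
            return val
    policy.counters["binomial_fallback"] += 1
    return float(_binom_logpmf(x, n, pi))


def betabin_logpmf_vec(x, n, pi: float, theta: float):
    """Vectorized beta-binomial log PMF (fast path, no escalation policy).

    Intended for the EM / score-test inner loops where parameters are kept
    in safe ranges by the optimizer's transform clipping.  ``x`` and ``n``
    broadcast; ``pi`` and ``theta`` are scalars.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if theta == 0.0 or pi == 0.0 or pi == 1.0:
        return _binom_logpmf(x, n, pi)
    val, _, _ = _logpmf_beta_terms(x, n, pi, theta)
    return val


def betabin_cmf(x: int, n: int, params: BetaBinParams,
                policy: PrecisionPolicy | None = None) -> float:
    """Cumulative mass P(X <= x); ``cmf(n) == 1`` within numerical tolerance."""
    _validate_xn(x, n)
    xs = np.arange(0, x + 1)
    lp = betabin_logpmf_vec(xs, n, params.pi, params.theta)
    if not np.all(np.isfinite(lp)):
        lp = np.array([betabin_logpmf(int(xi), n, params, policy) for xi in xs])
    return float(min(1.0, np.exp(logsumexp(lp))))


def _grad_single(x, n, pi, theta):
    """Analytic (d/dpi, d/dtheta) of the log PMF via digamma; arrays ok."""
    a = pi / theta
    b = (1.0 - pi) / theta
    # d betaln(a,b)/da = digamma(a) - digamma(a+b)
    da = digamma(x + a) - digamma(n + a + b) - digamma(a) + digamma(a + b)
    db = digamma(n - x + b) - digamma(n + a + b) - digamma(b) + digamma(a + b)
    dpi = da / theta - db / theta
    dtheta = -(a / theta) * da - (b / theta) * db
    return dpi, dtheta


def betabin_loglik_grad(
    data,
    params: BetaBinParams,
    weights=None,
    policy: PrecisionPolicy | None = None,
):
    """Gradient of the weighted log-likelihood over (pi, theta).

    ``data`` is a sequence of ``(x, n)`` pairs (or a 2-column array);
    ``weights`` in [0, 1] default to 1.  Analytic digamma expressions are
    used in the interior; at ``theta == 0`` or boundary ``pi`` the theta
    derivative is taken by one-sided finite differences.
    """
    arr = np.asarray(data, dtype=float)
    x, n = arr[:, 0], arr[:, 1]
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    pi, theta = params.pi, params.theta

    if theta > 0.0 and 0.0 < pi < 1.0:
        dpi, dth = _grad_single(x, n, pi, theta)
        return float(np.sum(w * dpi)), float(np.sum(w * dth))

    # boundary: fall back to finite differences of the log-likelihood
    def ll(p, t):
        return float(np.sum(w * betabin_logpmf_vec(x, n, p, t)))

    h = 1e-6
    if 0.0 < pi < 1.0:
        dpi = (ll(min(pi + h, 1.0), theta) - ll(max(pi - h, 0.0), theta)) / (2 * h)
    else:
        lo, hi = (pi, pi + h) if pi == 0.0 else (pi - h, pi)
        dpi = (ll(hi, theta) - ll(lo, theta)) / h
    dth = (ll(pi, theta + h) - ll(pi, theta)) / h
    return float(dpi), float(dth)
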