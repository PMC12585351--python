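"""Moment estimators of beta-binomial parameters for unequal totals.

Kleinman-style method-of-moments starting values for the heterozygote
component: the mean allelic fraction ``pi`` as a weighted mean of
per-sample fractions and ``theta`` from the weighted sum of squares,
generalized to samples with differing total counts.  With all weights set
to 1 (the ideal weights for the zero-dispersion case) these are rough but
cheap initial estimates which the EM fit subsequently refines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MomentEstimate", "kleinman_estimate"]

THETA_FLOOR = 1e-6


@dataclass
class MomentEstimate:
    pi_hat: float
    theta_hat: float
    q: float
    z_s: np.ndarray
    w_s: np.ndarray
    p_hat_s: np.ndarray
    clamped: bool


def kleinman_estimate(data, weights=None, theta_floor: float = THETA_FLOOR) -> MomentEstimate:
    """Moment estimates of (pi, theta) from per-sample (x, n) counts.

    Parameters
    ----------
    data
        Sequence of ``(x, n)`` pairs (reference count, total count).
    weights
        Per-sample weights; default all 1.
    theta_floor
        Non-positive or non-finite theta estimates (e.g. under-dispersed
        data) are clamped here and flagged via ``clamped``.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 observations of (x, n)")
    x, n = arr[:, 0], arr[:, 1]
    if np.all(n == 0):
        raise ValueError("all totals are zero")
    keep = n > 0
    x, n = x[keep], n[keep]
    w = np.ones_like(n) if weights is None else np.asarray(weights, dtype=float)[keep]

    p_hat = x / n
    w_sum = w.sum()
    pi_hat = float(np.sum(w * p_hat) / w_sum)
    q = float(np.sum(w * (p_hat - pi_hat) ** 2))
    z = 1.0 - w / w_sum

    clamped = False
    num = pi_hat * (1.0 - pi_hat) * (np.sum(w * z) - np.sum(w * z / n))
    den = q - pi_hat * (1.0 - pi_hat) * np.sum(w * z / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
        theta_hat = 1.0 / (ratio - 1.0) if np.isfinite(ratio) else np.nan
    if not np.isfinite(theta_hat) or theta_hat <= 0.0:
        theta_hat = theta_floor
        clamped = True
    return MomentEstimate(
        pi_hat=pi_hat,
        theta_hat=float(theta_hat),
        q=q,
        z_s=z,
        w_s=w,
        p_hat_s=p_hat,
        clamped=clamped,
    )
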