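"""Hypothetical repeatability of fluctuating asymmetry.

Unsigned FA of one trait is a single noisy draw from an individual's
developmental-instability (DI) distribution, so even perfectly measured FA is
a weak proxy of DI.  The hypothetical repeatability R quantifies the fraction
of between-individual variance in unsigned FA attributable to real variation
in DI, modelling the signed asymmetry of individual i as N(0, sigma_i^2) with
sigma_i varying among individuals:

    R = (2/pi) * Var(sigma) / (E sigma^2 - (2/pi) * (E sigma)^2)

which, written in terms of the coefficient of variation of sigma (scale-free,
E sigma = 1), is R = (2/pi) cv^2 / (1 + cv^2 - 2/pi), bounded above by
2/pi ~ 0.637.  The moment estimator below additionally removes measurement
noise tau^2 = 2*sigma_me^2/K from the observed side differences; negative
estimates are possible (and are reported, not truncated) when sampling noise
dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RepeatabilityEstimate", "analytic_R", "estimate_R", "TWO_OVER_PI"]

TWO_OVER_PI = 2.0 / np.pi


@dataclass
class RepeatabilityEstimate:
    R: float | None
    E_sigma: float
    V_sigma: float
    E_sigma2: float
    tau2: float
    defined: bool


def analytic_R(cv_sigma: float) -> float:
    """Hypothetical repeatability for a given CV of sigma_i among individuals.

    Increases from 0 (cv = 0, no DI heterogeneity) towards the half-normal
    ceiling 2/pi as cv grows.
    """
    if cv_sigma < 0:
        raise ValueError("cv_sigma must be >= 0")
    cv2 = cv_sigma**2
    return TWO_OVER_PI * cv2 / (1.0 + cv2 - TWO_OVER_PI)


def estimate_R(
    raw_signed_fa: np.ndarray, sigma_me: float = 0.0, K: int = 1
) -> RepeatabilityEstimate:
    """Moment estimator of R from raw (unshrunken) DA-corrected differences.

    With d_i = raw signed FA and tau^2 = 2*sigma_me^2/K the noise variance of
    a per-individual side difference:

        M2      = mean(d^2) - tau^2          (estimates E sigma^2)
        E_sigma = sqrt(max((mean|d| * sqrt(pi/2))^2 - tau^2, 0))
        V_sigma = M2 - E_sigma^2
        R       = (2/pi) * V_sigma / (M2 - (2/pi) * E_sigma^2)

    The estimate is undefined (``defined=False``) when the denominator is not
    positive.  Population (divide-by-n) moments are used; the ME correction is
    first order and exact when cv = 0.  BLUP-shrunken inputs must not be used:
    shrinkage already encodes the variance components and would deflate
    V_sigma.
    """
    d = np.asarray(raw_signed_fa, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 10:
        raise ValueError("need >= 10 individuals: the moment estimator is unstable")
    if sigma_me < 0 or K < 1:
        raise ValueError("sigma_me must be >= 0 and K >= 1")
    tau2 = 2.0 * sigma_me**2 / K
    M2 = float(np.mean(d**2)) - tau2
    E_sigma = float(np.sqrt(max((np.mean(np.abs(d)) * np.sqrt(np.pi / 2.0)) ** 2 - tau2, 0.0)))
    V_sigma = M2 - E_sigma**2
    denom = M2 - TWO_OVER_PI * E_sigma**2
    if denom > 0:
        return RepeatabilityEstimate(
            R=TWO_OVER_PI * V_sigma / denom,
            E_sigma=E_sigma,
            V_sigma=V_sigma,
            E_sigma2=M2,
            tau2=tau2,
            defined=True,
        )
    return RepeatabilityEstimate(
        R=None, E_sigma=E_sigma, V_sigma=V_sigma, E_sigma2=M2, tau2=tau2, defined=False
    )
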