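"""Mixed regression decomposition of bilateral measurements.

For one trait measured on both sides in K digitization sessions the model is

    y_ijk = mu + delta * x_j + b_i + s_i * x_j + e_ijk

with side coded x = -0.5 (left) / +0.5 (right), individual effect
b_i ~ N(0, sigma2_ind), individual-by-side interaction (signed asymmetry)
s_i ~ N(0, sigma2_fa) and digitization error e ~ N(0, sigma2_me).  Under this
coding ``delta`` is the population right-minus-left difference (directional
asymmetry, DA), ``sigma_fa`` the SD of true fluctuating asymmetry (FA) and
``sigma_me`` the measurement-error SD.

Variance components are estimated by REML under nonnegativity constraints;
the DA test is a likelihood-ratio test between full-ML fits with and without
the fixed side term (REML likelihoods are not comparable across fixed-effect
structures); the test for real FA is a REML boundary LRT of sigma2_fa = 0
with the 50:50 chi2_0/chi2_1 mixture reference.

Per-individual signed FA is the DA-corrected right-minus-left difference,
either raw or as its BLUP (shrunken by the FA/(FA+error) variance ratio, the
mixed model's random-slope prediction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAFit",
    "DATest",
    "RealFATest",
    "SignedFAEstimates",
    "fit_fa_model",
    "restricted_loglik",
    "test_directional_asymmetry",
    "test_real_fa",
    "signed_fa",
    "summarize_traits",
    "fit_all_traits",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FAFit:
    trait_id: str
    mu_hat: float
    delta_hat: float
    sigma_ind: float
    sigma_fa: float
    sigma_me: float
    reml_loglik: float
    n_individuals: int
    converged: bool = True

    @property
    def da_percent_of_size(self) -> float:
        return 100.0 * self.delta_hat / self.mu_hat


@dataclass
class DATest:
    chi2: float
    df: int = 1
    p: float | None = None
    converged: bool = True


@dataclass
class RealFATest:
    chi2: float
    p: float | None = None
    converged: bool = True


@dataclass
class SignedFAEstimates:
    """Per-individual signed FA (right minus left, DA-corrected).

    ``table`` has columns individual, trait, raw, blup; ``flag`` selects which
    column :meth:`values` returns by default.
    """

    table: pd.DataFrame
    flag: str = "blup"

    def values(self, mode: str | None = None) -> pd.DataFrame:
        mode = mode or self.flag
        if mode not in ("blup", "raw"):
            raise ValueError(f"mode must be 'blup' or 'raw', got {mode!r}")
        return self.table.pivot(index="individual", columns="trait", values=mode)


# ---------------------------------------------------------------------------
# likelihood machinery


@dataclass
class _Grouped:
    """Measurements grouped by identical within-individual design pattern."""

    patterns: list[np.ndarray]  # x vector per pattern (length m_g)
    Y: list[np.ndarray]  # (n_g, m_g) responses per pattern
    n_obs: int
    n_individuals: int
    individuals: list[list[str]] = field(default_factory=list)


def _group(measurements: pd.DataFrame) -> _Grouped:
    df = measurements
    if df["value"].isna().any():
        raise ValueError("missing measurement values")
    if "trait" in df.columns and df["trait"].nunique() > 1:
        raise ValueError(
            "measurements contain several traits; fit one trait at a time "
            "(see fit_all_traits)"
        )
    x = np.where(df["side"].to_numpy() == "R", 0.5, -0.5)
    order = np.lexsort(
        (df["session"].to_numpy(), x, df["individual"].to_numpy())
    )
    ind = df["individual"].to_numpy()[order]
    xs = x[order]
    ys = df["value"].to_numpy(dtype=float)[order]

    by_pattern: dict[tuple, list] = {}
    ind_by_pattern: dict[tuple, list] = {}
    start = 0
    uniq, starts = np.unique(ind, return_index=True)
    starts = np.sort(starts)
    bounds = list(starts) + [len(ind)]
    for i in range(len(bounds) - 1):
        sl = slice(bounds[i], bounds[i + 1])
        key = tuple(xs[sl])
        by_pattern.setdefault(key, []).append(ys[sl])
        ind_by_pattern.setdefault(key, []).append(ind[sl][0])
    patterns = [np.array(k) for k in by_pattern]
    Y = [np.vstack(v) for v in by_pattern.values()]
    return _Grouped(
        patterns=patterns,
        Y=Y,
        n_obs=len(ys),
        n_individuals=len(bounds) - 1,
        individuals=list(ind_by_pattern.values()),
    )


def _loglik(
    theta: np.ndarray,
    g: _Grouped,
    reml: bool,
    with_delta: bool,
    include_fa: bool = True,
    return_beta: bool = False,
):
    """Profile (REML or ML) log-likelihood at variance components ``theta``.

    ``theta`` is (sigma2_ind, sigma2_fa, sigma2_me) when ``include_fa`` else
    (sigma2_ind, sigma2_me).  Returns -inf for a singular marginal covariance.
    """
    if include_fa:
        s2i, s2f, s2m = theta
    else:
        s2i, s2m = theta
        s2f = 0.0
    p = 2 if with_delta else 1
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for xvec, Y in zip(g.patterns, g.Y):
        m = len(xvec)
        V = s2i + s2f * np.outer(xvec, xvec) + s2m * np.eye(m)
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return (-np.inf, None) if return_beta else -np.inf
        logdet += 2.0 * np.log(np.diag(C)).sum() * Y.shape[0]
        X = np.ones((m, p))
        if with_delta:
            X[:, 1] = xvec
        # solve against the cholesky factor
        CiX = np.linalg.solve(C, X)
        CiY = np.linalg.solve(C, Y.T)  # (m, n_g)
        XtVX += Y.shape[0] * CiX.T @ CiX
        XtVy += CiX.T @ CiY.sum(axis=1)
        ytVy += float(np.einsum("ij,ij->", CiY, CiY))
    try:
        Cx = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return (-np.inf, None) if return_beta else -np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    yPy = ytVy - XtVy @ beta
    N = g.n_obs
    if reml:
        logdet_xtvx = 2.0 * np.log(np.diag(Cx)).sum()
        ll = -0.5 * (logdet + logdet_xtvx + yPy + (N - p) * _LOG2PI)
    else:
        ll = -0.5 * (logdet + yPy + N * _LOG2PI)
    return (ll, beta) if return_beta else ll


def restricted_loglik(
    components: tuple[float, float, float], measurements: pd.DataFrame
) -> float:
    """REML log-likelihood at ``(sigma2_ind, sigma2_fa, sigma2_me)``.

    Fixed effects (mu, delta) are profiled out.  Returns ``-inf`` when the
    marginal covariance is singular.
    """
    theta = np.asarray(components, dtype=float)
    if (theta < 0).any():
        raise ValueError("variance components must be nonnegative")
    return _loglik(theta, _group(measurements), reml=True, with_delta=True)


def _moment_starts(g: _Grouped) -> tuple[float, float, float, float]:
    """ANOVA-style starting values (s2i, s2f, s2m) and the response scale."""
    all_y = np.concatenate([Y.ravel() for Y in g.Y])
    scale = max(float(np.var(all_y)), 1e-12)
    within, d_list, m_list, wsum = [], [], [], 0.0
    for xvec, Y in zip(g.patterns, g.Y):
        for side_val in (-0.5, 0.5):
            mask = xvec == side_val
            if mask.sum() >= 2:
                cell = Y[:, mask]
                within.append(((cell - cell.mean(axis=1, keepdims=True)) ** 2).sum())
                wsum += Y.shape[0] * (mask.sum() - 1)
        has_l, has_r = (xvec == -0.5).any(), (xvec == 0.5).any()
        if has_l and has_r:
            mr = Y[:, xvec == 0.5].mean(axis=1)
            ml = Y[:, xvec == -0.5].mean(axis=1)
            d_list.append(mr - ml)
            m_list.append((mr + ml) / 2.0)
    s2m0 = float(np.sum(within) / wsum) if wsum > 0 else 0.05 * scale
    d = np.concatenate(d_list) if d_list else np.array([])
    mm = np.concatenate(m_list) if m_list else np.array([])
    var_d = float(np.var(d, ddof=1)) if len(d) > 1 else scale
    var_m = float(np.var(mm, ddof=1)) if len(mm) > 1 else scale
    s2f0 = max(var_d - 2.0 * s2m0, 1e-4 * scale)
    s2i0 = max(var_m - 0.5 * s2m0, 1e-4 * scale)
    return s2i0, s2f0, max(s2m0, 1e-6 * scale), scale


def _balanced_K(g: _Grouped) -> int | None:
    """Sessions per side if the design is fully balanced, else None."""
    if len(g.patterns) != 1:
        return None
    x = g.patterns[0]
    kl, kr = int(np.sum(x == -0.5)), int(np.sum(x == 0.5))
    return kl if (kl == kr and kl >= 1) else None


def _fit_balanced(
    g: _Grouped, reml: bool, with_delta: bool, include_fa: bool = True
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Exact constrained REML/ML for a fully balanced design.

    The block covariance V = s2i*J + s2f*xx' + s2m*I is simultaneously
    diagonalized by the all-ones vector (eigenvalue l1 = 2K*s2i + s2m), the
    side contrast x (l2 = K/2*s2f + s2m) and 2K-2 residual directions (s2m),
    and the fixed effects mu, delta load on the first two directions only.
    The likelihood therefore factorizes into three independent Gaussian
    samples and the constrained optimum is closed form: unconstrained moment
    solutions, or, when a component is pinned at zero, a pooled error
    variance.  Log-likelihood values match :func:`_loglik` exactly (same
    fixed-effect basis).
    """
    K = _balanced_K(g)
    x = g.patterns[0]
    Y = g.Y[0]
    n = Y.shape[0]
    N = g.n_obs
    p = 2 if with_delta else 1

    ybar = Y.mean(axis=1)  # per-individual grand mean
    d = Y[:, x == 0.5].mean(axis=1) - Y[:, x == -0.5].mean(axis=1)
    z1 = np.sqrt(2 * K) * ybar
    z2 = np.sqrt(K / 2.0) * d
    SS1 = float(np.sum((z1 - z1.mean()) ** 2))
    SS2 = float(np.sum((z2 - z2.mean()) ** 2)) if with_delta else float(np.sum(z2**2))
    if K >= 2:
        cells = np.concatenate([Y[:, x == -0.5], Y[:, x == 0.5]], axis=0)
        SS_w = float(((cells - cells.mean(axis=1, keepdims=True)) ** 2).sum())
        N_w = n * 2 * (K - 1)
    else:
        SS_w, N_w = 0.0, 0

    if N_w > 0 and SS_w == 0.0:
        # identical replicate sessions: zero ME; collapse to K = 1
        gg = _Grouped(
            patterns=[np.array([-0.5, 0.5])],
            Y=[np.column_stack([Y[:, x == -0.5].mean(axis=1), Y[:, x == 0.5].mean(axis=1)])],
            n_obs=2 * n,
            n_individuals=n,
            individuals=g.individuals,
        )
        # the likelihood diverges as s2m -> 0; report the collapsed-basis
        # log-likelihood (consistent across nested fits on the same data)
        return _fit_balanced(gg, reml, with_delta, include_fa)

    df1 = n - 1 if reml else n
    df2 = (n - 1 if reml else n) if with_delta else n

    def loglik_at(l1: float, l2: float, s2m: float) -> float:
        terms = 0.0
        for lam, SS, cnt in ((l1, SS1, n), (l2, SS2, n)):
            if lam <= 0:
                # SS == 0 with zero variance is a degenerate (point-mass)
                # direction: the likelihood supremum is +inf
                return -np.inf if SS > 0 else np.inf
            terms += cnt * np.log(lam) + SS / lam
        if N_w > 0:
            if s2m <= 0:
                return -np.inf
            terms += N_w * np.log(s2m) + SS_w / s2m
        if reml:
            terms += np.log(2 * K * n / l1)
            if with_delta:
                terms += np.log((K / 2.0) * n / l2)
            return -0.5 * (terms + (N - p) * _LOG2PI)
        return -0.5 * (terms + N * _LOG2PI)

    subsets = [(False, True), (True, True)] if not include_fa else [
        (False, False), (True, False), (False, True), (True, True)
    ]
    best = None
    for pin_i, pin_f in subsets:
        num, den = SS_w, N_w
        if pin_i:
            num, den = num + SS1, den + df1
        if pin_f:
            num, den = num + SS2, den + df2
        s2m = num / den if den > 0 else 0.0
        l1 = s2m if pin_i else SS1 / df1
        l2 = s2m if pin_f else SS2 / df2
        s2i = 0.0 if pin_i else (l1 - s2m) / (2 * K)
        s2f = 0.0 if pin_f else (l2 - s2m) / (K / 2.0)
        if s2i < 0 or s2f < 0:
            continue
        ll = loglik_at(l1, l2, s2m)
        if best is None or ll > best[1]:
            best = (np.array([s2i, s2f, s2m]), ll)
    if best is None:  # all candidates infeasible (degenerate); pin everything
        s2m = (SS_w + SS1 + SS2) / max(N_w + df1 + df2, 1)
        best = (np.array([0.0, 0.0, s2m]), loglik_at(s2m, s2m, s2m))
    theta, ll = best
    beta = np.array([ybar.mean(), d.mean()]) if with_delta else np.array([ybar.mean()])
    if not include_fa:
        theta = np.array([theta[0], theta[2]])
    return theta, ll, beta, True


def _maximize(
    g: _Grouped, reml: bool, with_delta: bool, include_fa: bool = True
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Maximize the profile likelihood over nonnegative variance components.

    Balanced designs use the exact closed form; unbalanced data fall back to
    bounded quasi-Newton with Nelder-Mead polish and boundary refits.
    """
    if _balanced_K(g) is not None:
        return _fit_balanced(g, reml, with_delta, include_fa)
    s2i0, s2f0, s2m0, scale = _moment_starts(g)
    if include_fa:
        start = np.array([s2i0, s2f0, s2m0])
    else:
        start = np.array([s2i0 + s2f0 / 4.0, s2m0])
    k = len(start)
    ub = 50.0 * scale

    def neg(theta):
        ll = _loglik(theta, g, reml, with_delta, include_fa)
        return 1e300 if not np.isfinite(ll) else -ll

    def solve_from(x0, free=None):
        free = list(range(k)) if free is None else free
        fixed = np.zeros(k)

        def neg_sub(sub):
            t = fixed.copy()
            t[free] = np.clip(sub, 0.0, ub)
            return neg(t)

        res = optimize.minimize(
            neg_sub,
            x0[free],
            method="L-BFGS-B",
            bounds=[(0.0, ub)] * len(free),
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        # Nelder-Mead polish (clipped into bounds)
        res2 = optimize.minimize(
            neg_sub,
            res.x,
            method="Nelder-Mead",
            options={
                "xatol": 1e-12 * max(scale, 1.0),
                "fatol": 1e-12,
                "maxiter": 2000,
            },
        )
        best = res2 if res2.fun <= res.fun else res
        t = fixed.copy()
        t[free] = np.clip(best.x, 0.0, ub)
        return t, -neg(t), bool(res.success or res2.success)

    candidates = [start, start * 0.3, start * 3.0, np.full(k, scale / k)]
    best_theta, best_ll, any_ok = None, -np.inf, False
    for x0 in candidates:
        t, ll, ok = solve_from(np.clip(x0, 0.0, ub))
        any_ok = any_ok or ok
        if ll > best_ll:
            best_theta, best_ll = t, ll
    # boundary refits when a component sits near zero
    near0 = [j for j in range(k) if best_theta[j] < 1e-3 * scale]
    for j in near0:
        free = [i for i in range(k) if i != j]
        if not free:
            continue
        t, ll, ok = solve_from(best_theta, free=free)
        if ll >= best_ll - 1e-12:
            best_theta, best_ll = t, ll
            any_ok = any_ok or ok
    ll, beta = _loglik(best_theta, g, reml, with_delta, include_fa, return_beta=True)
    return best_theta, ll, beta, any_ok


def _check_identifiable(g: _Grouped) -> None:
    n_both = sum(
        Y.shape[0]
        for xvec, Y in zip(g.patterns, g.Y)
        if (xvec == -0.5).any() and (xvec == 0.5).any()
    )
    sides = {v for xvec in g.patterns for v in xvec}
    if len(sides) < 2:
        raise ValueError("trait observed on one side only: asymmetry unidentifiable")
    if n_both < 2:
        raise ValueError("need >= 2 individuals measured on both sides")


def fit_fa_model(measurements: pd.DataFrame, trait_id: str | None = None) -> FAFit:
    """REML fit of the bilateral mixed model for a single trait.

    Returns variance-component SDs (sigma_ind, sigma_fa, sigma_me), the DA
    estimate ``delta_hat`` (right minus left), the overall mean ``mu_hat``
    and the REML log-likelihood at the optimum.  Data may be unbalanced.
    """
    if trait_id is None and "trait" in measurements.columns:
        traits = measurements["trait"].unique()
        trait_id = str(traits[0]) if len(traits) == 1 else None
    if trait_id is not None and "trait" in measurements.columns:
        sub = measurements[measurements["trait"] == trait_id]
        if sub["trait"].nunique() == 1:
            measurements = sub
    g = _group(measurements)
    _check_identifiable(g)

    all_y = np.concatenate([Y.ravel() for Y in g.Y])
    if np.ptp(all_y) == 0.0:
        warnings.warn("zero total variance: all variance components set to 0")
        return FAFit(
            trait_id=trait_id or "trait",
            mu_hat=float(all_y[0]),
            delta_hat=0.0,
            sigma_ind=0.0,
            sigma_fa=0.0,
            sigma_me=0.0,
            reml_loglik=np.inf,
            n_individuals=g.n_individuals,
        )

    theta, ll, beta, ok = _maximize(g, reml=True, with_delta=True)
    return FAFit(
        trait_id=trait_id or "trait",
        mu_hat=float(beta[0]),
        delta_hat=float(beta[1]),
        sigma_ind=float(np.sqrt(theta[0])),
        sigma_fa=float(np.sqrt(theta[1])),
        sigma_me=float(np.sqrt(theta[2])),
        reml_loglik=float(ll),
        n_individuals=g.n_individuals,
        converged=ok,
    )


def test_directional_asymmetry(measurements: pd.DataFrame) -> DATest:
    """Likelihood-ratio test of the fixed side effect (DA).

    Compares full-ML fits with and without the side term; the statistic is
    referred to chi-square with 1 df.
    """
    g = _group(measurements)
    _check_identifiable(g)
    all_y = np.concatenate([Y.ravel() for Y in g.Y])
    if np.ptp(all_y) == 0.0:
        return DATest(chi2=0.0, p=1.0)
    _, ll1, _, ok1 = _maximize(g, reml=False, with_delta=True)
    _, ll0, _, ok0 = _maximize(g, reml=False, with_delta=False)
    if not (np.isfinite(ll1) and np.isfinite(ll0)):
        if ll1 == ll0:  # both degenerate in the same direction: no evidence
            return DATest(chi2=0.0, p=1.0, converged=ok1 and ok0)
        return DATest(chi2=np.nan, p=None, converged=False)
    chi2 = max(0.0, 2.0 * (ll1 - ll0))
    p = 1.0 if chi2 == 0.0 else float(stats.chi2.sf(chi2, 1))
    return DATest(chi2=chi2, p=p, converged=ok1 and ok0)


def test_real_fa(measurements: pd.DataFrame) -> RealFATest:
    """REML boundary LRT of sigma2_fa = 0 ("is there real FA beyond ME?").

    The null value lies on the boundary of the parameter space, so the
    reference distribution is the 50:50 mixture of chi2_0 and chi2_1:
    p = 0.5 * P(chi2_1 > LRT), with p = 1 reported at LRT = 0.  Requires
    session replication (K >= 2), otherwise FA and ME are confounded.
    """
    g = _group(measurements)
    _check_identifiable(g)
    replicated = any(
        (np.sum(xvec == s) >= 2) for xvec in g.patterns for s in (-0.5, 0.5)
    )
    if not replicated:
        raise ValueError(
            "real-FA test needs >= 2 digitization sessions: with K = 1 the FA "
            "and measurement-error variances are confounded"
        )
    all_y = np.concatenate([Y.ravel() for Y in g.Y])
    if np.ptp(all_y) == 0.0:
        return RealFATest(chi2=0.0, p=1.0)
    _, ll1, _, ok1 = _maximize(g, reml=True, with_delta=True, include_fa=True)
    _, ll0, _, ok0 = _maximize(g, reml=True, with_delta=True, include_fa=False)
    if not (np.isfinite(ll1) and np.isfinite(ll0)):
        if ll1 == ll0:
            return RealFATest(chi2=0.0, p=1.0, converged=ok1 and ok0)
        return RealFATest(chi2=np.nan, p=None, converged=False)
    chi2 = max(0.0, 2.0 * (ll1 - ll0))
    p = 1.0 if chi2 == 0.0 else float(0.5 * stats.chi2.sf(chi2, 1))
    return RealFATest(chi2=chi2, p=p, converged=ok1 and ok0)


def signed_fa(
    fit: FAFit, measurements: pd.DataFrame, flag: str = "blup"
) -> SignedFAEstimates:
    """Per-individual DA-corrected signed FA, raw and BLUP.

    raw_i = mean(right sessions) - mean(left sessions) - delta_hat;
    BLUP_i = w_i * raw_i with w_i = sigma2_fa / (sigma2_fa + sigma2_me *
    (1/K_left + 1/K_right)), the random-slope shrinkage of the mixed model.
    Individuals missing a side get no estimate (not zero).
    """
    if not fit.converged:
        raise ValueError("signed FA requires a converged fit")
    if "trait" in measurements.columns:
        sub = measurements[measurements["trait"] == fit.trait_id]
        if len(sub):
            measurements = sub
    g = _group(measurements)
    s2f, s2m = fit.sigma_fa**2, fit.sigma_me**2
    rows = []
    for xvec, Y, inds in zip(g.patterns, g.Y, g.individuals):
        has_l, has_r = (xvec == -0.5).any(), (xvec == 0.5).any()
        if not (has_l and has_r):
            continue
        kl, kr = int(np.sum(xvec == -0.5)), int(np.sum(xvec == 0.5))
        raw = (
            Y[:, xvec == 0.5].mean(axis=1)
            - Y[:, xvec == -0.5].mean(axis=1)
            - fit.delta_hat
        )
        denom = s2f + s2m * (1.0 / kl + 1.0 / kr)
        w = 0.0 if s2f == 0.0 else (s2f / denom if denom > 0 else 1.0)
        for ind, r in zip(inds, raw):
            rows.append((ind, fit.trait_id, float(r), float(w * r)))
    table = pd.DataFrame(rows, columns=["individual", "trait", "raw", "blup"])
    table = table.sort_values("individual").reset_index(drop=True)
    return SignedFAEstimates(table=table, flag=flag)


def summarize_traits(
    fits: list[FAFit],
    da_tests: list[DATest] | None = None,
    repeatabilities: list[float | None] | None = None,
) -> pd.DataFrame:
    """Per-trait summary: real FA and ME (SD scale), the DA test, right-minus-
    left in trait units and as % of size, and the hypothetical repeatability."""
    if not fits:
        return pd.DataFrame(
            columns=[
                "trait", "real_fa", "me", "da_chi2", "da_p",
                "right_minus_left", "da_percent_of_size", "repeatability",
            ]
        )
    for name, lst in (("da_tests", da_tests), ("repeatabilities", repeatabilities)):
        if lst is not None and len(lst) != len(fits):
            raise ValueError(f"{name} not aligned with fits")
    rows = []
    for i, f in enumerate(fits):
        da = da_tests[i] if da_tests else None
        rows.append(
            {
                "trait": f.trait_id,
                "real_fa": f.sigma_fa,
                "me": f.sigma_me,
                "da_chi2": da.chi2 if da else np.nan,
                "da_p": da.p if da else np.nan,
                "right_minus_left": f.delta_hat,
                "da_percent_of_size": f.da_percent_of_size,
                "repeatability": (
                    repeatabilities[i] if repeatabilities is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def fit_all_traits(
    measurements: pd.DataFrame,
) -> tuple[list[FAFit], list[DATest], list[RealFATest], pd.DataFrame]:
    """Fit every trait in a long measurement table.

    Returns fits, DA tests, real-FA tests and the combined signed-FA table
    (columns individual, trait, raw, blup).
    """
    fits, da_tests, fa_tests, sf_frames = [], [], [], []
    for trait, sub in measurements.groupby("trait", sort=False):
        fit = fit_fa_model(sub, trait_id=str(trait))
        fits.append(fit)
        da_tests.append(test_directional_asymmetry(sub))
        fa_tests.append(test_real_fa(sub))
        sf_frames.append(signed_fa(fit, sub).table)
    signed = pd.concat(sf_frames, ignore_index=True) if sf_frames else pd.DataFrame()
    return fits, da_tests, fa_tests, signed
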