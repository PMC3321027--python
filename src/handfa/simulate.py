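"""Synthetic bilateral-measurement and life-history generator.

Emulates the statistical structure of a two-session, two-sided hand
morphometrics study: per-individual developmental instability (DI)
heterogeneity, trait-level directional asymmetry (DA), among-trait
integration of the signed asymmetries, digitization measurement error (ME),
and a seven-response life-history table with categorical covariates
(education, birth cohort, birth area) and a configurable dependence on the
latent DI.

Model per individual i, trait t:

* ``sigma_it = di_mean_sigma[t] * g_i`` with ``g_i ~ Gamma(mean 1,
  CV di_cv_sigma)`` — a single multiplicative DI factor shared across traits,
  so that individuals differ in how noisy their development is.
* signed asymmetry ``s_i ~ MVN(0, D(sigma_i) @ integration_corr @ D(sigma_i))``.
* side values ``size_it -/+ (da[t] + s_it)/2`` (left minus, right plus), so the
  trait size equals the side mean and DA is orthogonal to size.
* each of K digitization sessions adds independent N(0, me_sd[t]^2) noise.

The latent DI z-score driving life-history effects is the standardized
``log g_i`` (the first principal component of ``log sigma_i``, which is rank-1
under the shared-factor model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarks import TRAIT_ORDER, MeasurementScheme

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "CovariateSpec",
    "simulate_measurements",
    "simulate_life_history",
    "make_landmark_fixture",
    "default_config",
    "RESPONSES",
    "RESPONSE_BASELINES",
]

#: Life-history responses, in report order.
RESPONSES = [
    "bmi",
    "age_first_repro",
    "n_offspring",
    "age_last_repro",
    "age_menarche",
    "prop_sons",
    "offspring_survival",
]

#: (mean, SD) of each response in a post-menopausal European cohort; counts
#: are rounded and floored at zero, proportions clamped to [0, 1].
RESPONSE_BASELINES = {
    "bmi": (26.4, 4.6),
    "age_first_repro": (24.3, 4.8),
    "n_offspring": (1.9, 1.0),
    "age_last_repro": (29.1, 5.1),
    "age_menarche": (13.0, 1.5),
    "prop_sons": (0.54, 0.39),
    "offspring_survival": (0.98, 0.10),
}


@dataclass
class CovariateSpec:
    """One categorical covariate: levels, sampling probabilities and additive
    per-level effects on each response (first level is the reference)."""

    levels: list[str]
    probs: list[float]
    effects: dict[str, list[float]] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if len(self.levels) != len(self.probs):
            raise ValueError(f"{name}: levels/probs length mismatch")
        if not np.isclose(sum(self.probs), 1.0):
            raise ValueError(f"{name}: probabilities must sum to 1")
        for resp, eff in self.effects.items():
            if resp not in RESPONSES:
                raise ValueError(f"{name}: unknown response {resp!r}")
            if len(eff) != len(self.levels):
                raise ValueError(f"{name}: effect vector for {resp!r} has wrong length")


@dataclass
class TruthRecord:
    """Ground truth for one simulated individual (for recovery tests)."""

    individual_id: str
    sigma_i: dict[str, float]
    signed_fa_true: dict[str, float]
    di_zscore: float


@dataclass
class SimulationConfig:
    n_individuals: int
    n_sessions: int
    trait_ids: list[str]
    trait_size_mean: dict[str, float]
    trait_size_sd: dict[str, float]
    da: dict[str, float]
    di_mean_sigma: dict[str, float]
    di_cv_sigma: float
    integration_corr: np.ndarray
    me_sd: dict[str, float]
    lifehistory_effects: dict[str, float] = field(default_factory=dict)
    covariate_levels: dict[str, CovariateSpec] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.di_cv_sigma < 0:
            raise ValueError("di_cv_sigma must be >= 0")
        for name, d in (
            ("trait_size_sd", self.trait_size_sd),
            ("di_mean_sigma", self.di_mean_sigma),
            ("me_sd", self.me_sd),
        ):
            for t in self.trait_ids:
                if d[t] < 0:
                    raise ValueError(f"{name}[{t!r}] must be >= 0")
        C = np.asarray(self.integration_corr, dtype=float)
        T = len(self.trait_ids)
        if C.shape != (T, T):
            raise ValueError(f"integration_corr must be {T}x{T}, got {C.shape}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("integration_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("integration_corr must have unit diagonal")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-8:
            raise ValueError(
                f"integration_corr is not positive semi-definite "
                f"(min eigenvalue {w.min():.3e})"
            )
        for resp in self.lifehistory_effects:
            if resp not in RESPONSES:
                raise ValueError(f"unknown life-history response {resp!r}")
        for name, cov in self.covariate_levels.items():
            cov.validate(name)


# Trait-level defaults on the cm scale of an adult female hand: mean sizes,
# right-minus-left DA, per-individual signed-FA SD (DI level) and digitization
# error SD.
_DEFAULT_SIZE = {
    "P": 8.0, "D2": 7.0, "D3": 7.8, "D4": 7.4, "D5": 6.0,
    "D21": 2.5, "D31": 2.8, "D41": 2.7, "D51": 2.2,
    "D22": 2.0, "D32": 2.2, "D42": 2.1, "D52": 1.7,
    "D23": 2.5, "D33": 2.8, "D43": 2.6, "D53": 2.1,
    "W2": 1.8, "W3": 1.9, "W4": 1.8, "W5": 1.5,
}
_DEFAULT_DA = {
    "P": 0.08, "D2": 0.08, "D3": 0.05, "D4": 0.03, "D5": -0.02,
    "D21": -0.02, "D31": 0.02, "D41": 0.01, "D51": 0.02,
    "D22": 0.03, "D32": 0.01, "D42": 0.00, "D52": -0.04,
    "D23": 0.08, "D33": 0.02, "D43": 0.01, "D53": 0.00,
    "W2": 0.02, "W3": 0.04, "W4": 0.02, "W5": 0.01,
}
_DEFAULT_SIGMA = {
    "P": 0.031, "D2": 0.019, "D3": 0.016, "D4": 0.024, "D5": 0.022,
    "D21": 0.015, "D31": 0.013, "D41": 0.024, "D51": 0.017,
    "D22": 0.011, "D32": 0.009, "D42": 0.015, "D52": 0.011,
    "D23": 0.008, "D33": 0.008, "D43": 0.009, "D53": 0.009,
    "W2": 0.006, "W3": 0.003, "W4": 0.003, "W5": 0.005,
}
_DEFAULT_ME = {
    "P": 0.002, "D2": 0.002, "D3": 0.001, "D4": 0.003, "D5": 0.002,
    "D21": 0.003, "D31": 0.003, "D41": 0.004, "D51": 0.003,
    "D22": 0.002, "D32": 0.003, "D42": 0.003, "D52": 0.003,
    "D23": 0.001, "D33": 0.001, "D43": 0.001, "D53": 0.002,
    "W2": 0.001, "W3": 0.001, "W4": 0.001, "W5": 0.001,
}

# position of each trait on the radio-ulnar axis, for the integration kernel
_TRAIT_POSITION = {t: (1.0 if t == "P" else float(t[1])) for t in TRAIT_ORDER}


def default_integration_corr(
    trait_ids: list[str] | None = None, alpha: float = 0.5, rho: float = 0.55
) -> np.ndarray:
    """Integration correlation from an AR-type kernel on digit position.

    Traits on the same digit correlate at ``alpha``; correlation decays by
    ``rho`` per digit of separation (adjacent digits ~ alpha*rho).  The
    construction ``alpha*K + (1-alpha)*I`` with the AR-1 kernel K is positive
    semi-definite by design.
    """
    trait_ids = trait_ids or list(TRAIT_ORDER)
    pos = np.array([_TRAIT_POSITION.get(t, 0.0) for t in trait_ids])
    K = rho ** np.abs(pos[:, None] - pos[None, :])
    C = alpha * K + (1 - alpha) * np.eye(len(trait_ids))
    np.fill_diagonal(C, 1.0)
    return C


def default_config(
    n_individuals: int = 209,
    n_sessions: int = 2,
    di_cv_sigma: float = 0.25,
    lifehistory_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """Study-like defaults: 209 individuals, 21 hand traits, 2 sessions.

    Trait sizes, DA, DI level and ME are set to values typical of landmark
    distances on scanned adult female hands (cm scale); ``di_cv_sigma`` of
    0.25 puts the hypothetical repeatability of single-trait FA below 0.1,
    i.e. hand FA is a weak readout of DI.  Life-history effects default to
    zero (no FA/life-history association), matching the null study condition.
    """
    trait_ids = list(TRAIT_ORDER)
    covs = {
        "education": CovariateSpec(
            levels=["elementary", "secondary", "university"],
            probs=[0.45, 0.35, 0.20],
            effects={
                "age_first_repro": [0.0, 1.0, 3.0],
                "age_last_repro": [0.0, 0.8, 2.5],
                "n_offspring": [0.0, -0.1, -0.5],
            },
        ),
        "cohort": CovariateSpec(
            levels=["1946-47", "1951-52", "1956-58"],
            probs=[1 / 3, 1 / 3, 1 / 3],
        ),
        "area": CovariateSpec(
            levels=["North", "South", "West", "abroad"],
            probs=[0.30, 0.35, 0.30, 0.05],
        ),
    }
    return SimulationConfig(
        n_individuals=n_individuals,
        n_sessions=n_sessions,
        trait_ids=trait_ids,
        trait_size_mean=dict(_DEFAULT_SIZE),
        trait_size_sd={t: 0.06 * _DEFAULT_SIZE[t] for t in trait_ids},
        da=dict(_DEFAULT_DA),
        di_mean_sigma=dict(_DEFAULT_SIGMA),
        di_cv_sigma=di_cv_sigma,
        integration_corr=default_integration_corr(trait_ids),
        me_sd=dict(_DEFAULT_ME),
        lifehistory_effects=lifehistory_effects or {},
        covariate_levels=covs,
        seed=seed,
    )


def _corr_sqrt(C: np.ndarray) -> np.ndarray:
    """Matrix square root tolerant of PSD-singular correlation matrices."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def simulate_measurements(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Draw a bilateral repeated-measurement table plus its ground truth.

    Returns the long measurement table (individual, side, session, trait,
    value) and one :class:`TruthRecord` per individual.  Identical seeds give
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K = config.n_individuals, config.n_sessions
    traits = config.trait_ids
    T = len(traits)

    mean_sigma = np.array([config.di_mean_sigma[t] for t in traits])
    da = np.array([config.da[t] for t in traits])
    size_mu = np.array([config.trait_size_mean[t] for t in traits])
    size_sd = np.array([config.trait_size_sd[t] for t in traits])
    me = np.array([config.me_sd[t] for t in traits])

    cv = config.di_cv_sigma
    if cv > 0:
        g = rng.gamma(shape=1.0 / cv**2, scale=cv**2, size=n)
    else:
        g = np.ones(n)
    sigma = g[:, None] * mean_sigma[None, :]  # (n, T)

    L = _corr_sqrt(np.asarray(config.integration_corr, dtype=float))
    z = rng.standard_normal((n, T)) @ L.T
    s = sigma * z  # signed FA, (n, T)

    size = size_mu[None, :] + size_sd[None, :] * rng.standard_normal((n, T))
    left = size - (da[None, :] + s) / 2.0
    right = size + (da[None, :] + s) / 2.0

    ids = [f"I{i + 1:04d}" for i in range(n)]
    frames = []
    for side, base in (("L", left), ("R", right)):
        for k in range(1, K + 1):
            noisy = base + me[None, :] * rng.standard_normal((n, T))
            frames.append(
                pd.DataFrame(
                    {
                        "individual": np.repeat(ids, T),
                        "side": side,
                        "session": k,
                        "trait": np.tile(traits, n),
                        "value": noisy.ravel(),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["individual", "side", "session"], kind="stable"
    ).reset_index(drop=True)

    if cv > 0 and np.std(np.log(g)) > 0:
        di_z = (np.log(g) - np.log(g).mean()) / np.log(g).std()
    else:
        di_z = np.zeros(n)
    truth = [
        TruthRecord(
            individual_id=ids[i],
            sigma_i={t: sigma[i, j] for j, t in enumerate(traits)},
            signed_fa_true={t: s[i, j] for j, t in enumerate(traits)},
            di_zscore=float(di_z[i]),
        )
        for i in range(n)
    ]
    return table, truth


def simulate_life_history(
    config: SimulationConfig, truth: list[TruthRecord], seed: int | None = None
) -> pd.DataFrame:
    """Life-history table with covariate effects and a DI dependence.

    Each response is baseline mean + additive covariate effects +
    ``lifehistory_effects[response] * di_zscore`` + Gaussian noise at the
    baseline SD.  Offspring counts are rounded and floored at 0; proportions
    clamped to [0, 1]; women with no offspring have missing reproductive ages,
    offspring sex ratio and survival.
    """
    if not truth:
        raise ValueError("truth records must be non-empty")
    if len(truth) != config.n_individuals:
        raise ValueError(
            f"truth length {len(truth)} != config.n_individuals {config.n_individuals}"
        )
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed))
    n = len(truth)
    di_z = np.array([tr.di_zscore for tr in truth])

    out = pd.DataFrame({"individual": [tr.individual_id for tr in truth]})
    level_idx: dict[str, np.ndarray] = {}
    for name, cov in config.covariate_levels.items():
        idx = rng.choice(len(cov.levels), size=n, p=cov.probs)
        level_idx[name] = idx
        out[name] = [cov.levels[i] for i in idx]

    for resp in RESPONSES:
        mu, sd = RESPONSE_BASELINES[resp]
        y = mu + sd * rng.standard_normal(n)
        for name, cov in config.covariate_levels.items():
            if resp in cov.effects:
                y = y + np.asarray(cov.effects[resp])[level_idx[name]]
        y = y + config.lifehistory_effects.get(resp, 0.0) * di_z
        if resp == "n_offspring":
            y = np.maximum(np.round(y), 0.0)
        elif resp in ("prop_sons", "offspring_survival"):
            y = np.clip(y, 0.0, 1.0)
        out[resp] = y

    childless = out["n_offspring"] == 0
    for col in ("age_first_repro", "age_last_repro", "prop_sons", "offspring_survival"):
        out.loc[childless, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# exact-geometry landmark fixture


def _chain_points(T: float, p1: float, p2: float, p3: float, x0: float):
    """Coordinates of (base, c1, c2, tip) with |tip-base|=T, |base-c1|=p1,
    |c1-c2|=p2, |c2-tip|=p3, solved by two circle intersections."""
    lo = max(abs(p2 - p3), abs(T - p1))
    hi = min(p2 + p3, T + p1)
    if lo > hi + 1e-9:
        raise ValueError(
            f"digit targets geometrically inconsistent: total {T} unreachable "
            f"from phalanges ({p1}, {p2}, {p3})"
        )
    r = min(max((lo + hi) / 2.0, lo), hi)  # |c1 - tip|
    base = np.array([x0, 0.0])
    tip = np.array([x0, T])
    if T == 0:
        raise ValueError("total digit length of 0 with nonzero phalanges is unsupported")
    a = (p1**2 - r**2 + T**2) / (2 * T)
    h = np.sqrt(max(p1**2 - a**2, 0.0))
    c1 = np.array([x0 + h, a])
    d = np.linalg.norm(tip - c1)
    if d == 0:
        c2 = c1 + np.array([p2, 0.0])  # only consistent if p2 == p3 == 0
    else:
        a2 = (p2**2 - p3**2 + d**2) / (2 * d)
        h2 = np.sqrt(max(p2**2 - a2**2, 0.0))
        u = (tip - c1) / d
        perp = np.array([-u[1], u[0]])
        c2 = c1 + a2 * u + h2 * perp
    return base, c1, c2, tip


def make_landmark_fixture(
    scheme: MeasurementScheme, target_distances: dict[str, float]
) -> pd.DataFrame:
    """Landmark coordinates that reproduce the target distances exactly.

    Standalone landmark pairs (palm width, joint widths) are placed on
    dedicated axis-aligned segments.  Each digit's four shared landmarks
    (base, two creases, tip) form a distance-constrained chain solved by
    circle intersection; the construction is exact whenever the digit targets
    are geometrically consistent (total length reachable by the three
    phalanges) and raises otherwise.

    Returns a one-group landmark table (individual="fixture", side="L",
    session=1).
    """
    for tid, tgt in target_distances.items():
        if tgt < 0:
            raise ValueError(f"negative target distance for trait {tid!r}: {tgt}")
    missing = [t for t in scheme.traits if t not in target_distances]
    if missing:
        raise ValueError(f"no target distance for traits: {missing}")

    coords: dict[str, tuple[float, float]] = {}
    digits: dict[int, dict[str, str]] = {}
    standalone: list[str] = []
    for tid, tdef in scheme.traits.items():
        if tdef.digit is not None and tdef.kind in (
            "digit_length",
            "phalange1",
            "phalange2",
            "phalange3",
        ):
            digits.setdefault(tdef.digit, {})[tdef.kind] = tid
        else:
            standalone.append(tid)

    for d, kinds in sorted(digits.items()):
        if set(kinds) != {"digit_length", "phalange1", "phalange2", "phalange3"}:
            # partial digit: treat present traits as standalone pairs
            standalone.extend(kinds.values())
            continue
        T = target_distances[kinds["digit_length"]]
        p1 = target_distances[kinds["phalange1"]]
        p2 = target_distances[kinds["phalange2"]]
        p3 = target_distances[kinds["phalange3"]]
        base, c1, c2, tip = _chain_points(T, p1, p2, p3, x0=30.0 * d)
        tip_lm, base_lm = scheme.pair(kinds["digit_length"])
        _, c1_lm = scheme.pair(kinds["phalange1"])
        _, c2_lm = scheme.pair(kinds["phalange2"])
        coords[base_lm] = tuple(base)
        coords[c1_lm] = tuple(c1)
        coords[c2_lm] = tuple(c2)
        coords[tip_lm] = tuple(tip)

    for row, tid in enumerate(standalone):
        a, b = scheme.pair(tid)
        y = -10.0 * (row + 1)
        coords[a] = (0.0, y)
        coords[b] = (target_distances[tid], y)

    rows = [
        ("fixture", "L", 1, lm, x, y) for lm, (x, y) in sorted(coords.items())
    ]
    return pd.DataFrame(
        rows, columns=["individual", "side", "session", "landmark", "x", "y"]
    )
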