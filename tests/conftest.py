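import numpy as np
import pandas as pd
import pytest

from handfa.simulate import (
    CovariateSpec,
    SimulationConfig,
    default_config,
    simulate_life_history,
    simulate_measurements,
)


def bilateral_frame(
    n=50,
    K=2,
    delta=0.08,
    sigma_fa=0.10,
    sigma_me=0.03,
    sigma_ind=0.5,
    mu=8.0,
    seed=0,
    trait="T",
):
    """Long bilateral measurement table drawn directly from the mixed model.

    Independent of the package generator so it can serve as an oracle input
    for the fitting code.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(mu, sigma_ind, n)
    s = rng.normal(0.0, sigma_fa, n)
    ids = np.array([f"I{i:05d}" for i in range(n)])
    frames = []
    for side, x in (("L", -0.5), ("R", 0.5)):
        for k in range(1, K + 1):
            frames.append(
                pd.DataFrame(
                    {
                        "individual": ids,
                        "side": side,
                        "session": k,
                        "trait": trait,
                        "value": b + (delta + s) * x + rng.normal(0, sigma_me, n),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def small_config(n=209, n_sessions=2, n_traits=5, di_cv_sigma=0.25, seed=0, **kw):
    """A reduced trait panel with the study-scale noise structure."""
    base = default_config(n_individuals=n, n_sessions=n_sessions, seed=seed, **kw)
    traits = base.trait_ids[:n_traits]
    return SimulationConfig(
        n_individuals=n,
        n_sessions=n_sessions,
        trait_ids=traits,
        trait_size_mean={t: base.trait_size_mean[t] for t in traits},
        trait_size_sd={t: base.trait_size_sd[t] for t in traits},
        da={t: base.da[t] for t in traits},
        di_mean_sigma={t: base.di_mean_sigma[t] for t in traits},
        di_cv_sigma=di_cv_sigma,
        integration_corr=np.asarray(base.integration_corr)[:n_traits, :n_traits],
        me_sd={t: base.me_sd[t] for t in traits},
        lifehistory_effects=dict(base.lifehistory_effects),
        covariate_levels=base.covariate_levels,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort():
    """A full study-scale simulated cohort (209 women, 21 traits, 2 sessions)."""
    cfg = default_config(n_individuals=209, n_sessions=2, seed=11)
    measurements, truth = simulate_measurements(cfg)
    life = simulate_life_history(cfg, truth, seed=12)
    return cfg, measurements, truth, life


@pytest.fixture(scope="session")
def cohort_fits(cohort):
    from handfa.fa_model import fit_all_traits

    _, measurements, _, _ = cohort
    return fit_all_traits(measurements)


def make_covariates_null():
    """Covariates with no effects, for calibration studies."""
    return {
        "education": CovariateSpec(
            levels=["elementary", "secondary", "university"], probs=[0.45, 0.35, 0.20]
        ),
        "cohort": CovariateSpec(
            levels=["1946-47", "1951-52", "1956-58"], probs=[1 / 3, 1 / 3, 1 / 3]
        ),
        "area": CovariateSpec(
            levels=["North", "South", "West", "abroad"], probs=[0.3, 0.35, 0.3, 0.05]
        ),
    }
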