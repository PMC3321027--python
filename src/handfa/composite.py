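"""Composite hand-FA indices.

A per-individual hand-asymmetry score is the mean of per-trait standardized
unsigned asymmetries |signed FA| over a trait subset -- either all traits, or
only traits without significant directional asymmetry (and hence less
affected by handedness).  Standardization (z-score per trait over available
individuals) makes traits of different sizes commensurable; unsigned values
are the field convention for FA indices (switchable to signed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fa_model import DATest, SignedFAEstimates

__all__ = ["CompositeFA", "composite_fa", "select_non_da_traits"]


@dataclass
class CompositeFA:
    scores: pd.Series  # individual -> score (NaN when < min_traits available)
    subset: list[str]
    standardization: pd.DataFrame  # per-trait mean, sd of |FA|
    min_traits: int
    excluded: list[str]  # zero-SD traits dropped from the subset


def composite_fa(
    estimates: SignedFAEstimates | pd.DataFrame,
    subset: list[str] | None = None,
    min_traits: int | None = None,
    mode: str | None = None,
    signed: bool = False,
) -> CompositeFA:
    """Average standardized (unsigned) asymmetry over a trait subset.

    Per trait u = |signed FA| (or the signed value when ``signed=True``),
    z = (u - mean(u)) / SD(u); the score is the mean of available z-values,
    reported only for individuals with at least ``min_traits`` non-missing
    traits (default: half the subset, rounded up).  Zero-SD traits are
    excluded with a warning rather than dividing by zero.
    """
    if isinstance(estimates, SignedFAEstimates):
        wide = estimates.values(mode)
    else:
        wide = estimates
    subset = list(subset) if subset is not None else list(wide.columns)
    if not subset:
        raise ValueError("trait subset is empty")
    missing = [t for t in subset if t not in wide.columns]
    if missing:
        raise ValueError(f"subset traits absent from estimates: {missing}")

    u = wide[subset] if signed else wide[subset].abs()
    mean = u.mean(axis=0)
    sd = u.std(axis=0, ddof=1)
    excluded = [t for t in subset if not (sd[t] > 0)]
    if excluded:
        warnings.warn(f"zero-variance traits excluded from composite: {excluded}")
    kept = [t for t in subset if t not in excluded]
    if not kept:
        raise ValueError("no traits with positive |FA| variance in subset")
    if min_traits is None:
        min_traits = math.ceil(len(kept) / 2)

    z = (u[kept] - mean[kept]) / sd[kept]
    available = z.notna().sum(axis=1)
    scores = z.mean(axis=1)
    scores[available < min_traits] = np.nan
    return CompositeFA(
        scores=scores.rename("composite_fa"),
        subset=kept,
        standardization=pd.DataFrame({"mean": mean[kept], "sd": sd[kept]}),
        min_traits=min_traits,
        excluded=excluded,
    )


def select_non_da_traits(
    da_tests: dict[str, DATest], alpha: float = 0.05
) -> list[str]:
    """Traits whose DA test is not significant at ``alpha`` (p >= alpha)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return [t for t, test in da_tests.items() if test.p is not None and test.p >= alpha]
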