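"""Multivariate association of composite hand FA with life-history traits.

Seven life-history responses (BMI, ages of first/last reproduction, number of
offspring, age at menarche, proportion of sons, offspring survival) are
modelled jointly as multivariate normal on a common design: composite FA
(standardized) plus the categorical covariates education, birth cohort and
birth area (dummy-coded, first level as reference).  Responses are
z-standardized so FA coefficients are in SD units.  Predictor blocks are
tested with Pillai's trace and its standard F approximation; for a 1-df block
this reduces to Hotelling's T2 shape F_{q, df_e - q + 1} and all four
classical multivariate statistics coincide.

Analysis is complete-case (listwise over the responses and predictors used);
the number of complete cases is always reported with the tests.  Proportions
are treated as normal responses -- a deliberate modelling simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composite import CompositeFA
from .simulate import RESPONSES

__all__ = [
    "AssociationResult",
    "BlockTest",
    "fit_multivariate_lm",
    "multivariate_block_test",
    "add_bmi_squared",
    "interaction_tests",
    "pillai_trace_F",
]

COVARIATES = ["education", "cohort", "area"]


@dataclass
class BlockTest:
    block: str
    pillai: float
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class AssociationResult:
    per_response: pd.DataFrame  # response, beta, se, t, df, p (FA predictor)
    block_tests: pd.DataFrame
    n_complete: int
    responses: list[str]
    options: dict = field(default_factory=dict)
    # fitted internals, used by multivariate_block_test
    design_columns: list[str] = field(default_factory=list)
    blocks: dict[str, list[str]] = field(default_factory=dict)
    B: np.ndarray | None = None
    E: np.ndarray | None = None
    XtX_inv: np.ndarray | None = None
    df_error: int = 0


def pillai_trace_F(
    H: np.ndarray, E: np.ndarray, b: int, df_e: int
) -> tuple[float, float, int, int, float]:
    """Pillai's trace and its F approximation.

    H and E are the hypothesis and error SSCP matrices (q x q), ``b`` the
    hypothesis df (rank of the contrast), ``df_e`` the error df.  Returns
    (pillai, F, df1, df2, p).
    """
    q = H.shape[0]
    try:
        np.linalg.cholesky(E)
    except np.linalg.LinAlgError:
        raise ValueError(
            "error SSCP is singular: too few complete cases for the number of responses"
        ) from None
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(q, b)
    m = 0.5 * (abs(q - b) - 1)
    nn = 0.5 * (df_e - q - 1)
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * nn + s + 1)))
    if df2 <= 0:
        raise ValueError("nonpositive error df in Pillai F approximation")
    ratio = (V / s) / (1.0 - V / s) if V < s else np.inf
    F = ratio * (2 * nn + s + 1) / (2 * m + s + 1)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return V, float(F), df1, df2, p


def add_bmi_squared(life: pd.DataFrame) -> pd.DataFrame:
    """Append BMI^2 (an eighth response, standardized downstream)."""
    if "bmi" not in life.columns:
        raise ValueError("life-history table has no 'bmi' column")
    out = life.copy()
    out["bmi_squared"] = out["bmi"] ** 2
    return out


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _build_design(
    df: pd.DataFrame, interaction: str | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intercept + standardized FA + covariate dummies (+ FA x factor)."""
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["fa"] = _zscore(df["fa"].to_numpy(dtype=float))
    blocks: dict[str, list[str]] = {"fa": ["fa"]}
    for cov in COVARIATES:
        levels = pd.unique(df[cov])
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level in complete cases")
        dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True, dtype=float)
        for c in dummies.columns:
            X[c] = dummies[c].to_numpy()
        blocks[cov] = list(dummies.columns)
    if interaction is not None:
        if interaction not in COVARIATES:
            raise ValueError(f"interaction factor must be one of {COVARIATES}")
        cols = []
        for c in blocks[interaction]:
            name = f"fa_x_{c}"
            X[name] = X["fa"] * X[c]
            cols.append(name)
        # every factor cell must contain FA variation
        for lev, sub in df.groupby(interaction):
            if len(sub) == 0 or sub["fa"].nunique() < 2:
                raise ValueError(
                    f"empty or degenerate cell for {interaction}={lev!r} crossed with FA"
                )
        blocks[f"fa_x_{interaction}"] = cols
    return X, blocks


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(A, mode="economic", pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"design matrix rank deficient; offending columns: {bad}")


def fit_multivariate_lm(
    life: pd.DataFrame,
    composite: CompositeFA | pd.Series,
    responses: list[str] | None = None,
    bmi_squared: bool = False,
    interaction: str | None = None,
    min_complete: int = 30,
) -> AssociationResult:
    """Multivariate linear model of life-history responses on composite FA.

    Responses and the FA predictor are z-standardized over complete cases, so
    per-response FA coefficients are in SD units.  Returns per-response
    coefficient tests for FA and Pillai block tests for every predictor block
    (FA, each covariate, and the FA x factor interaction when requested).
    """
    scores = composite.scores if isinstance(composite, CompositeFA) else composite
    df = life.copy()
    if bmi_squared:
        df = add_bmi_squared(df)
    responses = list(responses) if responses is not None else list(RESPONSES)
    if bmi_squared and "bmi_squared" not in responses:
        responses = responses + ["bmi_squared"]
    for r in responses:
        if r not in df.columns:
            raise ValueError(f"response {r!r} absent from life-history table")
        if df[r].isna().all():
            raise ValueError(f"response {r!r} is entirely missing")

    df = df.set_index("individual") if "individual" in df.columns else df
    df = df.join(scores.rename("fa"), how="inner")
    keep = responses + ["fa"] + COVARIATES
    cc = df[keep].dropna()
    n = len(cc)
    if n < min_complete:
        raise ValueError(f"only {n} complete cases (< {min_complete})")

    Y = np.column_stack([_zscore(cc[r].to_numpy(dtype=float)) for r in responses])
    X_df, blocks = _build_design(cc, interaction=interaction)
    _check_rank(X_df)
    X = X_df.to_numpy(dtype=float)
    p = X.shape[1]
    q = Y.shape[1]

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    df_e = n - p

    cols = list(X_df.columns)
    fa_idx = cols.index("fa")
    sigma2 = np.diag(E) / df_e
    se = np.sqrt(XtX_inv[fa_idx, fa_idx] * sigma2)
    tvals = B[fa_idx, :] / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_e)
    per_response = pd.DataFrame(
        {
            "response": responses,
            "beta": B[fa_idx, :],
            "se": se,
            "t": tvals,
            "df": df_e,
            "p": pvals,
        }
    )

    result = AssociationResult(
        per_response=per_response,
        block_tests=pd.DataFrame(),
        n_complete=n,
        responses=responses,
        options={"bmi_squared": bmi_squared, "interaction": interaction},
        design_columns=cols,
        blocks=blocks,
        B=B,
        E=E,
        XtX_inv=XtX_inv,
        df_error=df_e,
    )
    tests = [multivariate_block_test(result, name) for name in blocks]
    result.block_tests = pd.DataFrame(
        {
            "block": [t.block for t in tests],
            "pillai": [t.pillai for t in tests],
            "F": [t.F for t in tests],
            "df1": [t.df1 for t in tests],
            "df2": [t.df2 for t in tests],
            "p": [t.p for t in tests],
        }
    )
    return result


def multivariate_block_test(
    result: AssociationResult, block: str | list[str]
) -> BlockTest:
    """Pillai's trace test that a block of design columns is jointly zero
    across all responses."""
    if isinstance(block, str):
        name = block
        cols = result.blocks.get(block, [block] if block in result.design_columns else [])
    else:
        name = "+".join(block)
        cols = list(block)
    if not cols:
        raise ValueError(f"block {block!r} selects no design columns")
    idx = [result.design_columns.index(c) for c in cols]
    Lb = result.B[idx, :]  # (b, q)
    G = result.XtX_inv[np.ix_(idx, idx)]
    H = Lb.T @ np.linalg.solve(G, Lb)
    pillai, F, df1, df2, p = pillai_trace_F(H, result.E, len(idx), result.df_error)
    return BlockTest(block=name, pillai=pillai, F=F, df1=df1, df2=df2, p=p)


def interaction_tests(
    life: pd.DataFrame,
    composite: CompositeFA | pd.Series,
    factor: str,
    **kwargs,
) -> BlockTest:
    """Does the FA/life-history association differ across ``factor`` levels?

    Adds FA x factor columns to the model and returns the multivariate Pillai
    test of the interaction block.
    """
    if factor not in ("cohort", "education"):
        raise ValueError("interaction factor must be 'cohort' or 'education'")
    result = fit_multivariate_lm(life, composite, interaction=factor, **kwargs)
    return multivariate_block_test(result, f"fa_x_{factor}")
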