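"""Developmental integration: between-trait correlations of signed FA.

Traits sharing a developmental pathway also share developmental errors, so
their signed asymmetries correlate.  Pairwise-complete Pearson correlations
with t-distribution p-values (df = n_pair - 2); pairs observed in fewer than
three individuals, or involving a zero-variance trait, are flagged undefined
rather than propagated as NaN silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fa_model import SignedFAEstimates

__all__ = ["CorrMatrix", "signed_fa_correlations"]

MIN_PAIR_N = 3


@dataclass
class CorrMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined: list[tuple[str, str, str]]  # (trait_a, trait_b, reason)

    def lower_triangle(self, digits: int = 2) -> pd.DataFrame:
        """Lower-triangular view (report shape)."""
        out = self.r.round(digits).astype(object)
        mask = np.triu(np.ones(out.shape, dtype=bool))
        out.values[mask] = ""
        return out.iloc[1:, :-1]


def signed_fa_correlations(
    estimates: SignedFAEstimates | pd.DataFrame, mode: str | None = None
) -> CorrMatrix:
    """Pairwise-complete Pearson correlation of per-individual signed FA.

    ``estimates`` is either :class:`SignedFAEstimates` (``mode`` picks blup or
    raw values) or an individual-by-trait wide frame.
    """
    if isinstance(estimates, SignedFAEstimates):
        wide = estimates.values(mode)
    else:
        wide = estimates
    traits = list(wide.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    undefined = []
    X = wide.to_numpy(dtype=float)
    np.fill_diagonal(n, np.isfinite(X).sum(axis=0))
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            m = int(ok.sum())
            n[i, j] = n[j, i] = m
            if m < MIN_PAIR_N:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                undefined.append((traits[i], traits[j], f"only {m} complete pairs"))
                continue
            xi, xj = X[ok, i], X[ok, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                undefined.append((traits[i], traits[j], "zero-variance trait"))
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((m - 2) / (1.0 - rij**2))
                pij = float(2.0 * stats.t.sf(abs(t), m - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return CorrMatrix(
        r=pd.DataFrame(r, index=traits, columns=traits),
        p=pd.DataFrame(p, index=traits, columns=traits),
        n=pd.DataFrame(n, index=traits, columns=traits),
        undefined=undefined,
    )
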