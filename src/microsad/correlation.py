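"""Pearson correlation structure among diversity measures.

Correlations come with two-sided p-values from the exact t transform
``t = r sqrt(n - 2) / sqrt(1 - r^2)`` with ``n - 2`` degrees of freedom.
Zero-variance inputs are an error, never a silent ``r = 0``. No
multiple-testing correction is applied; the long-format table carries all
raw p-values so users can adjust as they see fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "pearson_with_p", "metric_matrix"]

#: Diversity measures entering the all-pairs correlation table.
METRIC_VARS = ["S_obs", "chao1", "H", "J", "dominance"]


@dataclass(frozen=True)
class CorrelationResult:
    var1: str
    var2: str
    n: int
    r: float
    p_value: float


def pearson_with_p(x, y, names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(var1=names[0], var2=names[1], n=n, r=r, p_value=p)


def metric_matrix(profiles: pd.DataFrame, dominance: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """All-pairs Pearson correlations among diversity measures.

    Parameters
    ----------
    profiles
        Per-sample diversity profile with columns S_obs, chao1, H, J.
    dominance
        Per-sample top-rank dominance (the ``dominance`` column of the
        SAD summary), aligned on sample id.

    Returns
    -------
    Long-format frame (var1, var2, n, r, p) over all unordered pairs of
    {S_obs, chao1, H, J, dominance}.
    """
    dom = dominance["dominance"] if isinstance(dominance, pd.DataFrame) else dominance
    data = profiles.join(dom.rename("dominance"))
    if len(data) < 3:
        raise ValueError("need at least 3 communities")
    rows = []
    for a, b in combinations(METRIC_VARS, 2):
        res = pearson_with_p(data[a], data[b], names=(a, b))
        rows.append({"var1": a, "var2": b, "n": res.n, "r": res.r, "p": res.p_value})
    return pd.DataFrame(rows)


def correlation_square(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format table into a symmetric r matrix with unit diagonal."""
    mat = pd.DataFrame(1.0, index=METRIC_VARS, columns=METRIC_VARS)
    for _, row in long.iterrows():
        mat.loc[row["var1"], row["var2"]] = row["r"]
        mat.loc[row["var2"], row["var1"]] = row["r"]
    return mat
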