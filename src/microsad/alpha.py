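"""Per-community (alpha) diversity: richness, Shannon indices, PIE, rarefaction.

All metrics operate on an :class:`AbundanceVector`, one community's
integer species counts ``n_i`` with total ``N = sum(n_i)``. Shannon
diversity uses the natural log throughout, so Pielou's evenness is
``J = H / ln(S_obs)``. The probability of interspecific encounter (PIE)
uses the unbiased without-replacement form, which makes it exactly the
initial slope of the analytic rarefaction curve: ``E[S(2)] - E[S(1)] = PIE``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .table import OTUTable

__all__ = [
    "AbundanceVector",
    "RarefactionCurve",
    "shannon",
    "evenness",
    "chao1",
    "pie",
    "rarefaction",
    "profile_table",
    "PROFILE_COLUMNS",
]

PROFILE_COLUMNS = ["N", "S_obs", "chao1", "H", "J", "PIE"]


class AbundanceVector:
    """One community's species counts with derived quantities.

    Attributes
    ----------
    counts : ndarray of positive int
        Abundances ``n_i`` of the observed species (zeros dropped).
    species_ids : list of str or None
        Optional identifiers aligned with ``counts``.
    """

    def __init__(self, counts: Iterable[int], species_ids: Sequence[str] | None = None):
        arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("abundances must be integers")
        arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("abundances must be non-negative")
        if species_ids is not None:
            species_ids = [str(s) for s in species_ids]
            if len(species_ids) != arr.size:
                raise ValueError("species_ids length does not match counts")
            keep = np.flatnonzero(arr)
            species_ids = [species_ids[i] for i in keep]
            arr = arr[keep]
        else:
            arr = arr[arr > 0]
        if arr.size == 0:
            raise ValueError("community has no observed species (N = 0)")
        self.counts = arr
        self.species_ids = species_ids

    @property
    def N(self) -> int:
        """Total abundance (number of sequences)."""
        return int(self.counts.sum())

    @property
    def S_obs(self) -> int:
        """Observed species richness."""
        return int(self.counts.size)

    @property
    def p(self) -> np.ndarray:
        """Relative abundances ``p_i = n_i / N``."""
        return self.counts / self.N

    @property
    def F1(self) -> int:
        """Singleton count (species seen exactly once)."""
        return int(np.count_nonzero(self.counts == 1))

    @property
    def F2(self) -> int:
        """Doubleton count (species seen exactly twice)."""
        return int(np.count_nonzero(self.counts == 2))

    def __repr__(self) -> str:
        return f"<AbundanceVector N={self.N} S_obs={self.S_obs}>"


def _as_vector(v) -> AbundanceVector:
    return v if isinstance(v, AbundanceVector) else AbundanceVector(v)


def shannon(v) -> float:
    """Shannon diversity ``H = -sum p_i ln p_i`` in nats."""
    v = _as_vector(v)
    p = v.p
    return float(-np.sum(p * np.log(p)))


def evenness(v) -> float:
    """Pielou's evenness ``J = H / ln(S_obs)``; undefined for S_obs = 1."""
    v = _as_vector(v)
    if v.S_obs < 2:
        raise ValueError("evenness is undefined for a single-species community")
    return shannon(v) / math.log(v.S_obs)


def chao1(v, variant: str = "bias_corrected") -> float:
    """Chao1 nonparametric richness estimate from singletons and doubletons.

    ``classic``: ``S_obs + F1^2 / (2 F2)`` (falls back to
    ``S_obs + F1 (F1 - 1) / 2`` when there are no doubletons).
    ``bias_corrected`` (default): ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``.
    """
    v = _as_vector(v)
    S, F1, F2 = v.S_obs, v.F1, v.F2
    if variant == "classic":
        if F2 > 0:
            return S + F1 * F1 / (2.0 * F2)
        return S + F1 * (F1 - 1) / 2.0
    if variant == "bias_corrected":
        return S + F1 * (F1 - 1) / (2.0 * (F2 + 1))
    raise ValueError(f"unknown Chao1 variant {variant!r}")


def pie(v) -> float:
    """Probability of interspecific encounter (two sequences differ in species).

    Unbiased without-replacement form ``1 - sum n_i (n_i - 1) / (N (N - 1))``;
    equals the initial slope of the rarefaction curve.
    """
    v = _as_vector(v)
    N = v.N
    if N < 2:
        raise ValueError("PIE needs at least two sequences")
    same = np.sum(v.counts * (v.counts - 1.0))
    return float(1.0 - same / (N * (N - 1.0)))


@dataclass
class RarefactionCurve:
    """Expected species richness at a grid of subsampling depths."""

    metric: str  # observed_richness or chao1
    mode: str  # analytic or monte_carlo
    depths: np.ndarray
    means: np.ndarray
    sds: np.ndarray | None = None  # monte_carlo only
    reps: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"depth": self.depths, "mean": self.means}
        if self.sds is not None:
            data["sd"] = self.sds
        return pd.DataFrame(data)


def _analytic_expected_richness(counts: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """``E[S(d)] = sum_i [1 - C(N - n_i, d) / C(N, d)]``.

    The binomial ratio is the probability species ``i`` is absent from a
    depth-``d`` subsample; it obeys ``r_i(d+1) = r_i(d) (m_i - d)/(N - d)``
    with ``m_i = N - n_i`` and ``r_i(0) = 1``, which is evaluated by a
    single sweep over depths (numerically exact at the boundaries:
    ``E[S(N)] = S_obs`` and ``E[S(1)] = 1``).
    """
    N = int(counts.sum())
    m = (N - counts).astype(float)
    absent = np.ones(counts.size)  # r_i(0)
    wanted = {int(d): k for k, d in enumerate(depths)}
    out = np.empty(depths.size)
    for d in range(1, int(depths.max()) + 1):
        absent *= np.maximum(m - (d - 1), 0.0) / (N - (d - 1))
        if d in wanted:
            out[wanted[d]] = counts.size - absent.sum()
    return out


def default_depth_grid(N: int, n_points: int = 10) -> np.ndarray:
    """Ten (by default) evenly spaced integer depths from min(10, N) to N."""
    lo = min(10, N)
    return np.unique(np.linspace(lo, N, num=n_points).round().astype(int))


def rarefaction(
    v,
    depths: Sequence[int] | None = None,
    mode: str = "analytic",
    metric: str = "observed_richness",
    reps: int = 100,
    seed: int | None = None,
) -> RarefactionCurve:
    """Rarefy a community to the given depths (subsampling without replacement).

    Analytic mode evaluates the closed-form expectation of observed
    richness; Monte-Carlo mode subsamples ``reps`` times at each depth and
    supports the Chao1 metric as well.
    """
    v = _as_vector(v)
    if depths is None:
        depths_arr = default_depth_grid(v.N)
    else:
        depths_arr = np.asarray(list(depths), dtype=np.int64)
    if np.any(depths_arr < 1) or np.any(depths_arr > v.N):
        raise ValueError(f"depths must lie in [1, N={v.N}]")
    if metric not in ("observed_richness", "chao1"):
        raise ValueError(f"unknown rarefaction metric {metric!r}")

    if mode == "analytic":
        if metric != "observed_richness":
            raise ValueError("analytic rarefaction supports observed_richness only")
        means = _analytic_expected_richness(v.counts, depths_arr)
        return RarefactionCurve("observed_richness", "analytic", depths_arr, means)

    if mode != "monte_carlo":
        raise ValueError(f"unknown rarefaction mode {mode!r}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(v.S_obs), v.counts)
    means = np.empty(depths_arr.size)
    sds = np.empty(depths_arr.size)
    for k, d in enumerate(depths_arr):
        vals = np.empty(reps)
        for r in range(reps):
            draw = rng.choice(pool, size=d, replace=False)
            sub = np.bincount(draw, minlength=v.S_obs)
            sub_v = AbundanceVector(sub)
            vals[r] = sub_v.S_obs if metric == "observed_richness" else chao1(sub_v)
        means[k] = vals.mean()
        sds[k] = vals.std(ddof=1) if reps > 1 else 0.0
    return RarefactionCurve(metric, "monte_carlo", depths_arr, means, sds, reps, seed)


def profile_table(table: OTUTable, chao1_variant: str = "bias_corrected") -> pd.DataFrame:
    """Per-sample diversity profile: N, S_obs, Chao1, H, J, PIE.

    Single-species samples get a missing evenness (with a warning) rather
    than a silent zero. The ``dominance`` column of the full community
    summary is appended by the rank-abundance stage.
    """
    rows = []
    for sample in table.sample_ids:
        v = AbundanceVector(table.sample_counts(sample))
        if v.S_obs >= 2:
            J = evenness(v)
        else:
            warnings.warn(f"sample {sample!r} has a single species; evenness undefined")
            J = np.nan
        rows.append(
            {
                "N": v.N,
                "S_obs": v.S_obs,
                "chao1": chao1(v, chao1_variant),
                "H": shannon(v),
                "J": J,
                "PIE": pie(v) if v.N >= 2 else np.nan,
            }
        )
    df = pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample"))
    return df[PROFILE_COLUMNS]


def write_profile(df: pd.DataFrame, path, orientation: str = "tidy") -> None:
    """Write the profile: ``tidy`` (one row per sample) or ``metrics_as_rows``
    (metrics × samples, the layout of a printed community-characteristics table)."""
    out = df if orientation == "tidy" else df.T
    out.to_csv(path, sep="\t")
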