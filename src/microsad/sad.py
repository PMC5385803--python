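"""Species abundance distributions: ranked curves, power-law fits, dominance.

A community's SAD is displayed as a rank-abundance curve (species ordered
from most to least abundant). Its shape is quantified by an ordinary
least-squares fit of ``ln n_(r)`` on ``ln r`` over all ranks; the
power-law exponent is ``s = -slope``. Communities whose top-ranked
species sit far above the fitted line (standardized residual beyond a
z threshold) are flagged as dominance-regime communities, and the
top-rank dominance statistic — the percentage of all sequences
contributed by the single most abundant species — summarizes that
regime directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alpha import AbundanceVector
from .table import OTUTable, TaxonomyMap, UNCLASSIFIED

__all__ = [
    "RankAbundance",
    "PowerLawFit",
    "rank_abundance",
    "fit_power_law",
    "top_rank_dominance",
    "dominance_summary",
    "phylum_summary",
]


@dataclass
class RankAbundance:
    """Phylum-annotated species list in decreasing order of abundance.

    Ranks run 1..S_obs with no gaps; ties in abundance are broken by OTU
    id (ascending), so the ranking is deterministic.
    """

    records: pd.DataFrame  # columns: rank, otu_id, abundance, phylum, ln_rank, ln_abundance

    @property
    def S_obs(self) -> int:
        return len(self.records)

    @property
    def N(self) -> int:
        return int(self.records["abundance"].sum())


def rank_abundance(v, tax: TaxonomyMap | None = None) -> RankAbundance:
    """Rank a community's species by abundance, annotating each with its phylum."""
    if not isinstance(v, AbundanceVector):
        v = AbundanceVector(v)
    ids = v.species_ids if v.species_ids is not None else [f"sp{i}" for i in range(v.S_obs)]
    order = sorted(range(v.S_obs), key=lambda i: (-v.counts[i], ids[i]))
    tax = tax or TaxonomyMap()
    records = pd.DataFrame(
        {
            "rank": np.arange(1, v.S_obs + 1),
            "otu_id": [ids[i] for i in order],
            "abundance": v.counts[order],
            "phylum": [tax.phylum(ids[i]) for i in order],
        }
    )
    records["ln_rank"] = np.log(records["rank"])
    records["ln_abundance"] = np.log(records["abundance"].astype(float))
    return RankAbundance(records)


@dataclass
class PowerLawFit:
    """OLS fit of ln abundance against ln rank, with deviant flagging.

    Attributes
    ----------
    slope, intercept : float
        Fitted line in log-log space (slope expected <= 0).
    exponent : float
        Power-law decay exponent ``s = -slope``.
    r_squared : float
        Coefficient of determination (1 for degenerate all-equal data).
    std_residuals : ndarray
        Residual / residual standard deviation (S - 2 df), per rank.
    upward_deviants : list of int
        Ranks whose standardized residual exceeds ``z_threshold``.
    """

    slope: float
    intercept: float
    exponent: float
    r_squared: float
    std_residuals: np.ndarray
    upward_deviants: list[int]
    z_threshold: float
    n_ranks: int
    ranked: RankAbundance = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Rank-abundance power-law fit (OLS, ln abundance ~ ln rank)",
            f"  ranks fitted        : {self.n_ranks}",
            f"  slope               : {self.slope: .4f}",
            f"  exponent s          : {self.exponent: .4f}",
            f"  intercept           : {self.intercept: .4f}",
            f"  R^2                 : {self.r_squared: .4f}",
            f"  upward deviants (z>{self.z_threshold:g}): "
            + (", ".join(map(str, self.upward_deviants)) if self.upward_deviants else "none"),
        ]
        return "\n".join(lines)


def fit_power_law(ra: RankAbundance | AbundanceVector, z_threshold: float = 2.0) -> PowerLawFit:
    """Fit ``ln n_(r) = intercept + slope * ln r`` over all ranks by OLS.

    Standardized residuals use the residual standard deviation with
    ``S - 2`` degrees of freedom; ranks with standardized residual above
    ``z_threshold`` are reported as upward deviants (higher-than-expected
    abundance). All-equal abundances are a perfect flat-line fit
    (slope 0, ``R^2 = 1``) rather than a 0/0.
    """
    if not isinstance(ra, RankAbundance):
        ra = rank_abundance(ra)
    if ra.S_obs < 3:
        raise ValueError("power-law fit needs at least 3 ranks")
    x = ra.records["ln_rank"].to_numpy()
    y = ra.records["ln_abundance"].to_numpy()
    n = x.size
    # OLS closed form; x always has spread (ranks 1..S distinct)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((y - ym) ** 2))
    if sst == 0.0:  # flat data: perfect fit by convention
        r2 = 1.0
    else:
        r2 = 1.0 - ssr / sst
    sigma = np.sqrt(ssr / (n - 2)) if n > 2 else 0.0
    scale = max(1.0, float(np.abs(y).max()))
    if sigma > 1e-12 * scale:
        std_resid = resid / sigma
    else:  # numerically perfect fit: residuals are rounding noise
        std_resid = np.zeros_like(resid)
        r2 = 1.0
    deviants = [int(r) for r in ra.records["rank"][std_resid > z_threshold]]
    return PowerLawFit(
        slope=float(slope),
        intercept=float(intercept),
        exponent=float(-slope),
        r_squared=float(r2),
        std_residuals=std_resid,
        upward_deviants=deviants,
        z_threshold=z_threshold,
        n_ranks=n,
        ranked=ra,
    )


def top_rank_dominance(v) -> float:
    """Abundance share (%) of the single most abundant species."""
    if not isinstance(v, AbundanceVector):
        v = AbundanceVector(v)
    return float(100.0 * v.counts.max() / v.N)


def dominance_summary(table: OTUTable) -> pd.DataFrame:
    """Per sample: most abundant OTU and its top-rank dominance (%)."""
    rows = []
    for sample in table.sample_ids:
        v = AbundanceVector(table.sample_counts(sample), species_ids=table.otu_ids)
        ra = rank_abundance(v)
        rows.append(
            {
                "top_otu_id": ra.records.iloc[0]["otu_id"],
                "dominance": top_rank_dominance(v),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample"))


def phylum_summary(table: OTUTable, tax: TaxonomyMap) -> pd.DataFrame:
    """Per (sample, phylum): species richness S_p and mean abundance N_p / S_p.

    Phyla absent from a sample are omitted. Before any rounding,
    ``sum_p S_p == S_obs`` and ``sum_p S_p * mean_p == N`` for every sample.
    """
    rows = []
    for sample in table.sample_ids:
        abund = table.sample_abundances(sample)
        per_phylum: dict[str, list[int]] = {}
        for otu_id, n in abund.items():
            per_phylum.setdefault(tax.phylum(otu_id), []).append(n)
        for phylum, counts in sorted(per_phylum.items()):
            rows.append(
                {
                    "sample": sample,
                    "phylum": phylum,
                    "richness": len(counts),
                    "mean_abundance": float(np.mean(counts)),
                    "total_abundance": int(np.sum(counts)),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "phylum", "richness", "mean_abundance", "total_abundance"])


def sad_table(table: OTUTable, tax: TaxonomyMap | None = None, z_threshold: float = 2.0):
    """Rank every sample and fit its power law.

    Returns ``(ranked, fits)`` where ``ranked`` maps sample id to
    :class:`RankAbundance` and ``fits`` is a per-sample summary frame
    (slope, exponent s, intercept, R^2, number of upward deviants,
    dominance).
    """
    ranked: dict[str, RankAbundance] = {}
    rows = []
    for sample in table.sample_ids:
        v = AbundanceVector(table.sample_counts(sample), species_ids=table.otu_ids)
        ra = rank_abundance(v, tax)
        ranked[sample] = ra
        row = {"dominance": top_rank_dominance(v)}
        if ra.S_obs >= 3:
            fit = fit_power_law(ra, z_threshold)
            row.update(
                slope=fit.slope,
                s=fit.exponent,
                intercept=fit.intercept,
                r_squared=fit.r_squared,
                n_deviants=len(fit.upward_deviants),
            )
        else:
            row.update(slope=np.nan, s=np.nan, intercept=np.nan, r_squared=np.nan, n_deviants=0)
        rows.append(row)
    fits = pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample"))
    return ranked, fits[["slope", "s", "intercept", "r_squared", "n_deviants", "dominance"]]
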