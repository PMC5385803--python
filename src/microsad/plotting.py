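"""Rank-abundance plots colored by phylum.

Two views per community: rank-log (ln abundance vs rank) and log-log
(ln abundance vs ln rank with the fitted power-law line). Points are
colored by phylum with the conventional grouping Firmicutes /
Proteobacteria / Actinobacteria / other.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sad import PowerLawFit, RankAbundance, fit_power_law

__all__ = ["plot_rank_abundance", "PHYLUM_COLORS"]

PHYLUM_COLORS = {
    "Firmicutes": "#1f77b4",
    "Proteobacteria": "#d62728",
    "Actinobacteria": "#2ca02c",
}
_OTHER_COLOR = "#7f7f7f"


def _colors(phyla):
    return [PHYLUM_COLORS.get(p, _OTHER_COLOR) for p in phyla]


def plot_rank_abundance(
    ra: RankAbundance,
    fit: PowerLawFit | None = None,
    title: str = "",
    path=None,
):
    """Side-by-side rank-log and log-log SAD plots; returns the figure.

    When ``fit`` is omitted it is computed on the fly (for >= 3 ranks).
    """
    if fit is None and ra.S_obs >= 3:
        fit = fit_power_law(ra)
    rec = ra.records
    colors = _colors(rec["phylum"])
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(rec["rank"], rec["ln_abundance"], c=colors, s=14)
    ax1.set_xlabel("rank")
    ax1.set_ylabel("ln abundance")
    ax2.scatter(rec["ln_rank"], rec["ln_abundance"], c=colors, s=14)
    if fit is not None:
        ax2.plot(
            rec["ln_rank"],
            fit.intercept + fit.slope * rec["ln_rank"],
            color="red",
            lw=1,
            label=f"s = {fit.exponent:.2f}, R² = {fit.r_squared:.2f}",
        )
        ax2.legend(frameon=False, fontsize=8)
    ax2.set_xlabel("ln rank")
    ax2.set_ylabel("ln abundance")
    if title:
        fig.suptitle(title)
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=c, label=p)
        for p, c in {**PHYLUM_COLORS, "other": _OTHER_COLOR}.items()
    ]
    ax1.legend(handles=handles, frameon=False, fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
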