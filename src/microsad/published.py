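"""Printed summary tables of a two-host, six-gut-site clone-library survey.

These are the published per-community summary rows of a 16S rRNA
clone-library study of the gut microbiota of two wild flying squirrels
(hosts FS1 and FS2), sampled at the food bolus (F) and mucus layer (M)
of the proximal small intestine (S), cecum (C) and distal large
intestine (L). They serve as worked-example input data: the per-OTU
tables behind them are not shipped, but the printed rows alone support
several internal-consistency computations (the evenness convention
J = H / ln(S_obs), per-phylum richness sums, abundance reconstruction,
and the evenness–diversity correlation).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SAMPLES",
    "community_characteristics",
    "phylum_breakdown",
    "recomputed_evenness",
    "phylum_richness_totals",
    "reconstructed_abundance",
    "total_sequences",
]

#: Community labels, host then gut site.
SAMPLES = (
    "FS1SF", "FS1CF", "FS1LF", "FS1SM", "FS1CM", "FS1LM",
    "FS2SF", "FS2CF", "FS2LF", "FS2SM", "FS2CM", "FS2LM",
)

# Per-community characteristics as printed: total abundance (sequences),
# observed richness (OTUs at 97% identity), Chao1 estimated richness,
# Shannon diversity (nats), Shannon (Pielou) evenness.
_CHARACTERISTICS = {
    "N":     [397, 528, 389, 348, 382, 425, 365, 443, 435, 284, 368, 404],
    "S_obs": [88, 184, 149, 157, 115, 65, 98, 172, 140, 137, 128, 64],
    "chao1": [198, 290, 244, 282, 214, 135, 228, 321, 226, 334, 256, 130],
    "H":     [2.39, 4.52, 4.37, 4.74, 3.98, 2.48, 2.92, 4.76, 4.31, 4.57, 4.33, 2.31],
    "J":     [0.53, 0.87, 0.87, 0.94, 0.84, 0.59, 0.64, 0.92, 0.87, 0.93, 0.89, 0.56],
}

# Per-(phylum, community) species richness and (parenthesized in print)
# mean species abundance, i.e. average sequences per OTU. None = absent.
_PHYLA = {
    "Firmicutes": [
        (81, 2), (173, 3), (138, 3), (145, 2), (108, 3), (39, 3),
        (85, 2), (155, 3), (126, 2), (125, 2), (118, 3), (54, 1),
    ],
    "Proteobacteria": [
        (3, 77), (2, 2), (3, 2), (3, 1), None, (10, 4),
        (9, 18), (4, 2), (4, 13), (7, 3), (4, 1), (2, 68),
    ],
    "Actinobacteria": [
        (4, 1), (8, 2), (7, 2), (7, 2), (5, 5), (13, 21),
        (1, 1), (9, 3), (7, 7), (2, 2), (5, 2), (7, 27),
    ],
    "Deinococcus-Thermus": [
        None, None, None, (1, 1), None, (1, 3),
        (1, 2), None, None, (1, 1), None, None,
    ],
    "Verrucomicrobia": [
        None, None, (1, 2), (1, 1), (1, 7), (1, 9),
        (1, 2), (1, 14), (1, 31), (1, 2), (1, 11), (1, 2),
    ],
    "Unclassified": [
        None, (1, 1), None, None, (1, 1), (1, 1),
        (1, 1), (3, 1), (2, 2), (1, 3), None, None,
    ],
}


def community_characteristics() -> pd.DataFrame:
    """Per-community N, S_obs, Chao1, H, J (one row per community)."""
    return pd.DataFrame(_CHARACTERISTICS, index=pd.Index(SAMPLES, name="sample"))


def phylum_breakdown() -> pd.DataFrame:
    """Long-format per-(sample, phylum) richness and mean abundance.

    Mean abundances are the printed integer-rounded values; absent
    (sample, phylum) combinations are omitted, as in print.
    """
    rows = []
    for phylum, cells in _PHYLA.items():
        for sample, cell in zip(SAMPLES, cells):
            if cell is None:
                continue
            richness, mean = cell
            rows.append(
                {
                    "sample": sample,
                    "phylum": phylum,
                    "richness": richness,
                    "mean_abundance": mean,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "phylum", "richness", "mean_abundance"])


# -- internal-consistency computations over the printed rows ----------------------


def recomputed_evenness() -> pd.Series:
    """Pielou evenness ``H / ln(S_obs)`` recomputed from the printed H and
    observed richness; matches the printed evenness after 2-decimal rounding."""
    import numpy as np

    df = community_characteristics()
    return pd.Series(df["H"] / np.log(df["S_obs"]), index=df.index, name="J_recomputed")


def phylum_richness_totals() -> pd.Series:
    """Per community: sum of per-phylum species richness (equals S_obs)."""
    return phylum_breakdown().groupby("sample")["richness"].sum().reindex(list(SAMPLES))


def reconstructed_abundance() -> pd.Series:
    """Per community: ``sum_p S_p * mean_p``, the total sequence count
    rebuilt from the per-phylum breakdown (printed means are rounded, so
    this reconstruction is exact only where rounding cancels)."""
    df = phylum_breakdown()
    contrib = df["richness"] * df["mean_abundance"]
    return contrib.groupby(df["sample"]).sum().reindex(list(SAMPLES))


def total_sequences() -> int:
    """Survey-wide sequence total: sum of the 12 printed total abundances."""
    return int(community_characteristics()["N"].sum())
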