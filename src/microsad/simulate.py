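"""Synthetic gut-community generator.

Emulates the design of a two-host, six-gut-site 16S clone-library survey
(food bolus F and mucus layer M of the small intestine S, cecum C, and
large intestine L): one community per (host, site), a few hundred
sequences per community, tens to ~180 observed OTUs, five phyla with
many rare Firmicutes species versus a few dominant Proteobacteria /
Actinobacteria species, site-dependent top-rank dominance regimes
(high-dominance SF and LM versus even communities elsewhere), and
partial cross-host species sharing.

Everything is driven by explicit seeds and is bit-reproducible from
(spec, seed). The generator is a statistical stand-in for clone
libraries: it draws relative abundances from a parametric species
abundance distribution per community, then draws reads multinomially.
No sequence-level features are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alpha import AbundanceVector
from .table import OTUTable, TaxonomyMap, UNCLASSIFIED
from .tree import PhyloTree

__all__ = [
    "CommunitySpec",
    "GutDesignSpec",
    "GutDataset",
    "SITE_DEFAULTS",
    "relative_abundances",
    "sample_community",
    "generate_gut_dataset",
    "random_tree",
    "retention_probability",
]

SAD_FAMILIES = ("zipf", "logseries", "lognormal", "broken_stick", "geometric")


@dataclass(frozen=True)
class CommunitySpec:
    """Parametric recipe for one community.

    ``sad_family`` is one of zipf (pi_i ∝ i^-s), logseries
    (pi_i ∝ theta^i / i), lognormal (iid LN(mu, sigma), sorted),
    broken_stick (expected ordered fractions), geometric
    (pi_i ∝ k (1-k)^(i-1)); ``N`` is the number of reads, either a fixed
    integer or an inclusive (lo, hi) range sampled uniformly.
    """

    S_pool: int
    sad_family: str = "lognormal"
    params: dict = field(default_factory=dict)
    N: int | tuple[int, int] = 400
    seed: int | None = None

    def __post_init__(self):
        if self.sad_family not in SAD_FAMILIES:
            raise ValueError(f"unknown SAD family {self.sad_family!r}")
        if self.S_pool < 1:
            raise ValueError("S_pool must be >= 1")
        lo = self.N if isinstance(self.N, int) else self.N[0]
        if lo < 1:
            raise ValueError("N must be >= 1")
        p = self.params
        if self.sad_family == "zipf" and not p.get("s", 1.0) > 0:
            raise ValueError("zipf exponent s must be > 0")
        if self.sad_family == "logseries" and not 0 < p.get("theta", 0.5) < 1:
            raise ValueError("logseries theta must be in (0, 1)")
        if self.sad_family == "lognormal" and not p.get("sigma", 1.0) > 0:
            raise ValueError("lognormal sigma must be > 0")
        if self.sad_family == "geometric" and not 0 < p.get("k", 0.5) < 1:
            raise ValueError("geometric k must be in (0, 1)")


def relative_abundances(
    family: str, S: int, rng: np.random.Generator | None = None, **params
) -> np.ndarray:
    """Relative-abundance profile pi_1 >= pi_2 >= ... over ``S`` species.

    Deterministic for all families except lognormal, whose iid draws need
    ``rng`` (they are sorted descending so rank order is well defined).
    """
    i = np.arange(1, S + 1, dtype=float)
    if family == "zipf":
        s = params.get("s", 1.0)
        w = i ** (-s)
    elif family == "logseries":
        theta = params.get("theta", 0.5)
        # evaluate in log space: theta^i / i underflows for large i
        w = np.exp(i * np.log(theta) - np.log(i))
    elif family == "geometric":
        k = params.get("k", 0.5)
        w = k * (1 - k) ** (i - 1)
    elif family == "broken_stick":
        # expected ordered fractions: E[p_(i)] = (1/S) * sum_{j=i..S} 1/j
        inv = 1.0 / i
        w = np.cumsum(inv[::-1])[::-1] / S
    elif family == "lognormal":
        if rng is None:
            raise ValueError("lognormal profile needs an rng")
        mu, sigma = params.get("mu", 0.0), params.get("sigma", 1.0)
        w = np.sort(rng.lognormal(mu, sigma, size=S))[::-1]
    else:
        raise ValueError(f"unknown SAD family {family!r}")
    return w / w.sum()


def sample_community(
    spec: CommunitySpec,
    rng: np.random.Generator | None = None,
    species_ids: list[str] | None = None,
) -> AbundanceVector:
    """Draw one community: SAD profile over the pool, then multinomial reads.

    Zero-count species are dropped; the result is fully determined by the
    spec's (or the supplied) random generator state.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pi = relative_abundances(spec.sad_family, spec.S_pool, rng=rng, **spec.params)
    N = spec.N if isinstance(spec.N, int) else int(rng.integers(spec.N[0], spec.N[1] + 1))
    counts = rng.multinomial(N, pi)
    if species_ids is None:
        species_ids = [f"sp{i:04d}" for i in range(spec.S_pool)]
    elif len(species_ids) != spec.S_pool:
        raise ValueError("species_ids length must equal S_pool")
    return AbundanceVector(counts, species_ids=species_ids)


# -- the two-host, six-site gut design --------------------------------------------

#: Per-site community recipes calibrated so that, at the default design,
#: SF and LM communities land in the high-dominance regime (top species
#: ~30-60% of reads) and the other four sites in the even regime (~3-15%),
#: with read totals and observed richness in the ranges of a two-host
#: clone-library survey. ``pool`` is the per-host species-pool size.
SITE_DEFAULTS: dict[str, dict] = {
    "SF": dict(family="zipf", params={"s": 1.48}, pool=300, N=(360, 400), regime="dominant", dominant_phylum="Proteobacteria"),
    "SM": dict(family="zipf", params={"s": 0.75}, pool=240, N=(280, 350), regime="even", dominant_phylum=None),
    "CF": dict(family="zipf", params={"s": 0.75}, pool=270, N=(440, 530), regime="even", dominant_phylum=None),
    "CM": dict(family="zipf", params={"s": 0.78}, pool=160, N=(365, 385), regime="even", dominant_phylum=None),
    "LF": dict(family="zipf", params={"s": 0.80}, pool=220, N=(385, 440), regime="even", dominant_phylum=None),
    "LM": dict(family="zipf", params={"s": 1.45}, pool=220, N=(400, 430), regime="dominant", dominant_phylum="Actinobacteria"),
}

#: Dominance-regime target intervals in percent.
REGIME_INTERVALS = {"dominant": (30.0, 60.0), "even": (3.0, 15.0)}


def retention_probability(rho: float) -> float:
    """Pool retention probability q giving expected cross-host Jaccard rho.

    Each host independently keeps each master-pool species with
    probability q, so E|A∩B| = q^2 M and E|A∪B| = (2q - q^2) M, hence
    expected Jaccard q / (2 - q); solving gives q = 2 rho / (1 + rho).
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    return 2 * rho / (1 + rho)


@dataclass(frozen=True)
class GutDesignSpec:
    """Full two-host, six-site design.

    ``rho`` is the target expected cross-host Jaccard overlap of the
    per-site species pools. ``p_dominant_phylum`` is the probability the
    top-ranked species of a dominance-regime community belongs to the
    site's signature phylum (Proteobacteria for SF, Actinobacteria for
    LM). ``p_unclassified`` is the fraction of pool species left without
    a classified phylum.
    """

    hosts: tuple[str, ...] = ("FS1", "FS2")
    sites: tuple[str, ...] = ("SF", "SM", "CF", "CM", "LF", "LM")
    site_specs: dict | None = None  # overrides merged over SITE_DEFAULTS
    rho: float = 0.55
    p_dominant_phylum: float = 0.95
    p_unclassified: float = 0.01
    seed: int | None = None

    def resolved_sites(self) -> dict[str, dict]:
        out = {}
        for site in self.sites:
            if site not in SITE_DEFAULTS and (self.site_specs is None or site not in self.site_specs):
                raise ValueError(f"no community spec for site {site!r}")
            cfg = dict(SITE_DEFAULTS.get(site, {}))
            if self.site_specs and site in self.site_specs:
                cfg.update(self.site_specs[site])
            out[site] = cfg
        return out


@dataclass
class GutDataset:
    """Generated OTU table, taxonomy, tree, and bookkeeping pools."""

    table: OTUTable
    taxonomy: TaxonomyMap
    tree: PhyloTree
    master_pools: dict[str, list[str]]  # site -> master pool species ids
    host_pools: dict[tuple[str, str], list[str]]  # (host, site) -> retained pool


def _assign_phyla(
    pool: list[str], cfg: dict, rng: np.random.Generator, p_unclassified: float
) -> dict[str, str]:
    """Mark pool species with phyla: mostly Firmicutes, a few others.

    Dominance-regime sites get a handful of signature-phylum species from
    which the community's top rank is drawn; every site carries single
    Verrucomicrobia / Deinococcus-Thermus species and ~1% unclassified.
    """
    phyla = {sp: "Firmicutes" for sp in pool}
    order = list(rng.permutation(len(pool)))
    cursor = 0

    def take(n):
        nonlocal cursor
        picked = [pool[i] for i in order[cursor : cursor + n]]
        cursor += n
        return picked

    signature = cfg.get("dominant_phylum")
    if signature:
        accessory = "Actinobacteria" if signature == "Proteobacteria" else "Proteobacteria"
        for sp in take(6):
            phyla[sp] = signature
        for sp in take(3):
            phyla[sp] = accessory
    else:
        for sp in take(4):
            phyla[sp] = "Proteobacteria"
        for sp in take(6):
            phyla[sp] = "Actinobacteria"
    for sp in take(1):
        phyla[sp] = "Verrucomicrobia"
    for sp in take(1):
        phyla[sp] = "Deinococcus-Thermus"
    n_unclassified = int(round(p_unclassified * len(pool)))
    for sp in take(n_unclassified):
        phyla[sp] = UNCLASSIFIED
    return phyla


def generate_gut_dataset(spec: GutDesignSpec | None = None) -> GutDataset:
    """Generate the full design: one community per (host, site).

    Per site, a master species pool is drawn and each host retains each
    species with probability q(rho); a host's community permutes its
    retained pool into a rank order (forcing the top rank to a
    signature-phylum species at dominance-regime sites), assigns the
    site's SAD profile to that order, and draws reads multinomially.
    A Yule tree over the union pool supports UniFrac.
    """
    spec = spec or GutDesignSpec()
    rng = np.random.default_rng(spec.seed)
    q = retention_probability(spec.rho)
    sites = spec.resolved_sites()

    master_pools: dict[str, list[str]] = {}
    host_pools: dict[tuple[str, str], list[str]] = {}
    phylum_of: dict[str, str] = {}
    sample_ids: list[str] = []
    communities: dict[str, dict[str, int]] = {}

    for site, cfg in sites.items():
        pool_size = int(cfg["pool"])
        master_size = max(pool_size, int(round(pool_size / q))) if q < 1 else pool_size
        master = [f"{site}_sp{i:03d}" for i in range(master_size)]
        master_pools[site] = master
        phylum_of.update(_assign_phyla(master, cfg, rng, spec.p_unclassified))
        signature = cfg.get("dominant_phylum")
        signature_pool = [sp for sp in master if phylum_of[sp] == signature] if signature else []

        for host in spec.hosts:
            if q >= 1.0:
                retained = list(master)
            else:
                keep = rng.random(master_size) < q
                retained = [sp for sp, k in zip(master, keep) if k]
            if len(retained) < 3:  # degenerate retention at tiny pools
                retained = master[:3]
            host_pools[(host, site)] = retained

            order = [retained[i] for i in rng.permutation(len(retained))]
            if signature_pool and rng.random() < spec.p_dominant_phylum:
                present = [sp for sp in order if sp in signature_pool]
                if present:
                    top = present[int(rng.integers(len(present)))]
                    order.remove(top)
                    order.insert(0, top)
            community_spec = CommunitySpec(
                S_pool=len(order),
                sad_family=cfg["family"],
                params=dict(cfg["params"]),
                N=tuple(cfg["N"]) if not isinstance(cfg["N"], int) else cfg["N"],
            )
            v = sample_community(community_spec, rng=rng, species_ids=order)
            label = f"{host}{site}"
            sample_ids.append(label)
            communities[label] = dict(zip(v.species_ids, (int(c) for c in v.counts)))

    all_otus = [sp for site in sites for sp in master_pools[site]]
    counts = np.zeros((len(sample_ids), len(all_otus)), dtype=np.int64)
    index = {sp: j for j, sp in enumerate(all_otus)}
    for i, label in enumerate(sample_ids):
        for sp, n in communities[label].items():
            counts[i, index[sp]] = n
    table = OTUTable(counts, sample_ids=sample_ids, otu_ids=all_otus).drop_empty_otus()

    taxonomy = TaxonomyMap({sp: phylum_of[sp] for sp in table.otu_ids})
    tree_seed = int(rng.integers(2**31))
    tree = random_tree(len(table.otu_ids), seed=tree_seed, tip_labels=table.otu_ids)
    return GutDataset(
        table=table,
        taxonomy=taxonomy,
        tree=tree,
        master_pools=master_pools,
        host_pools=host_pools,
    )


def random_tree(
    n_tips: int,
    model: str = "yule",
    seed: int | None = None,
    tip_labels: list[str] | None = None,
) -> PhyloTree:
    """Random rooted binary tree: Yule (pure-birth) topology, exponential
    branch lengths (mean 1). Fully determined by the seed."""
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if tip_labels is None:
        tip_labels = [f"t{i}" for i in range(n_tips)]
    elif len(tip_labels) != n_tips:
        raise ValueError("tip_labels length must equal n_tips")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    while len(leaves) < n_tips:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        leaves.extend([node.new_child(), node.new_child()])
    for leaf, label in zip(leaves, tip_labels):
        leaf.taxon = tns.new_taxon(label)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.exponential(1.0))
    return PhyloTree(tree)
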