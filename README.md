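# microsad

Spatial-heterogeneity analysis of gut microbial communities from 16S
rRNA OTU count tables: per-community diversity profiles, phylum-annotated
species abundance distributions (SADs) with power-law shape fitting,
presence/absence species overlap, weighted-UniFrac/PCoA ordination, and
the correlation structure among diversity measures — plus a seeded
synthetic gut-community generator so the whole pipeline is testable
without any external data.

## The scientific problem

Gut microbiota are usually characterized from fecal samples, but the gut
is not one habitat: the food bolus (F) and the mucus layer (M) of the
small intestine (S), cecum (C) and large intestine (L) differ sharply in
disturbance and resource structure, and so do their bacterial
communities. With one community per (host, gut site), the package
quantifies that heterogeneity along several complementary axes:

- **Alpha diversity** per community `i` with counts `n_i`, `N = Σ n_i`:
  observed richness `S_obs`, Chao1 estimated richness
  (`S_obs + F1²/(2F2)` classic, `S_obs + F1(F1−1)/(2(F2+1))`
  bias-corrected, from singletons `F1` and doubletons `F2`), Shannon
  diversity `H = −Σ p_i ln p_i`, Pielou evenness `J = H/ln S_obs`, and
  PIE `1 − Σ n_i(n_i−1)/(N(N−1))`, the probability that two randomly
  picked sequences belong to different species. Rarefaction curves come
  in an analytic form, `E[S(d)] = Σ_i [1 − C(N−n_i,d)/C(N,d)]`, and a
  seeded Monte-Carlo form; the analytic curve's initial slope equals PIE
  exactly (`E[S(2)] − E[S(1)] = PIE`).
- **SAD shape.** Species ranked from most to least abundant, both axes
  natural-log transformed, fitted by OLS over all ranks:
  `ln n_(r) = intercept + slope·ln r`, power-law exponent `s = −slope`.
  Ranks whose standardized residual exceeds a threshold (default z* = 2)
  are flagged as upward deviants — the signature of a community whose top
  species is far more abundant than the power-law decay predicts. The
  top-rank dominance, `100·max n_i/N`, summarizes the same regime.
- **Overlap.** Pairwise shared-species percentages (presence = count ≥ 1)
  under three denominators (Jaccard/union, min, first set), and exact
  Venn region counts for 2–3 communities.
- **Beta diversity.** Weighted UniFrac
  `Σ_b l_b·|P_A(b) − P_B(b)|` over branches `b` with length `l_b` and
  descendant abundance fractions `P`, optionally normalized by
  `Σ_b l_b·(P_A(b)+P_B(b))`, then classical PCoA (Gower centering,
  eigendecomposition, negative eigenvalues reported, not hidden).
- **Correlation structure.** Pearson `r` with exact t-based two-sided
  p-values among `{S_obs, Chao1, H, J, dominance}` across communities.

## Worked example

Generate a two-host, six-site synthetic dataset and profile it:

```python
from microsad import (GutDesignSpec, generate_gut_dataset, profile_table,
                      sad_table, unifrac_matrix, pcoa)

ds = generate_gut_dataset(GutDesignSpec(seed=42))
print(profile_table(ds.table).round(2).head(4))
```

```
          N  S_obs   chao1     H     J   PIE
sample
FS1SF   381     61   90.00  2.63  0.64  0.82
FS2SF   368     53  116.00  2.53  0.64  0.81
FS1SM   299    135  237.70  4.48  0.91  0.98
FS2SM   297    136  222.72  4.55  0.93  0.99
```

The two SF (small-intestine food bolus) communities are species-poor and
uneven; the SM (mucus layer) communities are rich and even — the
generator reproduces the contrast the analysis is designed to detect.
The SAD stage makes the mechanism explicit:

```python
ranked, fits = sad_table(ds.table, ds.taxonomy)
print(fits.round(2).head(4))
```

```
        slope     s  intercept  r_squared  n_deviants  dominance
sample
FS1SF   -1.17  1.17       4.45       0.95           1      39.90
FS2SF   -1.26  1.26       4.64       0.96           0      39.95
FS1SM   -0.70  0.70       3.22       0.94           0       8.70
FS2SM   -0.68  0.68       3.17       0.94           0       6.73
```

SF decays fast (s ≈ 1.2, top species ~40% of all reads, one upward
deviant at rank 1); SM decays gently (s ≈ 0.7, dominance 7–9%). Ordination
separates the high-dominance sites on the first principal coordinate:

```python
result = pcoa(unifrac_matrix(ds.table, ds.tree))
print(result.coordinates.round(3).iloc[:2, :2])   # P1, P2 scores
```

The same stages run from the shell:

```bash
microsad simulate --out demo --seed 42
microsad all --table demo/table.tsv --taxonomy demo/taxonomy.tsv \
             --tree demo/tree.nwk --out demo
```

writing `diversity_profile.tsv`, `sad_fits.tsv`, `overlap_*.tsv`,
`unifrac_distances.tsv`, `pcoa_coordinates.tsv`,
`metric_correlations.tsv` and a run log of every parameter in force.

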