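# Methods

This note records the statistical conventions, numerical choices and
synthetic-data design behind `microsad`, in the spirit of a model
description: what is computed, under which assumptions, and what the
passing tests do and do not establish.

## Data model and conventions

The universal input is an integer OTU count table (samples × OTUs).
Counts are sequence tallies per OTU per community; relative abundances
are rejected at parse time because the Chao1 estimator and PIE need the
integer frequencies `F1` (singletons) and `F2` (doubletons). Taxonomy is
carried as an opaque `;`-separated lineage of which only the first level
(phylum) is interpreted; OTUs without an assignment fall back to
`Unclassified`. Sample labels of the form `<host><site>` (site one of
SF, SM, CF, CM, LF, LM) can be decoded into host/compartment/fraction
metadata, but nothing requires it — site-aware logic degrades to
"ungrouped" when labels do not parse.

## Alpha diversity

- **Shannon diversity** uses the natural log. This is forced by the
  survey tables the package reproduces: every printed evenness equals
  `H/ln S_obs` under base e (e.g. `2.39/ln 88 = 0.53`), which also fixes
  **Pielou evenness** as `J = H/ln S_obs`. `J` is an error (not a silent
  0) for single-species communities.
- **Chao1** defaults to the bias-corrected form
  `S_obs + F1(F1−1)/(2(F2+1))`; the classic form
  `S_obs + F1²/(2F2)` (fallback `S_obs + F1(F1−1)/2` when `F2 = 0`) is
  selectable everywhere a variant argument appears. Which variant
  produced the survey's printed estimates cannot be recovered from the
  publication, so Chao1 values are never used as numeric targets.
- **PIE** uses the unbiased without-replacement estimator
  `1 − Σ n_i(n_i−1)/(N(N−1))`. This choice is not cosmetic: it makes the
  identity `E[S(2)] − E[S(1)] = PIE` exact, which is the precise sense in
  which PIE is "the initial slope of the rarefaction curve".
- **Analytic rarefaction** evaluates the hypergeometric expectation via
  the recurrence `r_i(d+1) = r_i(d)·(m_i−d)/(N−d)` for the per-species
  absence probability (`m_i = N − n_i`), swept once over depths. This is
  numerically exact at the boundaries (`E[S(1)] = 1`, `E[S(N)] = S_obs`)
  and keeps the `E[S(2)]` identity to ~1e-13, where a log-gamma
  formulation loses it. **Monte-Carlo rarefaction** subsamples without
  replacement (rarefaction proper, not a bootstrap), takes an explicit
  seed, and is the only mode that supports the Chao1 metric, since that
  estimator has no closed-form subsampling expectation here.
- Default depth grids are 10 evenly spaced integers from `min(10, N)`
  to `N`.

## SAD shape and dominance

Rank-abundance records sort by abundance descending with ties broken by
OTU id ascending, so ranks are deterministic; the fit is tie-invariant
because only (rank, abundance) pairs enter. The power-law fit is OLS of
`ln n_(r)` on `ln r` over **all** ranks — no tail truncation — because
the analysis reads the deviation of the top ranks *from* that single
line. Standardized residuals divide by the residual standard deviation
with `S − 2` df; "deviates significantly upward" is operationalized as
standardized residual > z* with z* = 2 by default (the underlying survey
states no criterion). Degenerate all-equal abundances are reported as a
perfect flat fit (slope 0, R² = 1) rather than 0/0, and a numerically
perfect fit (residual sd below 1e-12 of the data scale) likewise zeroes
the standardized residuals.

One estimator property worth knowing: at shallow sampling depth the
all-ranks fit is biased low, because the long run of count-1 species
flattens the tail. At a 200-species Zipf(s = 1.2) pool the mean fitted
exponent is ≈ 1.04 at 400 reads but ≈ 1.22 at 1600 reads (own
simulations, 200 seeds). The tests therefore check exact recovery on
noise-free data, agreement with an independent naive fitter to 1e-9, and
depth-consistent recovery; shape comparisons between communities at
similar depth (the analysis use case) are unaffected, but fitted
exponents from a few hundred reads should not be read as unbiased
estimates of a generating exponent.

Top-rank dominance is `100·max n_i/N` (%), bounded by `[100/S_obs, 100]`.

## Overlap

Presence is count ≥ 1 with no abundance filtering. Because the survey's
printed overlap percentages never define their denominator, all three
conventions — Jaccard (shared/union, the default), shared/min, and
shared/first — are computed and written, so either reading can be
matched. Venn region counts are exact for 2 or 3 sets; more sets fall
back to the pairwise matrix.

## Weighted UniFrac and PCoA

UniFrac iterates branches once (postorder tip-set accumulation); the
matrix version resolves branch tip sets once per tree and accumulates
per-sample descendant fractions, so all pairs reduce to vector
operations. The **normalized** variant (raw divided by
`Σ_b l_b (P_A+P_B)`, bounded in [0, 1]) is the default; the raw variant
is exposed because the upstream pipeline's choice is not recoverable.

PCoA applies Gower centering to `−½ d²` and a symmetric
eigendecomposition. Negative eigenvalues (non-Euclidean input) are
retained and reported with a warning; Cailliez and Lingoes corrections
are available but never applied silently. Coordinates exist only for
positive eigenvalues, scaled so axis `k` has sum of squares `λ_k`
(hence per-axis variance `λ_k/n`); proportion explained divides by the
sum of positive eigenvalues only. Eigenvector sign is fixed by making
the largest-magnitude coordinate on each axis positive, so output is
deterministic across runs and platforms.

## Correlations

Pearson product-moment `r` with the exact two-sided p-value from
`t = r√(n−2)/√(1−r²)` on `n−2` df. Zero-variance input is an error, not
`r = 0`. No multiple-testing correction is applied (none is applied in
the survey being reproduced); the long-format output carries raw
p-values so users can adjust.

## The synthetic gut-community generator

The generator emulates the *statistical design* of a two-host, six-site
clone-library survey — not its sequences. Per site, a master species
pool is drawn; each host independently retains each species with
probability `q = 2ρ/(1+ρ)`, which makes the expected cross-host Jaccard
overlap of the retained pools exactly `ρ` (`E|A∩B|/E|A∪B| = q/(2−q)`).
Each (host, site) community then assigns a parametric SAD profile to a
random permutation of its pool and draws reads multinomially. Available
families: zipf (`π_i ∝ i^−s`), logseries (`π_i ∝ θ^i/i`, evaluated in
log space), lognormal (iid draws, sorted), broken stick
(`E[p_(i)] = (1/S)Σ_{j≥i} 1/j`), geometric (`π_i ∝ k(1−k)^{i−1}`).
Everything is driven by one `numpy` Generator, so outputs are
bit-reproducible from (spec, seed).

Default site recipes are calibrated to the survey's regimes: SF and LM
use steep zipf (s = 1.48 and 1.45) so the top species takes ~30–60% of
reads; SM, CF, CM, LF use mild zipf (s = 0.75–0.80) so dominance stays
in ~3–15%, with per-site pool sizes and read ranges chosen to match the
survey's 280–530 reads and tens-to-~180 observed OTUs per community.
Logseries was considered for the even sites but cannot reach that
dominance band: its rank form has top share ≈ 1/ln(S_eff), which would
need ~e¹² effective species to drop below 15%. A lognormal was also
considered, but the iid tail of its top draws is heavy enough to
throw a few percent of communities out of band, which defeats the
calibration goal of *all twelve* communities landing in regime for
≥ 90% of seeds; mild zipf concentrates dominance to multinomial noise
only (calibration harness: 100/100 seeds in regime).

The default cross-host sharing parameter is ρ = 0.55 at the pool level.
Observed-species sharing is necessarily lower — rare pool species go
unobserved at a few hundred reads — and lands at ~24% mean Jaccard,
matching the survey's reported ~20–30%.

Phylum assignment mirrors the survey's taxonomic structure: the bulk of
each pool is Firmicutes (the rare tail); dominance-regime sites carry a
handful of signature-phylum species (Proteobacteria at SF,
Actinobacteria at LM) from which the community's top rank is drawn with
probability 0.95; each site carries single Verrucomicrobia and
Deinococcus-Thermus species and ~1% unclassified. Trees are Yule
(pure-birth) topologies with iid exponential branch lengths — adequate
for exercising UniFrac, not a model of 16S evolution.

What passing tests on generated data show: the pipeline's estimators
and distances behave correctly on communities with the survey's
abundance structure (dominance regimes, pool sharing, phylum skew).
What they do not show: robustness to real-data features the generator
omits — chimeras and sequencing error, compositional coupling between
sites within a host, phylogenetic signal in abundances (phyla are
assigned independently of the tree), or any temporal dynamics.

## Problem sizes in the shipped checks

The consistency computations over the published summary rows are
instantaneous. The property suites use: 1,000 random vectors for the
Chao1 bound; 100 random vectors for the rarefaction identities; 5,000
Monte-Carlo replicates for the rarefaction convergence check; 200
seeded simulations for exponent-recovery statistics; 50 random 32-tip
trees for the UniFrac brute-force comparison; and 100 generator seeds
(12 communities each) for the dominance-regime calibration check. The
full suite runs in well under a minute on one CPU.

## Known limitations

- Chao1 variance / confidence intervals are not computed.
- Analytic rarefaction covers observed richness only (by construction).
- The power-law fit is least squares on log-log data, not a discrete
  maximum-likelihood power-law estimator; exponents are comparative
  shape descriptors, and at shallow depth carry the downward bias
  quantified above.
- Unweighted UniFrac and permutation tests (PERMANOVA/ANOSIM) are out
  of scope; the ordination is descriptive.
- The generator draws each (host, site) community independently given
  its pool; it does not model within-host correlation beyond species
  sharing.
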