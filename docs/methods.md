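# Methods

This note documents the models implemented in `isonicheweb`, the choices made
where the methods literature leaves latitude, and what the packaged synthetic
scenarios do and do not establish about real data.

## Delta notation

Isotope values are handled throughout in delta notation,
δX = 1000·(R_sample − R_std)/R_std (‰), with δ13C referenced to VPDB and δ15N
to atmospheric N2. `delta_from_ratio` / `ratio_from_delta` convert exactly and
are inverse to one another to machine precision.

## Scaled trophic position

Additive TP estimators assume a constant δ15N enrichment per trophic step.
The scaled framework instead lets the per-step enrichment narrow linearly
with dietary δ15N (Δδ15N = β0 + β1·δ15N_diet, β1 < 0), which makes consumer
δ15N saturate toward

    δ15N_lim = −β0/β1,     k = −log((β0 − δ15N_lim)/(−δ15N_lim)),

and gives, for a consumer measured at δ15N_TP against a baseline organism of
known trophic level TP_base,

    TP = [log(δ15N_lim − δ15N_base) − log(δ15N_lim − δ15N_TP)]/k + TP_base.

Defaults are the meta-analytic estimates β0 = 5.924 ‰ and β1 = −0.271, giving
δ15N_lim ≈ 21.860 ‰ and k ≈ 0.3161 (natural logs). Because TP depends on a
ratio of logs, it is invariant to the log base as long as k and the TP
equation use the same base; the property suite verifies natural-log and
base-10 evaluation agree to 1e−12. Both δ15N values must lie strictly below
δ15N_lim; at or above it the estimator raises a saturation error rather than
returning an extrapolation.

Per-taxon estimation: the baseline δ15N is the mean over the baseline taxon's
replicates *at the same site* (each site anchors its own food web). Every
other taxon's TP is computed per replicate and summarized as mean with a 95%
t-interval (df = n − 1). The baseline taxon itself is anchored by
construction — its TP is TP_base evaluated at the baseline mean — because
averaging the nonlinear per-replicate TPs would put the anchor slightly off
TP_base under noise. A bootstrap CI would also be defensible; the t-interval
was chosen for determinism and small-n transparency.

Cross-site machinery: per-species two-sample comparisons use the
pooled-variance Student's t (df = n1 + n2 − 2, two-sided), uncorrected for
multiple testing since each species' test is reported individually.
Degenerate zero-variance groups resolve to t = 0, p = 1 (equal means) or
t = ±inf, p = 0 (shifted means) instead of erroring. Cross-site agreement is
the Pearson correlation over taxa present at both sites.

## Bayesian mixing model

The source-mixing model is of the SIAR family. For consumer observation i
and isotope j, with sources k = 1..K (means μ_jk, SDs ω_jk) and trophic
enrichment factor λ_j ± τ_j:

    x_ij ~ Normal( Σ_k p_k (μ_jk + λ_j),  Σ_k p_k²(ω_jk² + τ_j²) + σ_j² ).

Choices and rationale:

- **TEF** defaults to the widely used per-step values δ13C 0.40 ± 1.30 ‰ and
  δ15N 3.40 ± 1.00 ‰, applied as exactly **one** trophic step for every
  consumer group. This is the conventional usage but is scientifically
  debatable for carnivores (two or more steps above the sources); see the
  bias discussion under the noise-free scenario below.
- **Prior** on p is Dirichlet(1, …, 1) (flat on the simplex, configurable).
- **Residual SD** σ_j per isotope carries a half-normal(0, 5 ‰) prior. It
  absorbs unmodelled variation (within-group diet heterogeneity, multi-step
  enrichment) and prevents a zero-variance degenerate likelihood.
- **Sampler**: Metropolis-within-Gibbs. The simplex is mapped to R^(K−1) by
  the additive log-ratio transform; the Jacobian (Π_k p_k) is included, so a
  flat Dirichlet prior contributes Σ_k α_k log p_k to the log target.
  Each coordinate (K−1 log-ratios, 2 log-σ) takes a Gaussian random-walk
  update. Proposal scales adapt toward 44% acceptance in windows of 200
  iterations during burn-in only, so retained draws come from a fixed
  transition kernel. Defaults: 100,000 iterations, 10,000 burn-in, thinning
  10 (9,000 retained draws); all configurable. Seeded via
  `numpy.random.default_rng`, hence bit-reproducible.
- **Summaries**: posterior means plus central (equal-tailed) credibility
  intervals at 50/75/95%, nested by construction.
- **Group fitting**: independent fits per (site, trophic category) with that
  site's source table. Consumer points default to species means (one point
  per taxon), matching the convention used for the niche metrics; fitting
  individual replicates is available by flag.

Verified sampler properties (test suite): draws stay on the simplex to 1e−9;
prior-only sampling returns marginal means 1/K; posterior means recover
p = (0.6, 0.3, 0.1) from 30 consumers within ±0.10 with 95% CIs covering the
truth; the classic Gelman–Rubin statistic over 4 independent chains is below
1.05 (the convergence check uses 20,000-iteration chains on the standard
three-source problem); permuting source order permutes the posterior within
Monte-Carlo error.

## Isotopic niche geometry

For a group of points in the (δ13C, δ15N) plane:

- **NR, CR**: ranges of δ15N and δ13C.
- **TA**: convex-hull area (Qhull), 0 for collinear input.
- **SEA**: π·√det(Σ̂) with Σ̂ the sample covariance (n−1); this is the area of
  the 1-SD ellipse, which contains 1 − e^(−1/2) ≈ 39.3% of a bivariate
  normal (verified empirically in the suite).
- **SEAc**: SEA·(n−1)/(n−2), the small-sample correction.
- **Bayesian SEA**: the covariance posterior under a conjugate
  inverse-Wishart prior (df = d + 1 = 3, scale 1e−3·I — vague but proper)
  with the mean marginalized under a flat prior. The centered scatter S then
  carries n − 1 degrees of freedom, so the posterior is
  IW(df + n − 1, scale + S); each draw maps to π·√det. With the naive
  df + n update the posterior is visibly over-concentrated (90% intervals
  cover the true SEA in slightly under 80% of simulated datasets); with
  n − 1 the suite's 200-dataset coverage check sits inside 80–97%.
- **Overlap**: ellipses are compared at SEAc scale (covariance multiplied by
  (n−1)/(n−2)), polygonized with 512 boundary vertices (configurable) and
  clipped with shapely. The polygonal route was preferred to the closed-form
  conic intersection because it is robust near tangency and directly
  checkable against grid integration (the suite verifies agreement with a
  2000×2000 grid to < 0.5%). Percentages of each group's SEAc covered are
  reported exactly and as round-half-up integers, the convention used in
  published niche-overlap tables.

Group construction defaults to one point per taxon (species means) per
(trophic category, site); groups need ≥ 3 non-collinear points, otherwise an
error names the offending group.

## Benthic surveys

Point-intercept transects (100 points per 10-m line by default) reduce to
percent cover per component; unknown component labels are kept verbatim and
only aggregated under "other" when an explicit component list is supplied.
The macroalgae aggregate sums erect fleshy and calcareous groups and
deliberately excludes algal turf. The rugosity index is chain length over
linear length (≥ 1, enforced at validation). Site contrasts use the
pooled-variance Student's t with t-quantile 95% CIs (df = n − 1 per site).

## Synthetic two-reef generator

`default_scenario()` emulates a two-site study contrasting a coral-dominated
reef with a degraded, macroalgae-dominated one:

- **Sites**: "Limones" (coral-dominated) and "Bonanza" (degraded). Six basal
  sources per site (POM, turf, epiphytes, three macroalgae). The degraded
  site spans a wider source δ13C breadth (−22.5 to −8.8 ‰ vs −21.0 to
  −10.5 ‰); source δ15N sits in the 1.0–2.8 ‰ band typical of reef primary
  producers. Source SDs (0.6–1.3 ‰) are realistic values fixed once; they
  are not estimated from any dataset.
- **Consumers**: 12 taxa per trophic category (herbivore/omnivore/carnivore)
  plus a filter-feeding baseline bivalve fixed at TP 2 feeding on POM —
  37 consumer taxa, 4 replicates each (the 3–5 replicate design floor is
  enforced). True TPs are evenly spaced within category-typical ranges
  (herbivores 2.0–2.6, omnivores 2.4–3.2, carnivores 3.0–4.1) and identical
  at both sites, reflecting a shared-species design with a common
  food-chain length.
- **Diets**: category-level pathways follow the contrast the design targets —
  on the coral site turf+epiphytes dominate all categories (60/80/85% for
  herbivores/omnivores/carnivores, herbivores take ~29% macroalgae), on the
  degraded site herbivores and omnivores feed evenly across sources while
  carnivores draw ~70% from POM. Each taxon modulates its category's
  pathway with one gamma-multiplier "dietary tendency" (~13% CV) shared by
  both sites, so a species keeps its feeding identity across reefs; the
  split of pooled groups into concrete sources is likewise drawn once per
  taxon.
- **Forward model**: replicate means are Σ_k p_k μ_jk + (TP − 1)·λ_j
  (sources sit at trophic level 1), with variance
  Σ_k p_k²(ω_jk² + τ_j²·(TP − 1)) + residual² and residual SD 0.3 ‰ per
  isotope. δ15N can alternatively follow the scaled saturating curve
  (`nitrogen_model="scaled"`), which is what the TP estimator inverts.
- **Surveys**: 8 transects of 100 multinomial point draws per site (50%
  coral cover on the coral site vs 7%; macroalgal groups dominant on the
  degraded site), chain lengths = 10 m × true rugosity (1.92 vs 1.42) ×
  lognormal noise (σ = 0.05).

`noise_free_scenario()` is the deterministic recovery fixture: all SDs zero,
δ15N generated through the scaled framework, and all sources sharing one
δ15N so that a single baseline is *exactly* valid — under these conditions
estimated TPs equal the scenario truth to machine precision, end to end.
Because a shared source δ15N leaves only the δ13C axis informative about
diet, this scenario uses two sources so the proportion vector stays
identified. Mixing recovery on it is near-exact rather than exact: the
fitting convention applies one TEF step to every group, while consumers
above TP 2 were generated with (TP − 1) steps, leaving a δ13C offset of
(TP − 2)·0.4 ‰. The recovery tests therefore hold herbivores (TP ≈ 2, where
the conventions coincide) to ±0.05 and carnivores to ±0.12.

### What the synthetic tests do and do not show

Passing recovery tests demonstrate that the estimators invert their own
generative assumptions correctly — unbiased pipelines, correct geometry,
calibrated posteriors. They do not show that real reef consumers satisfy
those assumptions: real within-species isotopic variance is not known here
(defaults are plausible, not estimated), diet–tissue discrimination varies
by taxon and tissue, consumer categories mix species with different true
enrichment-step counts, and the one-step TEF convention biases source
apportionment for high-TP groups exactly as it would in a field analysis.
Field-derived summary numbers (cover t statistics, per-species correlation
coefficients) depend on unpublished raw data and are emulated only in
distributional shape, not reproduced.

## Numerical details and degenerate inputs

- Sample SDs use the n−1 convention everywhere, matching "mean ± SD"
  reporting conventions.
- CSV isotope values serialize with 4 decimals; write→read→write is
  byte-stable.
- Collinear point sets: TA = 0; the standard ellipse raises a
  degenerate-ellipse error (singular covariance).
- Pooled source groups with a single sample have no defined SD and require
  an explicit override.
- Zero-variance t tests resolve to the appropriate limits instead of NaN.
- Pipeline seeds are spawned from one root seed with `numpy SeedSequence`;
  rerunning a configuration reproduces every output file byte for byte. The
  report manifest carries a SHA-256 of the configuration (excluding the
  output path) plus the per-stage seeds.

## Known limitations

- Two isotopes only; no concentration dependence, covariates, or
  hierarchical (MixSIAR-style) structure in the mixing model.
- No isotope-turnover, tissue-specific discrimination, or lipid-correction
  modelling.
- The survey module assumes transect points arrive already classified; no
  image analysis.
- The synthetic generator is statistical, not spatial: no within-reef
  habitat structure, no seasonal drift.
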