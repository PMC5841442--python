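# isonicheweb

Stable-isotope food-web analysis for contrasting reef sites: scaled
trophic-position estimation, Bayesian source mixing, isotopic-niche geometry,
and benthic-survey statistics, plus a synthetic two-reef data generator so
the entire pipeline can be exercised and validated without field data.

## The scientific problem

Habitat degradation on coral reefs — loss of live coral, replacement by
macroalgae — may rewire food webs. Two questions recur when comparing a
coral-dominated reef with a degraded one: does food-chain length change, and
do consumers switch basal carbon pathways? Stable isotopes answer both:
δ15N (‰ vs atmospheric N2) tracks trophic position, δ13C (‰ vs VPDB) tracks
the carbon source. This package implements the full analytical chain used in
such two-site studies, for ecologists working with tidy tables of per-specimen
δ13C/δ15N measurements and point-intercept benthic surveys.

## Core methods

**Scaled trophic position.** Per-step δ15N enrichment narrows as dietary δ15N
rises, so consumer δ15N saturates toward a limit. With discrimination modelled
as Δδ15N = β0 + β1·δ15N (β1 < 0),

    δ15N_lim = −β0/β1,    k = −log((β0 − δ15N_lim)/(−δ15N_lim)),

    TP = [log(δ15N_lim − δ15N_base) − log(δ15N_lim − δ15N_TP)] / k + TP_base

where δ15N_base is the site mean of a baseline organism of known trophic
level (here a filter-feeding bivalve at TP_base = 2). Defaults β0 = 5.924,
β1 = −0.271 give δ15N_lim ≈ 21.86 ‰, k ≈ 0.3161. TP is invariant to the
log base (tested to 1e−12).

**Bayesian mixing model (SIAR family).** Consumer isotope j is a TEF-shifted
mixture of K sources:

    x_ij ~ N( Σ_k p_k (μ_jk + λ_j),  Σ_k p_k² (ω_jk² + τ_j²) + σ_j² ),

with a flat Dirichlet prior on the proportion vector p, per-isotope residual
SD σ_j ~ half-normal(0, 5‰), and TEF λ ± τ defaulting to δ13C 0.40 ± 1.30 ‰,
δ15N 3.40 ± 1.00 ‰ per trophic step. Sampling is adaptive
Metropolis-within-Gibbs on additive log-ratio coordinates (100,000
iterations, 10,000 burn-in, thin 10 by default), summarized as posterior
means with nested 50/75/95% credibility intervals.

**Isotopic niche geometry.** Per (trophic category, site) group: δ15N and
δ13C ranges (NR, CR), convex-hull total area (TA), standard ellipse area
SEA = π√det Σ̂ (the 1-SD ellipse, ≈ 40% of the data), its small-sample
correction SEAc = SEA·(n−1)/(n−2), a Bayesian SEA posterior
(inverse-Wishart), and between-site overlap of SEAc ellipses computed by
dense polygonization and clipping, reported in ‰² and as a percentage of
each group's ellipse.

**Benthic surveys.** Point-intercept percent cover (100 points per 10-m
transect), the chain rugosity index (chain/linear length, 1 = flat), and
pooled-variance Student's t comparisons with 95% t-intervals.

See `docs/methods.md` for assumptions, priors, numerical choices, and known
limitations.

## Worked example

The packaged scenario emulates a two-reef design: 6 basal sources and 37
consumer taxa (12 per trophic category plus a baseline bivalve at TP 2)
sampled at a coral-dominated site ("Limones") and a degraded site
("Bonanza"), with the degraded site spanning a wider source δ13C range and
its carnivores drawing mostly on particulate organic matter (POM).

```python
from isonicheweb import (default_scenario, generate_dataset, estimate_species_tp,
                         cross_site_correlation, category_metrics, ellipse_overlap,
                         ChainConfig, fit_by_category, pool_sources, summarize_posterior)
from isonicheweb.synthetic_reef import DEFAULT_SOURCE_GROUPING
from isonicheweb.trophic_position import paired_taxon_values

scenario = default_scenario()
dataset = generate_dataset(scenario, seed=1)

est = {site: estimate_species_tp(dataset.samples, scenario.baseline_taxon, site)
       for site in scenario.sites}
for e in est["Limones"][:3]:
    print(f"{e.taxon:18s} TP = {e.tp_mean:.2f}  95% CI [{e.ci_low:.2f}, {e.ci_high:.2f}]  n={e.n}")
tp_a, tp_b, shared = paired_taxon_values(est["Limones"], est["Bonanza"])
print(f"cross-site TP correlation over {len(shared)} taxa: r = {cross_site_correlation(tp_a, tp_b):.2f}")

metrics = category_metrics(dataset.samples, dataset.category_map, sea_draws=10_000, seed=1)
ha, hb = metrics[("herbivore", "Limones")], metrics[("herbivore", "Bonanza")]
ov = ellipse_overlap(ha.ellipse, hb.ellipse, ha.seac / ha.sea, hb.seac / hb.sea)
print(f"herbivore SEAc overlap: {ov.overlap_area:.2f} units^2 "
      f"({ov.pct_of_a:.0f}% of Limones, {ov.pct_of_b:.0f}% of Bonanza)")

sources = {site: pool_sources([s for s in dataset.samples
                               if s.site == site and s.taxon in DEFAULT_SOURCE_GROUPING],
                              DEFAULT_SOURCE_GROUPING)
           for site in scenario.sites}
posts, _ = fit_by_category(dataset.samples, sources, scenario.tef, dataset.category_map,
                           mcmc=ChainConfig(iterations=40_000, burn_in=5_000, thin=10), seed=1)
for site in scenario.sites:
    s = summarize_posterior(posts[(site, "carnivore")])
    print(f"carnivore diet @ {site}: "
          + ", ".join(f"{k} {v['mean']*100:.0f}%" for k, v in sorted(s.items())))
```

Output:

```
herbivore_sp01     TP = 2.31  95% CI [2.01, 2.61]  n=4
herbivore_sp02     TP = 2.40  95% CI [2.25, 2.56]  n=4
herbivore_sp03     TP = 2.36  95% CI [2.25, 2.47]  n=4
cross-site TP correlation over 37 taxa: r = 0.97
herbivore SEAc overlap: 0.34 units^2 (24% of Limones, 34% of Bonanza)
carnivore diet @ Limones: POM 17%, macroalgae 35%, turf+epiphytes 48%
carnivore diet @ Bonanza: POM 59%, macroalgae 14%, turf+epiphytes 27%
```

Reading the numbers: trophic positions per species are nearly identical at
the two sites (r = 0.97) — same food-chain length — while the carnivore
mixing posteriors identify opposite carbon pathways: benthic turf+epiphytes
dominate at the coral site, POM dominates at the degraded site. Posterior
percentages are pulled toward the prior mean (33%) relative to the
generating diets (85% and 70%) because each category contributes only 12
species-mean points and the single-step TEF convention leaves residual
misfit for high-TP consumers; `docs/methods.md` discusses this bias.

The same stages are available from the shell:

```sh
isonicheweb simulate --scenario default --seed 1 --out data/
isonicheweb tp --samples data/samples.csv --baseline "Barbatia domingensis" --out tp.json
isonicheweb niche --samples data/samples.csv --draws 100000 --seed 1 --out niche.json
isonicheweb mix --samples data/samples.csv --tef "C:0.40:1.30,N:3.40:1.00" --seed 1 --out mix.json
isonicheweb survey --points data/transect_points.csv --chains data/transect_chains.csv
isonicheweb run --config study.yaml     # full pipeline + manifest
```

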