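# isocast

Forecasting the trophic impact of a predator introduction from carbon and
nitrogen stable-isotope data.

Freshwater managers often need to judge the risk of a fish introduction
*before* it happens. When donor populations of the candidate invader have
been sampled elsewhere, their δ¹³C/δ¹⁵N signatures can be superimposed
into the recipient community's isotope biplot and the standard toolkit of
isotope ecology — Bayesian trophic-position models, diet mixing models and
isotopic-niche metrics — can be run as if the introduction had occurred.
`isocast` implements that pipeline end to end for bivariate (C, N) data:

* **Two-baseline trophic position.** For a consumer with isotope values
  (δ¹³C_c, δ¹⁵N_c) and baselines b1, b2 at trophic level λ,

      δ¹⁵N_c = α·b1_N + (1−α)·b2_N + Δ_N·(TP − λ) + ε_N
      δ¹³C_c = α·b1_C + (1−α)·b2_C + Δ_C·(TP − λ) + ε_C

  where α is the proportion of baseline-1 carbon and Δ_N, Δ_C are trophic
  discrimination factors (TDFs), treated as stochastic
  (Δ_N ~ N(3.4, 0.98²) ‰ by default). Posterior sampling is by partially
  collapsed Gibbs: the TDF and baseline-mean latents are integrated out
  analytically when updating (TP, α), then restored by an exact draw.
* **Diet mixing model.** Consumer values are a proportion-weighted
  combination of prey-source signatures plus TDF, with per-source
  variance propagation and a residual term
  (`y_ij ~ N(Σ_k p_k μ_kj + Δ_j, √(Σ_k p_k²(σ_kj²+τ_j²) + σ_j²))`);
  the simplex prior is softmax-normal.
* **Standard ellipse niches.** SEA = π√det Σ, the small-sample corrected
  SEAc = SEA·(n−1)/(n−2), and the Bayesian SEAb from a conjugate
  normal–inverse-Wishart posterior (closed form, no MCMC).
* **Directional niche overlap.** The probability that a random individual
  of group A falls inside group B's α-level niche region, estimated by
  Monte Carlo over both groups' posteriors (10,000 steps by default);
  the resulting matrix is asymmetric by construction.
* **Invasion projection.** `run_projection` chains the stages: donor
  signatures appended raw ("superimposition"), prey selected by the
  stated exclusion rules, TP for every fish group, diet posteriors per
  donor, SEAb and directional overlap versus the resident apex predator,
  with full provenance and an assumed-SD sensitivity scan.

The İznik Lake community table (19 groups, 12 fish species) and the
five-site Eurasian perch donor table ship as packaged fixtures; a
synthetic-data module generates communities and consumers with known
truth for testing every stage without downloads.

## Worked example

`examples/full_projection.py` forecasts a perch introduction into İznik
Lake (shortened chains for speed; see `examples/` for one script per
capability):

```
posterior median trophic positions (top 6):
P. fluviatilis (lakes)         5.46
P. fluviatilis (reservoirs)    4.62
Silurus glanis                 4.55
Gambusia holbrooki             3.65
Vimba vimba                    3.51
Rutilus rutilus                3.37

P. fluviatilis (lakes): top-2 prey = ['Vimba vimba', 'Rutilus rutilus']
P. fluviatilis (reservoirs): top-2 prey = ['Rutilus rutilus', 'Vimba vimba']

P(P. fluviatilis (lakes) individual in S. glanis 95% niche) = 90.0%
P(P. fluviatilis (reservoirs) individual in S. glanis 95% niche) = 75.3%
```

Reading the numbers: both donor perch groups would enter at top-predator
trophic positions (TP ≥ 4.6, alongside the resident catfish at 4.55),
their forecast diet concentrates on *Vimba vimba* and *Rutilus rutilus*,
and individuals of either group fall inside the catfish's 95% isotopic
niche with high probability — predation pressure on two cyprinids plus
competition with the established apex predator.

A thin CLI mirrors the library (`isocast tp|mix|niche|overlap|project
|simulate|config`); every stochastic subcommand requires `--seed`.

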