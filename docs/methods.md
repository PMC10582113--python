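# Methods

This note documents the models, priors, numerical choices and known
limitations of `isocast`. Notation: δ¹³C and δ¹⁵N are per-mil (‰)
deviations from VPDB and atmospheric N₂; Σ is a 2×2 covariance in ‰².

## Two-baseline trophic position

A consumer's δ¹⁵N enrichment above an isotopic baseline measures its
trophic position (TP). With two baselines — here detritus (baseline 1)
and pooled phyto-/zooplankton (baseline 2) — the consumer's δ¹³C places
it on a mixing axis between the two basal carbon pathways, and the
mixing proportion α sets the effective δ¹⁵N baseline:

    δ¹⁵N_i ~ Normal(α·b1_N + (1−α)·b2_N + Δ_N·(TP−λ), σ_N)
    δ¹³C_i ~ Normal(α·b1_C + (1−α)·b2_C + Δ_C·(TP−λ), σ_C)

**Parameters and defaults.**

| parameter | meaning | default | why |
|---|---|---|---|
| Δ_N | ¹⁵N trophic discrimination per step | 3.4 ± 0.98 ‰ | canonical muscle-tissue literature value |
| Δ_C | ¹³C discrimination per step | 0.39 ± 1.3 ‰ | canonical literature value |
| λ | trophic level of the baselines | 2 | baselines treated as primary-consumer level; configurable because detritus and plankton levels genuinely differ |
| TP prior | Uniform(λ, 10) | — | weakly informative, covers any plausible food web |
| α prior | Beta(1, 1) | — | uninformative on the mixing proportion |
| σ_N, σ_C prior | half-Normal(5 ‰) | — | vague; floored at 10⁻³ ‰ (below) |

TDFs are *simulated*, not fixed: Δ_N, Δ_C are latent parameters with the
TDF distribution as prior, redrawn every iteration. Baseline means are
likewise latent with prior Normal(mean, SD/√n); for n < 3 the SD is used
unreduced (too few samples to trust the √n shrinkage). Baseline 2 pools
the phytoplankton and zooplankton rows by unweighted mean of means and
root-mean-square of SDs, with sample sizes summed.

**Sampler.** Partially collapsed Gibbs, vectorized across chains
(default 4 chains × 10,000 iterations after 2,000 burn-in, matching the
stated Monte-Carlo chain length of the directional-overlap stage). TP
and Δ_N enter the δ¹⁵N mean only through Δ_N·(TP−λ), so they are jointly
unidentified by data and mix poorly under one-at-a-time updates (lag-1
autocorrelation ≈ 0.99 in plain Gibbs). Because the TDFs and baseline
means are normal latents acting linearly on the group mean, they are
integrated out in closed form — their contribution is extra variance on
the consumer mean — giving a 2-D collapsed posterior for (TP, α) updated
by adaptive random-walk Metropolis (Robbins–Monro adaptation to 0.44
acceptance during burn-in); the latents are then restored by an exact
draw from their joint normal conditional (rank-one update of the
diagonal prior precision), and log σ_N, log σ_C take adaptive
random-walk steps. The collapsed sampler was cross-checked against
brute-force grid integration of the exact posterior (medians and 95%
interval endpoints agree to three decimals) and reduces the lag-1
autocorrelation to ≈ 0.6.

**Numerical choices.** σ's are floored at 10⁻³ ‰: with all-identical
consumer points the σ posterior is improper at 0, and the floor makes
the degenerate limit (posterior collapsing onto the closed-form point
estimate) well behaved. Pinned latents (prior SD 0) are handled with a
10⁻⁸ prior-SD floor so the collapsed algebra stays uniform. Chains are
initialized at the closed-form point estimate with small jitter.
Split-R̂ on TP and α is reported in `diagnostics`; R̂ > 1.1 flags
non-convergence without aborting.

## Diet mixing model

For consumer point i and isotope j over K prey sources:

    y_ij ~ Normal( Σ_k p_k·μ_kj + Δ_j ,
                   sqrt( Σ_k p_k²·(σ_kj² + τ_j²) + σ_j² ) )

with diet proportions p on the simplex, source moments (μ_kj, σ_kj), TDF
mean/SD (Δ_j, τ_j), and a residual SD σ_j (half-Normal(2 ‰) prior)
absorbing group-level overdispersion. TDF uncertainty enters through the
variance term τ_j² with the mean shift fixed at Δ_j — the formulation in
which the synthetic consumer generator and the fitted likelihood are one
model, so inverse-fit recovery tests are exact. The prior on p is induced
by independent standard-normal latents pushed through the softmax:
symmetric over sources, strictly interior to the simplex. Sampling is
coordinate-wise adaptive Metropolis on the latent vector plus σ blocks
(4 × 10,000 after 2,000 burn-in by default). A single source returns
p = 1 without sampling; identical source means attach a
non-identifiability warning. Concentration dependence and
elemental-concentration weighting are not modelled (no such data here).

## Standard ellipse niches

The standard ellipse of a bivariate normal fit (the c = 1 Mahalanobis
contour) covers 1 − e^{−1/2} ≈ 39.35 % of the mass; "40 % of central
data points" is interpreted as this ellipse, with the exact coverage
level still exposed as a parameter. SEA = π√det Σ with the n−1 sample
covariance; SEAc = SEA·(n−1)/(n−2). SEAb draws come from the conjugate
normal–inverse-Wishart posterior with a vague proper prior (κ₀ = 10⁻³,
ν₀ = 3, scale 10⁻³·I ‰², prior mean at the sample mean) — closed form,
no MCMC. Ellipse boundaries are 360-vertex polylines; polygon areas use
the shoelace formula (via `shapely`), converging to π·q·√det Σ as the
vertex count grows.

## Niche overlap

Geometric overlap clips the two coverage-level ellipse polygons (convex
360-gons) and reports the intersection as a fraction of each ellipse and
as Jaccard similarity of the union; the Bayesian version pairs SEAb
draws. Directional overlap follows the probabilistic-niche-region
definition: per Monte-Carlo step (default 10,000), draw (μ, Σ) for both
groups from their normal–inverse-Wishart posteriors, draw one individual
from A's posterior predictive, and test whether it falls inside B's
χ²₂(α) Mahalanobis region. The matrix is asymmetric by construction — a
specialist nested in a generalist's niche overlaps it almost surely but
not conversely. Report tables are oriented rows = species A,
columns = species B. Because the raw normalization behind single-number
"percent overlap" summaries is ambiguous, all three geometric fractions
are always labelled explicitly.

## Superimposition and projection

Donor signatures are appended to the recipient community unchanged
(status `hypothetical`) — the "raw superimposition" forecast, assuming
the introduced population's niche would settle within the range spanned
by the donor populations. An optional standardized mode shifts donor
values by the difference of donor-system and recipient baseline means
when donor baselines are available. Recipient rows are never modified,
so resident inference is provably unchanged by adding donors.

Donor data here are site means only; pseudo-individuals (default 10 per
site) are generated around each site mean with an assumed SD (default
1 ‰ per isotope — a typical within-population spread for fish muscle).
Because that SD is an assumption, `run_projection` scans it (0.5/1.0/
2.0 ‰ when enabled) and reports the sensitivity of donor TP and top prey.
Prey selection takes all resident fish except the apex predator and
explicit exclusions, optionally dropping taxa whose mean total length
exceeds a threshold (a coarse stand-in for gape limitation; no
mouth-morphometry model). Non-fish groups are never prey.

## Moment-matched pseudo-individuals

Published community tables report *sample* statistics (n, mean, SD).
When the raw individuals are unavailable, `generate_group(...,
match_moments=True)` draws pseudo-individuals and affinely standardizes
them so their sample mean and covariance equal the printed values
exactly. A normal likelihood depends on data only through these
sufficient statistics, so moment-matched groups reproduce the published
data's likelihood exactly rather than a seed-dependent perturbation of
it; this is how the packaged tables are expanded for fitting. Plain
(unmatched) draws remain the default for generic simulation.

## What the synthetic generator does and does not emulate

Groups are bivariate normal with configurable means, SDs and correlation
(ρ = 0 by default — per-taxon isotope covariances are rarely reported);
consumers come from the mixing likelihood at known diet. One integer
seed plus the group label defines an independent stream per group, so
resizing one group never perturbs another's draws. Real isotope data
deviate from this in ways the generator does not model: skewed or
multimodal clusters (ontogenetic diet shifts), temporal baseline drift,
tissue-turnover lags, and lipid effects on δ¹³C. Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to these field realities.

## Problem sizes used by the tests

Unit tests run 2 chains × 1,500 iterations; the acceptance layer uses
2 × 4,000 for the İznik refits and 100 × (2 × 1,000) for the coverage
study; `scripts/acceptance.py` uses the full 4 × 10,000 default. The
coverage study generates replicates at fixed truth (TDF and baseline
means at their nominal values, consumer sampling noise fresh per
replicate), matching the synthetic generator's fixed-mean design;
intervals are then conservative because the model propagates TDF and
baseline uncertainty the generator holds fixed.

## Known limitations

* Two isotopes, two baselines, one consumer group per fit; no
  hierarchical pooling across consumers, one-baseline or multi-tissue
  models, or lipid correction.
* TP and Δ_N are only jointly identified; the TP posterior inherits the
  TDF prior's relative width and the reported medians depend on the TDF
  and λ configuration, which should be stated with any result.
* Mixing-model results for consumers far outside the source mixing
  polygon load on boundary sources and the residual term; inspect the
  biplot before trusting proportions.
* The superimposition forecast ignores behavioural and density feedbacks
  (prey switching, competition dynamics, young-of-the-year prey) — it is
  a static isotopic projection, not a population model.
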