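# Methods

## The model

A cultural innovation diffuses through a metapopulation of communities.
Communities holding the skill (fraction *I*) transmit it to susceptible
ones (*S* = 1 − *I*); holders lose it at recovery rate γ (death of the
skilled few, community fission or destruction).  Inter-community
encounter rates are assumed to scale as ρ^(1/φ) with population density
ρ; φ = 2 corresponds to the empirical square-root relation between
hunter-gatherer mobility and density, and the package treats φ as a
fixed design constant per analysis (sensitivity runs at 1.5, 2.5 and 6
are bundled).  With the transmission rate absorbed into the density
scale (β ≡ 1 — only the ratio γ/β is ever identifiable, so the simulator
exposes no separate β; any per-community contact count is likewise
folded into this normalisation), the dynamics are

    dI/dt = ρ^(1/φ) I (1 − I) − γ I.

Below the critical density ρ\* = γ^φ the only equilibrium is extinction;
above it a stable endemic fraction I\*(ρ) = 1 − (ρ\*/ρ)^(1/φ) exists,
continuous and increasing in ρ.

The observable is per (lattice cell × 25-year window) presence of the
*earliest* dated art at a location ("site"), modelled as a Bernoulli
trial with success probability

    P(ρ) = (1 − ε) ζ I*(ρ) ρ + ε,

clipped to [0, 1] so it is a valid probability (the clip engages only at
implausibly large ζρ).  ζ (per density unit) collects preservation and
research-effort effects; ε ∈ [0, 1) is a density-independent error
floor, so P(ρ) = ε everywhere at or below threshold.  Rivals: a
proportional model P = ζρ + ε (innovation scales with the number of
potential inventors) and a null model P = k.

## Parameters

| parameter | units | role | typical magnitude |
|---|---|---|---|
| γ | density^(1/φ) | recovery-to-transmission ratio; sets ρ\* = γ^φ | 2–6 |
| ζ | per (individuals/100 km²) | detection scale | 10⁻⁷–10⁻³ |
| ε | — | error floor | 0–10⁻³ |
| φ | — | encounter exponent | 2 |

Densities are individuals per 100 km² throughout (a "25–30 per km²"
reading of site medians is a unit slip; per-100 km² is canonical here).
Dates are calendar years before 1950.

## Likelihood and inference

Samples are binned by density into 35 equal-width bins from 0 to the
maximum observed density (bin count and scheme configurable; an
equal-count alternative and a per-bin mean representative are available
behind flags — the default representative density is the bin midpoint).
The log-likelihood is the binned Bernoulli form

    Σ_b [ n_site(b) ln P(ρ_b) + n_nonsite(b) ln(1 − P(ρ_b)) ],

with 0·ln 0 = 0, so a model putting P = 0 in a bin that holds sites
scores −∞ and simply ranks last.  Predicted frequencies are not
renormalised per bin.

Posteriors come from exhaustive evaluation over a parameter grid: γ and
ε uniformly spaced, ζ geometrically spaced, 50 nodes per axis by default
(resolution recorded in every output).  Equal node weights make the ζ
prior log-uniform.  Normalisation uses log-sum-exp (−∞ nodes drop out
naturally); the MAP is the first maximal node (deterministic
tie-break).  When more than 1% of posterior mass sits on a prior bound
the result carries an explicit warning, and an opt-in `auto_widen`
re-runs with that bound pushed out one octave — never silently.

The threshold posterior lives on the atoms ρ\* = γ^φ with the γ
marginal's weights.  Quantiles interpolate linearly between atoms by
placing each atom at the midpoint of its own mass on the CDF axis: a
point mass returns its atom for every probability, and a symmetric
two-atom posterior at {10, 20} has median 15.

The log marginal likelihood is the equal-weight mean of the likelihood
over the grid (log-sum-exp minus log node count); trapezoidal end-point
weights are available behind a flag and move the value by well under one
log unit on realistic grids.  Bayes factors are ratios of marginal
likelihoods; AIC = 2k − 2 ln L̂ uses the grid maximum with k = 3
(epidemiological), 2 (proportional), 1 (null).  The rival models' priors
are not separately specified anywhere authoritative, so the proportional
model reuses the analysis's ζ and ε bounds and the null model uses a
geometric k grid on [10⁻⁸, 10⁻¹]; Bayes factors against these rivals
inherit the usual sensitivity to prior ranges, which is why the package
also reports AIC.

## Nonparametric statistics

KS is the standard two-sided two-sample test with asymptotic p-values.
Mann–Whitney U follows the "pairs where a site density exceeds a
non-site density" convention (ties count ½), normal approximation with
continuity and tie correction, exact enumeration when min(n₁, n₂) ≤ 8
and no ties.  The sub-threshold binomial test counts sites strictly
below the threshold (inclusive comparison available and reported when
used), takes p as the non-site fraction in the same range at full
precision, and computes P(X ≤ k) by log-space accumulation of log-pmf
terms, exact to ~10⁻¹⁰ relative error against rational arithmetic.

## The synthetic generator

`synthetic.generate_landscape` draws i.i.d. cell densities from a
right-skewed law — default lognormal with median 15 individuals/100 km²
and σ = 1, truncated at a carrying-capacity ceiling of 150 — with an
optional fraction of sea (missing) cells, and scatters centroids over
the two non-equatorial latitude bands so geographic filters stay
exercisable.  The cap reflects how climate-driven density rasters are
produced (carrying capacity saturates at a maximum K); it also keeps
equal-width binning meaningful, since an unbounded tail would let a
handful of extreme cells dominate the bin span.  `generate_sites` then
inverts the observation model: each non-missing cell-window is a site
with probability P(ρ) under the chosen generating model, making the
generator the exact ground truth for recovery and model-selection
studies.

What the generator does *not* emulate: spatial and temporal
autocorrelation of densities (the likelihood treats cells independently,
so this matches the inference assumption but not real landscapes;
correlated stress tests can be layered on), climate dynamics, dispersal,
coastline effects, or non-random research effort.  Passing recovery
tests therefore show the inference machinery is correct and well
calibrated *under the model's own assumptions* — they cannot rule out
bias in real data from clustered sampling or dating error.

The bundled `data/synthetic_survey_raw.csv` is a fully synthetic
stand-in for a raw 190-record literature survey: its coordinates and
dates are fabricated, but its bookkeeping structure (eight exclusion
categories reducing 190 records to 133; 80 of 133 Holocene; 5 outside
the analysis window) matches the printed survey tallies so the cleaning
and counting paths are exercised at realistic scale.

## Numerical choices

- SIR integration: fixed-step RK4, default dt = 0.01/γ; the state is
  clamped to [0, 1] (the logistic-type ODE cannot leave it; clamping
  only absorbs round-off).  Equilibria match the closed form to 10⁻³
  over a (ρ, γ, φ) grid.
- Grid evaluation is fully vectorised; a 50×50×50 grid over 35 bins
  evaluates in about a second on one CPU.
- Degenerate inputs: ρ = 0 returns ε (epidemiological and proportional)
  or k (null); an all-−∞ grid raises an explicit error; empty sample
  sets and siteless analyses fail loudly.
- Nearest-centroid lookup uses the haversine great-circle distance; time
  windows are [t, t + 25) with the final upper edge closed.

## Problem sizes

The test suite runs landscapes of 1.5–3×10⁵ cells for unit and
consistency checks and 20 seeded landscapes of 10⁶ cells for the
recovery study (a scale chosen to mirror the real analyses' ~10⁻⁵ site
rate — about 100 sites per million cell-windows).  The acceptance script
uses the same sizes; the whole suite completes in a few minutes on one
CPU.

## Known limitations

- Mann–Whitney U is computed on the raw samples; published tables that
  report U on reduced representations of very large samples are not
  directly comparable (the binned route changes U's scale).
- Bayes factors depend on prior ranges, especially for the null model's
  k grid; AIC and the sub-threshold test provide prior-free
  corroboration.
- The likelihood's independence assumption ignores spatial clustering of
  sites; reported p-values and Bayes factors are optimistic to the
  extent real sites are dependent.
- Grid inference is exhaustive by design (replicating the original
  method); it scales as the product of node counts and is not meant for
  more than a handful of parameters.
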