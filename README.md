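# cultepi

Epidemiological modelling of cultural innovations against population
density: does an innovation such as parietal rock art persist in the
archaeological record only where ancient population density exceeded a
critical threshold?

`cultepi` is written for archaeologists and quantitative students of
cultural evolution who want to test demographic hypotheses on
presence/absence data.  It treats the maintenance of a cultural skill in
a metapopulation like an endemic disease: communities that hold the
skill ("infected", fraction *I*) pass it to those that do not at a rate
set by inter-community encounters, and lose it (recovery rate γ) through
death, fission or drift.  With encounter rates scaling as ρ^(1/φ) in
population density ρ (φ = 2 encodes the square-root mobility relation
seen in hunter-gatherer ethnography) and transmission normalised to 1,

    dI/dt = ρ^(1/φ) · I · (1 − I) − γ · I

has a stable endemic equilibrium only above the critical density
ρ\* = γ^φ, where the equilibrium infected fraction is
I\*(ρ) = 1 − (ρ\*/ρ)^(1/φ).  The archaeological observable is the *site
detection ratio* — the probability that a ~100 km lattice cell in a
25-year window holds the earliest dated art at a location:

    P(ρ) = (1 − ε) · ζ · I*(ρ) · ρ + ε

with ζ a detection scale (geology, climate, research effort) and ε an
error floor.  The package fits this model by exhaustive Bayesian grid
likelihood over (γ, ζ, ε), compares it against a proportional rival
(P = ζρ + ε) and a density-independent null (P = k) with Bayes factors
and AIC, and runs the supporting nonparametric statistics (two-sample
Kolmogorov–Smirnov, Mann–Whitney U, and a binomial test for a deficit of
sub-threshold sites).  A synthetic-landscape generator with a known
ground truth makes every stage testable end to end — including full
parameter-recovery and model-selection studies — without external data.

## Worked example

Generate a million-cell-scale synthetic landscape whose sites follow the
epidemiological model with γ = 3.5 (so ρ\* = 12.25 individuals/100 km²),
then recover the threshold from the data alone:

```python
import cultepi as ce

spec = ce.SyntheticSpec(
    n_cells=300_000,
    model_params=ce.ModelParams(gamma=3.5, zeta=5e-5, epsilon=1e-6, phi=2.0),
    seed=42,
)
grid = ce.generate_landscape(spec)
samples = ce.generate_sites(grid, spec)

cmp = ce.compare_distributions(samples)
binned = ce.bin_samples(samples, n_bins=35)
post = ce.evaluate_grid(binned, ce.PriorGrid(2, 5, 1e-7, 1e-3, 0, 5e-6), phi=2.0)
q = ce.threshold_quantiles(post)
null = ce.fit_null(binned)
sub = ce.subthreshold_binomial(samples, q[2])
```

Output:

```
128 sites among 300,000 cell-windows
median density: sites 67.65, non-sites 14.97 (KS D = 0.63, p = 4.1e-50)
critical density rho*: median 13.02, 95% CI [10.08, 15.43]  (true value 12.25)
Bayes factor epidemiological vs null: 6.08e+66
sub-threshold sites: 0/128 (non-site fraction below threshold 0.44, tail P = 1.99e-33)
```

Sites concentrate at high density (their median is four times the
landscape median), the posterior 95% interval for the critical density
covers the generating value, the Bayes factor overwhelmingly prefers the
epidemiological model over the null, and no site falls below the
inferred threshold even though 44% of non-site cell-windows do — the
signature threshold effect.

Real data enter through CSV: a site table (one row per dated site with
coordinates and years-BP dates) and a population grid in long format
(`cell_id, lat, lon, time_bp, density`) or NetCDF.  Twelve named
analysis configurations — non-equatorial full data, Australia,
France–Spain–Portugal, rest-of-world, Holocene/Pleistocene splits, an
exact-direct-dates subset, zero-density inclusion, an alternative
density raster, and φ ∈ {1.5, 2.5, 6} sensitivity runs — ship as YAML
files freezing each analysis's sample filter and prior bounds:

```sh
cultepi fit --name eriksson --site-csv sites.csv --grid-csv grid.csv --out results/
cultepi compare --name eriksson --name australia --out report.json
cultepi sirplot --gamma 3.5 --out sir.png
cultepi recovery --n-seeds 20 --out recovery.json
```

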