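"""End-to-end analysis runs: filter, test, fit, compare, report, plot.

One *analysis* pairs a sample filter (which cells and windows count as
non-sites, which sites enter) with a prior grid and an encounter
exponent phi, and produces every summary quantity of the study design:
sample counts, medians, KS and Mann-Whitney statistics, the posterior
threshold quantiles, maximum log-likelihood, AICs for the three rival
observation models, Bayes factors, and the sub-threshold binomial test.
Named analyses (``eriksson``, ``australia``, ``france_spain_portugal``,
``rest_of_world``, ``holocene``, ``pleistocene``, ``exact_direct``,
``include_zero``, ``timmermann``, ``phi_1.5``, ``phi_2.5``, ``phi_6.0``)
freeze the filters and prior bounds of the published analysis columns in
versioned YAML config files shipped with the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .inference import (
    N_PARAMS,
    BinnedCounts,
    PosteriorResult,
    PriorGrid,
    aic,
    bayes_factor,
    bin_samples,
    evaluate_grid,
    fit_null,
    fit_proportional,
    threshold_quantiles,
)
from .io import FilterSpec, PopulationGrid, SampleSet, build_samples, read_site_table, region_rectangle_filter
from .stats import compare_distributions, subthreshold_binomial
from .synthetic import SyntheticSpec, generate_landscape, generate_sites

logger = logging.getLogger("cultepi")

__all__ = [
    "AnalysisConfig",
    "AnalysisSummary",
    "named_config",
    "list_named_analyses",
    "run_analysis",
    "analyze_samples",
    "report",
    "plot_detection",
    "recovery_study",
]

THRESHOLD_KEYS = ("q0.025", "q0.25", "q0.5", "q0.75", "q0.975")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run.

    Inputs are either file paths (``site_csv`` + ``grid_csv`` /
    ``grid_netcdf``) or a :class:`SyntheticSpec`; the filter, prior
    bounds, phi, bin count, grid resolution and seed complete the recipe.
    """

    name: str = "custom"
    site_csv: str | None = None
    grid_csv: str | None = None
    grid_netcdf: str | None = None
    synthetic: SyntheticSpec | None = None
    filter: FilterSpec = field(default_factory=FilterSpec)
    exclude_rectangles: list = field(default_factory=list)
    prior: PriorGrid = field(
        default_factory=lambda: PriorGrid(2.0, 5.0, 1e-7, 1e-4, 0.0, 5e-6)
    )
    phi: float = 2.0
    n_bins: int = 35
    seed: int = 0
    null_k_min: float = 1e-8
    null_k_max: float = 0.1

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        if self.synthetic is not None:
            payload["synthetic"] = self.synthetic.to_jsonable()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisSummary:
    """All summary quantities of one analysis, JSON-serialisable."""

    name: str
    n_sites: int
    n_cells: int
    median_sites: float
    median_nonsites: float
    ks_d: float
    ks_p: float
    mw_u: float
    mw_p: float
    threshold: dict
    max_log_likelihood: float
    aic_epidemiological: float
    aic_proportional: float
    aic_null: float
    bf_vs_proportional: float
    bf_vs_null: float
    n_subthreshold_sites: int
    prop_subthreshold_nonsites: float
    subthreshold_tail_probability: float
    boundary_warnings: list
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSummary":
        return cls(**d)


# ---------------------------------------------------------------------------
# named configurations

def list_named_analyses() -> list[str]:
    """Names of the bundled analysis configurations."""
    base = resources.files("cultepi").joinpath("configs")
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))


def named_config(name: str, **overrides) -> AnalysisConfig:
    """Load a bundled analysis configuration by name.

    Keyword overrides replace top-level :class:`AnalysisConfig` fields
    (e.g. ``synthetic=...`` to point a named filter at synthetic data).
    """
    path = resources.files("cultepi").joinpath("configs", f"{name}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown analysis {name!r}; available: {list_named_analyses()}"
        ) from None
    return config_from_dict(yaml.safe_load(text), **overrides)


def config_from_dict(raw: dict, **overrides) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a plain (YAML) mapping."""
    raw = dict(raw)
    filt = raw.pop("filter", {}) or {}
    fs = FilterSpec(
        latitude_bands=[tuple(b) for b in filt["latitude_bands"]]
        if filt.get("latitude_bands") else None,
        date_range=tuple(filt["date_range"]) if filt.get("date_range") else None,
        rectangle=(tuple(filt["rectangle"][0]), tuple(filt["rectangle"][1]))
        if filt.get("rectangle") else None,
        include_zero_density=bool(filt.get("include_zero_density", False)),
        quality_only=bool(filt.get("quality_only", False)),
    )
    pr = raw.pop("prior", {}) or {}
    prior = PriorGrid(
        gamma_min=float(pr.get("gamma_min", 2.0)),
        gamma_max=float(pr.get("gamma_max", 5.0)),
        zeta_min=float(pr.get("zeta_min", 1e-7)),
        zeta_max=float(pr.get("zeta_max", 1e-4)),
        eps_min=float(pr.get("eps_min", 0.0)),
        eps_max=float(pr.get("eps_max", 5e-6)),
        n_gamma=int(pr.get("n_gamma", 50)),
        n_zeta=int(pr.get("n_zeta", 50)),
        n_eps=int(pr.get("n_eps", 50)),
    )
    synth = raw.pop("synthetic", None)
    if synth is not None and not isinstance(synth, SyntheticSpec):
        synth = SyntheticSpec(**synth)
    excl = [
        ((tuple(r[0])), tuple(r[1])) for r in raw.pop("exclude_rectangles", [])
    ]
    cfg = AnalysisConfig(filter=fs, prior=prior, synthetic=synth,
                         exclude_rectangles=excl, **raw)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# running

def _load_samples(config: AnalysisConfig) -> SampleSet:
    if config.synthetic is not None:
        spec = config.synthetic
        logger.info("generating synthetic landscape: %d cells x %d steps, seed %d",
                    spec.n_cells, spec.n_steps, spec.seed)
        grid = generate_landscape(spec)
        samples = generate_sites(grid, spec)
        # apply the analysis filter to the synthetic samples as well
        mask = np.ones(len(samples), dtype=bool)
        fs = config.filter
        if fs.latitude_bands and samples.latitude is not None:
            band = np.zeros(len(samples), dtype=bool)
            for south, north in fs.latitude_bands:
                band |= (samples.latitude >= south) & (samples.latitude <= north)
            mask &= band
        if not fs.include_zero_density:
            mask &= samples.density > 0
        return samples.subset(mask)

    if config.grid_csv:
        grid = PopulationGrid.from_long_csv(config.grid_csv)
    elif config.grid_netcdf:
        grid = PopulationGrid.from_netcdf(config.grid_netcdf)
    else:
        raise FileNotFoundError("config names neither a grid nor a synthetic spec")
    if not config.site_csv:
        raise FileNotFoundError("config names no site table")
    sites = read_site_table(config.site_csv)
    logger.info("loaded %d site records, %d grid cells", len(sites), grid.n_cells)
    samples = build_samples(grid, sites, config.filter)
    logger.info("built %d samples (%d sites); site log: %s",
                len(samples), samples.n_sites, samples.log)
    return samples


def analyze_samples(
    samples: SampleSet,
    config: AnalysisConfig,
) -> tuple[AnalysisSummary, BinnedCounts, PosteriorResult]:
    """Run the statistics and inference stack on prepared samples.

    Returns the summary plus the binned counts and epidemiological
    posterior so callers can plot or interrogate them.
    """
    for nw, se in config.exclude_rectangles:
        before = len(samples)
        samples = region_rectangle_filter(samples, nw, se, invert=True)
        logger.info("excluded rectangle %s/%s: %d -> %d samples",
                    nw, se, before, len(samples))
    if len(samples) == 0:
        raise ValueError(f"analysis {config.name!r}: no samples after filtering")
    if samples.n_sites == 0:
        raise ValueError(f"analysis {config.name!r}: no sites after filtering")

    comparison = compare_distributions(samples)
    binned = bin_samples(samples, n_bins=config.n_bins)

    epi = evaluate_grid(binned, config.prior, phi=config.phi)
    prop = fit_proportional(
        binned,
        zeta_min=config.prior.zeta_min, zeta_max=config.prior.zeta_max,
        eps_min=config.prior.eps_min, eps_max=config.prior.eps_max,
        n_zeta=config.prior.n_zeta, n_eps=config.prior.n_eps,
    )
    null = fit_null(binned, k_min=config.null_k_min, k_max=config.null_k_max)

    quants = threshold_quantiles(epi)
    threshold = dict(zip(THRESHOLD_KEYS, (float(q) for q in quants)))
    sub = subthreshold_binomial(samples, threshold["q0.5"])

    summary = AnalysisSummary(
        name=config.name,
        n_sites=comparison.n_sites,
        n_cells=comparison.n_cells,
        median_sites=comparison.median_sites,
        median_nonsites=comparison.median_nonsites,
        ks_d=comparison.ks_d,
        ks_p=comparison.ks_p,
        mw_u=comparison.mw_u,
        mw_p=comparison.mw_p,
        threshold=threshold,
        max_log_likelihood=epi.max_log_likelihood,
        aic_epidemiological=aic(epi.max_log_likelihood, N_PARAMS["epidemiological"]),
        aic_proportional=aic(prop.max_log_likelihood, N_PARAMS["proportional"]),
        aic_null=aic(null.max_log_likelihood, N_PARAMS["null"]),
        bf_vs_proportional=bayes_factor(
            epi.log_marginal_likelihood, prop.log_marginal_likelihood
        ),
        bf_vs_null=bayes_factor(
            epi.log_marginal_likelihood, null.log_marginal_likelihood
        ),
        n_subthreshold_sites=sub.k,
        prop_subthreshold_nonsites=sub.p,
        subthreshold_tail_probability=sub.tail_probability,
        boundary_warnings=list(epi.boundary_warnings),
        provenance={
            "config_digest": config.digest(),
            "seed": config.seed,
            "phi": config.phi,
            "n_bins": config.n_bins,
            "grid_resolution": [config.prior.n_gamma, config.prior.n_zeta,
                                config.prior.n_eps],
            "cultepi_version": __version__,
        },
    )
    _check_consistency(summary, sub, binned)
    return summary, binned, epi


def _check_consistency(summary: AnalysisSummary, sub, binned: BinnedCounts) -> None:
    """Internal recomputation guards run after every analysis."""
    from .stats import binomial_tail

    assert abs(
        summary.aic_epidemiological
        - (2 * N_PARAMS["epidemiological"] - 2 * summary.max_log_likelihood)
    ) < 1e-9
    recomputed = binomial_tail(sub.k, sub.n, sub.p)
    assert np.isclose(recomputed, summary.subthreshold_tail_probability,
                      rtol=1e-12, atol=0)
    assert binned.n_sites == summary.n_sites
    assert binned.n_total == summary.n_cells


def run_analysis(config: AnalysisConfig) -> AnalysisSummary:
    """Execute one full analysis from its config; deterministic under the seed."""
    if config.synthetic is not None and config.seed:
        config.synthetic.seed = config.seed
    samples = _load_samples(config)
    summary, _, _ = analyze_samples(samples, config)
    return summary


# ---------------------------------------------------------------------------
# reporting

_ROWS = (
    ("N sites", "n_sites", "{:d}"),
    ("N cells", "n_cells", "{:d}"),
    ("Median density sites", "median_sites", "{:.2f}"),
    ("Median density non-sites", "median_nonsites", "{:.2f}"),
    ("KS D", "ks_d", "{:.2f}"),
    ("KS p", "ks_p", "{:.2g}"),
    ("Mann-Whitney U", "mw_u", "{:.3g}"),
    ("Mann-Whitney p", "mw_p", "{:.2g}"),
    ("Threshold CI 0.025", ("threshold", "q0.025"), "{:.2f}"),
    ("Threshold CI 0.25", ("threshold", "q0.25"), "{:.2f}"),
    ("Threshold CI 0.5", ("threshold", "q0.5"), "{:.2f}"),
    ("Threshold CI 0.75", ("threshold", "q0.75"), "{:.2f}"),
    ("Threshold CI 0.975", ("threshold", "q0.975"), "{:.2f}"),
    ("Log likelihood", "max_log_likelihood", "{:.0f}"),
    ("AIC epidemiological", "aic_epidemiological", "{:.0f}"),
    ("AIC proportional", "aic_proportional", "{:.0f}"),
    ("AIC null", "aic_null", "{:.0f}"),
    ("BF vs proportional", "bf_vs_proportional", "{:.3g}"),
    ("BF vs null", "bf_vs_null", "{:.3g}"),
    ("N sub-threshold sites", "n_subthreshold_sites", "{:d}"),
    ("Prop. sub-threshold non-sites", "prop_subthreshold_nonsites", "{:.2f}"),
    ("P(N or fewer sites)", "subthreshold_tail_probability", "{:.3g}"),
)


def report(summaries: list[AnalysisSummary]) -> tuple[str, str]:
    """Format summaries as a fixed-width table plus its JSON twin.

    Columns follow the input order; the JSON round-trips exactly through
    :meth:`AnalysisSummary.from_dict`.
    """
    names = [s.name for s in summaries]
    header = ["Quantity"] + names
    lines = []
    for label, key, fmt in _ROWS:
        row = [label]
        for s in summaries:
            value = s.threshold[key[1]] if isinstance(key, tuple) else getattr(s, key)
            row.append(fmt.format(value))
        lines.append(row)
    widths = [max(len(r[i]) for r in [header] + lines) for i in range(len(header))]
    def fmt_row(r):
        return "  ".join(c.ljust(w) for c, w in zip(r, widths))
    table = "\n".join([fmt_row(header)] + [fmt_row(r) for r in lines])
    payload = json.dumps([s.to_dict() for s in summaries], indent=2)
    return table, payload


# ---------------------------------------------------------------------------
# plotting

def plot_detection(
    binned: BinnedCounts,
    result: PosteriorResult,
    path=None,
    n_draws: int = 500,
    rng_seed: int = 0,
):
    """Empirical vs modelled detection ratio by density.

    Grey bars show the observed per-bin site fraction; the red line and
    bands the posterior median, interquartile range and 95% interval of
    the model detection ratio; the vertical marker sits at the posterior
    median of the critical density.  Returns the matplotlib figure (and
    writes it to ``path`` when given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import ModelParams, detection_ratio_epidemiological
    from .inference import threshold_quantiles as _tq

    rng = np.random.default_rng(rng_seed)
    flat_post = result.posterior.ravel()
    draws = rng.choice(flat_post.size, size=n_draws, p=flat_post)
    idx = np.unravel_index(draws, result.posterior.shape)

    rho = np.linspace(binned.edges[0] + 1e-9, binned.edges[-1], 300)
    curves = np.empty((n_draws, rho.size))
    for row, (ig, iz, ie) in enumerate(zip(*idx)):
        params = ModelParams(
            gamma=result.param_values[0][ig],
            zeta=result.param_values[1][iz],
            epsilon=result.param_values[2][ie],
            phi=result.phi,
        )
        curves[row] = detection_ratio_epidemiological(rho, params)
    lo95, lo50, med, hi50, hi95 = np.percentile(curves, [2.5, 25, 50, 75, 97.5], axis=0)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    width = np.diff(binned.edges)
    ax.bar(binned.edges[:-1], binned.empirical_ratio(), width=width, align="edge",
           color="0.7", edgecolor="0.4", label="empirical")
    ax.fill_between(rho, lo95, hi95, color="pink", alpha=0.6, label="95% CI")
    ax.fill_between(rho, lo50, hi50, color="palevioletred", alpha=0.6, label="IQR")
    ax.plot(rho, med, color="red", lw=1.5, label="posterior median")
    thr = _tq(result, probs=(0.5,))[0]
    ax.axvline(thr, color="darkred", ls="--", lw=1, label=f"threshold {thr:.1f}")
    ax.set_xlabel("population density (individuals / 100 km$^2$)")
    ax.set_ylabel("detection ratio")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


# ---------------------------------------------------------------------------
# recovery

def recovery_study(
    n_seeds: int = 20,
    n_cells: int = 1_000_000,
    true_params=None,
    prior: PriorGrid | None = None,
    phi: float = 2.0,
    n_bins: int = 35,
    base_seed: int = 0,
) -> dict:
    """Parameter-recovery study on epidemiologically generated landscapes.

    For each seed, generates ``n_cells`` densities and site events under
    the true parameters, runs the grid posterior, and records whether
    the 95% threshold interval covers the true critical density.
    """
    from .model import ModelParams, critical_density

    if true_params is None:
        true_params = ModelParams(gamma=3.5, zeta=1e-5, epsilon=1e-6, phi=phi)
    if prior is None:
        prior = PriorGrid(2.0, 5.0, 1e-7, 1e-4, 0.0, 5e-6)
    rho_star = critical_density(true_params)
    seeds = [int(base_seed + 1000 * (i + 1)) for i in range(n_seeds)]
    runs = []
    for seed in seeds:
        spec = SyntheticSpec(
            n_cells=n_cells, generating_model="epidemiological",
            model_params=true_params, seed=seed,
        )
        grid = generate_landscape(spec)
        samples = generate_sites(grid, spec)
        binned = bin_samples(samples, n_bins=n_bins)
        result = evaluate_grid(binned, prior, phi=phi)
        lo, med, hi = threshold_quantiles(result, probs=(0.025, 0.5, 0.975))
        runs.append({
            "seed": seed,
            "n_sites": samples.n_sites,
            "ci_low": float(lo),
            "median": float(med),
            "ci_high": float(hi),
            "covered": bool(lo <= rho_star <= hi),
        })
    n_covered = sum(r["covered"] for r in runs)
    return {
        "true_rho_star": rho_star,
        "n_seeds": n_seeds,
        "n_cells": n_cells,
        "n_covered": n_covered,
        "coverage": n_covered / n_seeds,
        "median_of_medians": float(np.median([r["median"] for r in runs])),
        "runs": runs,
    }
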