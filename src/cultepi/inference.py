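"""Bayesian grid inference for detection-ratio models.

The likelihood treats every (cell, time-window) sample as an independent
Bernoulli trial whose success probability is the model's detection ratio
at that sample's density.  Samples are binned by density (35 bins by
default) and each bin contributes ``n_site * ln P + n_nonsite * ln(1-P)``
at its representative density.  Posteriors come from exhaustive
evaluation over a parameter grid: gamma and epsilon uniformly spaced,
zeta geometrically spaced (equal node weights, i.e. a log-uniform prior
on zeta).  Model comparison uses the log marginal likelihood — the
prior-weighted mean of the likelihood over the grid — via Bayes factors,
and the Akaike information criterion from the grid maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io import SampleSet
from .model import ModelParams, detection_ratio_epidemiological

__all__ = [
    "BinnedCounts",
    "PriorGrid",
    "PosteriorResult",
    "InferenceError",
    "bin_samples",
    "log_likelihood",
    "evaluate_grid",
    "fit_proportional",
    "fit_null",
    "threshold_quantiles",
    "marginal_likelihood",
    "bayes_factor",
    "aic",
]

THRESHOLD_PROBS = (0.025, 0.25, 0.5, 0.75, 0.975)

#: Free-parameter counts used in AIC: (gamma, zeta, epsilon) for the
#: epidemiological model, (zeta, epsilon) proportional, (k) null.
N_PARAMS = {"epidemiological": 3, "proportional": 2, "null": 1}


class InferenceError(RuntimeError):
    """Raised when a model has zero likelihood everywhere under its prior."""


@dataclass
class BinnedCounts:
    """Per-density-bin site / non-site counts.

    ``edges`` has ``n_bins + 1`` strictly increasing values; the last bin
    is closed on the right so every sample lands in exactly one bin.
    ``rep_density`` is the density at which the model is evaluated for
    the bin (midpoint by default).
    """

    edges: np.ndarray
    site_counts: np.ndarray
    nonsite_counts: np.ndarray
    rep_density: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.site_counts = np.asarray(self.site_counts)
        self.nonsite_counts = np.asarray(self.nonsite_counts)
        self.rep_density = np.asarray(self.rep_density, dtype=float)
        n = self.edges.size - 1
        if self.site_counts.shape != (n,) or self.nonsite_counts.shape != (n,):
            raise ValueError("counts must have one entry per bin")
        if self.rep_density.shape != (n,):
            raise ValueError("rep_density must have one entry per bin")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(self.site_counts < 0) or np.any(self.nonsite_counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def n_sites(self) -> int:
        return int(self.site_counts.sum())

    @property
    def n_total(self) -> int:
        return int(self.site_counts.sum() + self.nonsite_counts.sum())

    def empirical_ratio(self) -> np.ndarray:
        """Observed site fraction per bin (NaN for empty bins)."""
        tot = self.site_counts + self.nonsite_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.site_counts / tot, np.nan)


def bin_samples(
    samples: SampleSet,
    n_bins: int = 35,
    representative: str = "midpoint",
) -> BinnedCounts:
    """Bin samples by density into equal-width bins from 0 to the maximum.

    ``representative`` selects the density reported per bin: ``midpoint``
    (default) or ``mean`` (mean of the samples in the bin, falling back
    to the midpoint for empty bins).
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if representative not in {"midpoint", "mean"}:
        raise ValueError("representative must be 'midpoint' or 'mean'")
    if len(samples) == 0:
        raise ValueError("cannot bin an empty sample set")
    top = float(samples.density.max())
    if top <= 0:
        top = 1.0
    edges = np.linspace(0.0, top, n_bins + 1)
    site_counts, _ = np.histogram(samples.site_densities(), bins=edges)
    nonsite_counts, _ = np.histogram(samples.nonsite_densities(), bins=edges)
    rep = 0.5 * (edges[:-1] + edges[1:])
    if representative == "mean":
        idx = np.clip(np.digitize(samples.density, edges) - 1, 0, n_bins - 1)
        sums = np.bincount(idx, weights=samples.density, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            rep = np.where(counts > 0, sums / np.maximum(counts, 1), rep)
    return BinnedCounts(
        edges=edges, site_counts=site_counts, nonsite_counts=nonsite_counts,
        rep_density=rep,
    )


def _binned_loglik(p: np.ndarray, ns: np.ndarray, nn: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood summed over bins; broadcasts over leading axes.

    Bins with zero sites contribute nothing through ln P (and likewise
    for non-sites through ln(1-P)), so P = 0 or 1 is legal there; a bin
    with sites and P = 0 yields -inf, which simply ranks last.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
        term_s = np.where(ns > 0, ns * log_p, 0.0)
        term_n = np.where(nn > 0, nn * log_q, 0.0)
    return (term_s + term_n).sum(axis=-1)


def log_likelihood(binned: BinnedCounts, model) -> float:
    """Log-likelihood of a detection model against binned counts.

    ``model`` maps density -> P in [0, 1]; it is evaluated at each bin's
    representative density.  Returns -inf when a bin holds sites but the
    model puts P = 0 there (or non-sites with P = 1).
    """
    p = np.asarray(model(binned.rep_density), dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("model returned probabilities outside [0, 1]")
    return float(_binned_loglik(p, binned.site_counts, binned.nonsite_counts))


@dataclass
class PriorGrid:
    """Exhaustive parameter grid for the epidemiological model.

    gamma and epsilon are uniformly spaced between their bounds, zeta
    geometrically spaced; all nodes carry equal prior weight, which makes
    the zeta prior log-uniform.
    """

    gamma_min: float
    gamma_max: float
    zeta_min: float
    zeta_max: float
    eps_min: float = 0.0
    eps_max: float = 0.0
    n_gamma: int = 50
    n_zeta: int = 50
    n_eps: int = 50

    def __post_init__(self):
        if self.gamma_min <= 0:
            # gamma = 0 would put the threshold at zero density; the grid
            # needs positive values for the power law, so nudge the floor.
            self.gamma_min = max(self.gamma_min, 1e-6)
        if self.zeta_min <= 0 or self.zeta_max < self.zeta_min:
            raise ValueError("zeta bounds must be positive and ordered")
        if self.gamma_max < self.gamma_min:
            raise ValueError("gamma bounds ill-ordered")
        if self.eps_max < self.eps_min or self.eps_min < 0:
            raise ValueError("epsilon bounds ill-ordered")

    @property
    def gamma(self) -> np.ndarray:
        return np.linspace(self.gamma_min, self.gamma_max, self.n_gamma)

    @property
    def zeta(self) -> np.ndarray:
        return np.geomspace(self.zeta_min, self.zeta_max, self.n_zeta)

    @property
    def eps(self) -> np.ndarray:
        if self.eps_max == self.eps_min:
            return np.array([self.eps_min])
        return np.linspace(self.eps_min, self.eps_max, self.n_eps)

    def widen(self, param: str) -> "PriorGrid":
        """Return a copy with one octave added on both sides of a bound."""
        g = PriorGrid(**{k: getattr(self, k) for k in (
            "gamma_min", "gamma_max", "zeta_min", "zeta_max",
            "eps_min", "eps_max", "n_gamma", "n_zeta", "n_eps")})
        if param == "gamma":
            g.gamma_min, g.gamma_max = g.gamma_min / 2, g.gamma_max * 2
        elif param == "zeta":
            g.zeta_min, g.zeta_max = g.zeta_min / 2, g.zeta_max * 2
        elif param == "eps":
            g.eps_max = g.eps_max * 2 if g.eps_max > 0 else g.eps_max
        else:
            raise ValueError(f"unknown parameter {param!r}")
        return g


@dataclass
class PosteriorResult:
    """Gridded posterior for one model family.

    ``log_lik`` is the full log-likelihood array (one axis per
    parameter); ``posterior`` the normalised posterior over the same
    grid; marginals each sum to 1.  ``threshold_values`` /
    ``threshold_posterior`` carry the induced discrete posterior of the
    critical density rho* = gamma**phi (epidemiological family only).
    """

    family: str
    param_names: tuple
    param_values: tuple
    log_lik: np.ndarray
    posterior: np.ndarray
    map_params: dict
    max_log_likelihood: float
    marginals: dict
    log_marginal_likelihood: float
    phi: float | None = None
    threshold_values: np.ndarray | None = None
    threshold_posterior: np.ndarray | None = None
    boundary_warnings: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.family]

    def map_model_params(self) -> ModelParams:
        if self.family != "epidemiological":
            raise ValueError("MAP ModelParams only defined for the epidemiological family")
        return ModelParams(
            gamma=self.map_params["gamma"],
            zeta=self.map_params["zeta"],
            epsilon=self.map_params["eps"],
            phi=self.phi,
        )


def _finalize(family, names, values, log_lik, phi=None, weights="equal"):
    flat = log_lik.ravel()
    if not np.any(np.isfinite(flat)):
        raise InferenceError(
            f"{family} model cannot explain the data under the prior "
            "(likelihood is zero at every grid node)"
        )
    n_nodes = flat.size
    if weights == "equal":
        log_ml = float(logsumexp(flat) - np.log(n_nodes))
    elif weights == "trapezoid":
        w = None
        for v in values:
            wv = np.ones(len(v))
            if len(v) > 1:
                wv[0] = wv[-1] = 0.5
            w = wv if w is None else np.multiply.outer(w, wv)
        w = w / w.sum()
        log_ml = float(logsumexp(log_lik, b=w))
    else:
        raise ValueError("weights must be 'equal' or 'trapezoid'")

    log_post = log_lik - logsumexp(flat)
    posterior = np.exp(log_post)
    posterior /= posterior.sum()

    flat_idx = int(np.argmax(flat))  # first maximum: deterministic tie-break
    idx = np.unravel_index(flat_idx, log_lik.shape)
    map_params = {name: float(vals[i]) for name, vals, i in zip(names, values, idx)}

    marginals = {}
    warnings_list = []
    for axis, (name, vals) in enumerate(zip(names, values)):
        other = tuple(a for a in range(log_lik.ndim) if a != axis)
        marg = posterior.sum(axis=other)
        marginals[name] = marg
        if len(vals) > 1:
            for side, pos in (("lower", 0), ("upper", -1)):
                if marg[pos] > 0.01:
                    warnings_list.append(
                        f"{name}: posterior mass {marg[pos]:.3f} at {side} "
                        f"prior bound ({vals[pos]:g})"
                    )

    result = PosteriorResult(
        family=family,
        param_names=tuple(names),
        param_values=tuple(np.asarray(v, dtype=float) for v in values),
        log_lik=log_lik,
        posterior=posterior,
        map_params=map_params,
        max_log_likelihood=float(flat[flat_idx]),
        marginals=marginals,
        log_marginal_likelihood=log_ml,
        phi=phi,
        boundary_warnings=warnings_list,
    )
    if family == "epidemiological":
        gamma = result.param_values[0]
        result.threshold_values = gamma ** phi
        result.threshold_posterior = marginals["gamma"]
    return result


def evaluate_grid(
    binned: BinnedCounts,
    prior: PriorGrid,
    phi: float = 2.0,
    weights: str = "equal",
    auto_widen: int = 0,
) -> PosteriorResult:
    """Exhaustively evaluate the epidemiological model over a prior grid.

    Computes the Bernoulli log-likelihood at every (gamma, zeta, epsilon)
    node, normalises by log-sum-exp, and reports MAP, per-parameter
    marginals, the induced threshold posterior and the log marginal
    likelihood.  When more than 1% of posterior mass sits on a prior
    bound a warning is recorded; with ``auto_widen > 0`` the offending
    bound is widened by one octave (at most ``auto_widen`` times, each
    widening announced via ``warnings.warn``, never silently).
    """
    gamma, zeta, eps = prior.gamma, prior.zeta, prior.eps
    rho = binned.rep_density  # (B,)

    rho_star = gamma[:, None] ** phi
    with np.errstate(divide="ignore"):
        istar = 1.0 - (rho_star / rho[None, :]) ** (1.0 / phi)
    istar = np.where(rho[None, :] <= rho_star, 0.0, istar)  # (Ng, B)
    zr = istar * rho[None, :]

    # P = (1-eps) * zeta * I* rho + eps, on the (gamma, zeta, eps, bin) grid
    p = (
        (1.0 - eps[None, None, :, None])
        * zeta[None, :, None, None]
        * zr[:, None, None, :]
        + eps[None, None, :, None]
    )
    np.clip(p, 0.0, 1.0, out=p)
    log_lik = _binned_loglik(p, binned.site_counts, binned.nonsite_counts)

    result = _finalize(
        "epidemiological", ("gamma", "zeta", "eps"), (gamma, zeta, eps),
        log_lik, phi=phi, weights=weights,
    )
    if result.boundary_warnings and auto_widen > 0:
        for w in result.boundary_warnings:
            warnings.warn(f"widening prior: {w}", stacklevel=2)
        widened = prior
        for name in {w.split(":")[0] for w in result.boundary_warnings}:
            widened = widened.widen(name)
        return evaluate_grid(binned, widened, phi=phi, weights=weights,
                             auto_widen=auto_widen - 1)
    return result


def fit_proportional(
    binned: BinnedCounts,
    zeta_min: float,
    zeta_max: float,
    eps_min: float = 0.0,
    eps_max: float = 0.0,
    n_zeta: int = 50,
    n_eps: int = 50,
    weights: str = "equal",
) -> PosteriorResult:
    """Grid posterior for the proportional model P = zeta*rho + epsilon."""
    zeta = np.geomspace(zeta_min, zeta_max, n_zeta)
    eps = (np.array([eps_min]) if eps_max == eps_min
           else np.linspace(eps_min, eps_max, n_eps))
    rho = binned.rep_density
    p = zeta[:, None, None] * rho[None, None, :] + eps[None, :, None]
    np.clip(p, 0.0, 1.0, out=p)
    log_lik = _binned_loglik(p, binned.site_counts, binned.nonsite_counts)
    return _finalize("proportional", ("zeta", "eps"), (zeta, eps),
                     log_lik, weights=weights)


def fit_null(
    binned: BinnedCounts,
    k_min: float = 1e-8,
    k_max: float = 0.1,
    n_k: int = 200,
    weights: str = "equal",
) -> PosteriorResult:
    """Grid posterior for the density-independent null model P = k."""
    k = np.geomspace(k_min, k_max, n_k)
    p = np.broadcast_to(k[:, None], (n_k, binned.n_bins))
    log_lik = _binned_loglik(p, binned.site_counts, binned.nonsite_counts)
    return _finalize("null", ("k",), (k,), log_lik, weights=weights)


def threshold_quantiles(
    result: PosteriorResult,
    probs=THRESHOLD_PROBS,
) -> np.ndarray:
    """Quantiles of the discrete posterior of the critical density rho*.

    The posterior lives on the grid atoms rho* = gamma**phi.  Quantiles
    interpolate linearly between adjacent atoms by placing each atom at
    the midpoint of its own probability mass on the CDF axis, so a
    symmetric two-atom posterior at {10, 20} has median 15 and a point
    mass returns its atom for every probability.
    """
    if result.threshold_values is None:
        raise ValueError("result carries no threshold posterior")
    x = np.asarray(result.threshold_values, dtype=float)
    w = np.asarray(result.threshold_posterior, dtype=float)
    order = np.argsort(x)
    x, w = x[order], w[order]
    keep = w > 0
    x, w = x[keep], w[keep]
    w = w / w.sum()
    cdf_mid = np.cumsum(w) - 0.5 * w
    return np.interp(np.asarray(probs, dtype=float), cdf_mid, x)


def marginal_likelihood(result: PosteriorResult) -> float:
    """Log marginal likelihood: prior-weighted mean of the likelihood."""
    return result.log_marginal_likelihood


def bayes_factor(log_ml_a: float, log_ml_b: float) -> float:
    """Bayes factor exp(log_ml_a - log_ml_b) of model A over model B."""
    return float(np.exp(log_ml_a - log_ml_b))


def aic(log_likelihood_max: float, n_params: int) -> float:
    """Akaike information criterion 2*k - 2*lnL from a maximised log-likelihood."""
    if n_params < 0:
        raise ValueError("n_params must be nonnegative")
    return 2.0 * n_params - 2.0 * log_likelihood_max
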