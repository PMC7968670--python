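"""Epidemiological model of cultural innovation.

An innovation spreads through a metapopulation of communities like a
disease: communities that hold the skill ("infected", fraction ``I``)
transmit it to those that do not ("susceptible", ``S = 1 - I``) at a rate
that grows with the inter-community encounter rate, and lose it again at a
recovery rate ``gamma``.  Encounter rates are taken to scale as
``rho**(1/phi)`` with population density ``rho`` (``phi = 2`` encodes the
square-root mobility relation observed in hunter-gatherer ethnography).
With the transmission rate normalised to 1, the dynamics are

    dI/dt = rho**(1/phi) * I * (1 - I) - gamma * I

which admits a stable endemic equilibrium only above a critical density
``rho_star = gamma**phi``.  Below that threshold the innovation always
goes extinct; above it, a fraction ``1 - (rho_star/rho)**(1/phi)`` of
communities carry it at equilibrium.

The archaeological observable is not ``I`` but the *detection ratio* P:
the probability that a lattice cell-window is recorded as a site,

    P(rho) = (1 - epsilon) * zeta * I_star(rho) * rho + epsilon

where ``zeta`` collects the joint effects of geology, climate and research
effort, and ``epsilon`` is a baseline error floor.  Two rival observation
models are provided: a proportional model ``P = zeta*rho + epsilon`` and a
density-independent null model ``P = k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "SIRTrajectory",
    "critical_density",
    "endemic_fraction",
    "detection_ratio_epidemiological",
    "detection_ratio_proportional",
    "detection_ratio_null",
    "simulate_sir",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the epidemiological detection model.

    Parameters
    ----------
    gamma : float
        Recovery-to-transmission ratio, in units of density**(1/phi)
        (the transmission rate is normalised to 1).  Sets the critical
        density ``rho_star = gamma**phi``.
    zeta : float
        Per-density-unit detection scale; the probability that an
        innovation-bearing community leaves a detectable trace.
    epsilon : float
        Baseline error / detection floor, in ``[0, 1)``.
    phi : float
        Encounter-rate exponent: encounter rates scale as ``rho**(1/phi)``.
        Default 2 (square-root mobility relation).
    """

    gamma: float
    zeta: float
    epsilon: float = 0.0
    phi: float = 2.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not self.zeta > 0:
            raise ValueError(f"zeta must be positive, got {self.zeta}")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in [0, 1), got {self.epsilon}")
        if not self.phi > 0:
            raise ValueError(f"phi must be positive, got {self.phi}")


@dataclass(frozen=True)
class SIRTrajectory:
    """Time course of the infected (innovation-bearing) fraction."""

    times: np.ndarray
    infected_fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.infected_fraction, dtype=float)
        if t.shape != i.shape:
            raise ValueError("times and infected_fraction must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if i.size and (np.any(i < -1e-12) or np.any(i > 1 + 1e-12)):
            raise ValueError("infected_fraction must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "infected_fraction", np.clip(i, 0.0, 1.0))

    def to_csv(self, path) -> None:
        """Export as two-column CSV (time, infected_fraction)."""
        arr = np.column_stack([self.times, self.infected_fraction])
        np.savetxt(path, arr, delimiter=",", header="time,infected_fraction",
                   comments="")


def critical_density(params: ModelParams) -> float:
    """Critical population density ``rho_star = gamma**phi``.

    Below this density no endemic equilibrium exists and the innovation is
    always lost; above it a stable infected fraction persists.  Units:
    individuals per 100 km^2 (matching the density rasters).
    """
    return float(params.gamma ** params.phi)


def endemic_fraction(rho, params: ModelParams):
    """Equilibrium infected fraction ``I*`` at density ``rho``.

    Zero for ``rho <= rho_star``; ``1 - (rho_star/rho)**(1/phi)`` above.
    Continuous and monotone nondecreasing in ``rho``, approaching 1 as
    ``rho -> inf``.  Accepts scalars or arrays.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise ValueError("density must be nonnegative")
    rho_star = critical_density(params)
    with np.errstate(divide="ignore", over="ignore"):
        frac = 1.0 - (rho_star / rho_arr) ** (1.0 / params.phi)
    out = np.where(rho_arr <= rho_star, 0.0, frac)
    return float(out) if np.isscalar(rho) else out


def detection_ratio_epidemiological(rho, params: ModelParams):
    """Site detection ratio ``P = (1-eps) * zeta * I*(rho) * rho + eps``.

    Clipped to [0, 1] so it can serve directly as a per-cell Bernoulli
    probability.  Equals ``epsilon`` for every density at or below the
    critical threshold.
    """
    rho_arr = np.asarray(rho, dtype=float)
    istar = endemic_fraction(rho_arr, params)
    p = (1.0 - params.epsilon) * params.zeta * istar * rho_arr + params.epsilon
    out = np.clip(p, 0.0, 1.0)
    return float(out) if np.isscalar(rho) else out


def detection_ratio_proportional(rho, zeta: float, epsilon: float = 0.0):
    """Proportional observation model ``P = zeta*rho + epsilon``, clipped to [0, 1]."""
    if not zeta > 0:
        raise ValueError("zeta must be positive")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise ValueError("density must be nonnegative")
    out = np.clip(zeta * rho_arr + epsilon, 0.0, 1.0)
    return float(out) if np.isscalar(rho) else out


def detection_ratio_null(k: float, rho=None):
    """Density-independent null model ``P = k``."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    if rho is None:
        return k
    rho_arr = np.asarray(rho, dtype=float)
    out = np.full_like(rho_arr, k, dtype=float)
    return float(out) if np.isscalar(rho) else out


def simulate_sir(
    rho: float,
    params: ModelParams,
    i0: float = 0.01,
    t_max: float = 50.0,
    dt: float | None = None,
) -> SIRTrajectory:
    """Integrate ``dI/dt = rho**(1/phi) I (1-I) - gamma I`` with fixed-step RK4.

    Parameters
    ----------
    rho : float
        Population density (individuals / 100 km^2).
    i0 : float
        Initial infected fraction, in ``(0, 1]``.
    t_max : float
        Integration horizon, in units of 1/transmission-rate.
    dt : float, optional
        Step size.  Default ``0.01 / gamma``, small relative to the
        fastest time scale.

    Returns
    -------
    SIRTrajectory
        Times and infected fractions; the trajectory stays in [0, 1].
    """
    if rho < 0:
        raise ValueError("density must be nonnegative")
    if not 0.0 < i0 <= 1.0:
        raise ValueError(f"i0 must lie in (0, 1], got {i0}")
    if dt is None:
        dt = 0.01 / params.gamma
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")

    beta_eff = rho ** (1.0 / params.phi)  # encounter-scaled transmission
    gamma = params.gamma

    def deriv(i: float) -> float:
        return beta_eff * i * (1.0 - i) - gamma * i

    n_steps = int(np.ceil(t_max / dt))
    times = np.empty(n_steps + 1)
    infected = np.empty(n_steps + 1)
    times[0], infected[0] = 0.0, i0
    i = i0
    for step in range(1, n_steps + 1):
        k1 = deriv(i)
        k2 = deriv(i + 0.5 * dt * k1)
        k3 = deriv(i + 0.5 * dt * k2)
        k4 = deriv(i + dt * k3)
        i += (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        i = min(max(i, 0.0), 1.0)  # logistic-type ODE cannot leave [0,1]
        times[step] = step * dt
        infected[step] = i
    return SIRTrajectory(times=times, infected_fraction=infected)
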