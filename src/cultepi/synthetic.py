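"""Synthetic population landscapes and site events.

Real inputs to the analysis are a climate/genetics-derived density raster
and a literature-survey site table; neither is needed to exercise the
machinery.  This module fabricates both: a lattice of cells with
densities drawn from a right-skewed law (default lognormal with median
15 individuals / 100 km^2, matching the skewed landscape the real rasters
show), and rare site events drawn per cell as Bernoulli trials with
success probability given by a chosen observation model (epidemiological,
proportional or null).  Because sites are generated by inverting the
observation model, the generator doubles as the ground truth for
parameter-recovery and model-selection studies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import PopulationGrid, SampleSet
from .model import (
    ModelParams,
    detection_ratio_epidemiological,
    detection_ratio_null,
    detection_ratio_proportional,
)

__all__ = [
    "SyntheticSpec",
    "generate_landscape",
    "generate_sites",
    "make_fixture",
    "synthetic_survey_path",
]

_DENSITY_LAWS = {"lognormal", "gamma", "mixture"}
_GENERATORS = {"epidemiological", "proportional", "null"}

#: Default lognormal scale: median exp(mu) = 15 individuals / 100 km^2,
#: sigma = 1 giving a long right tail (90th percentile ~ 54), truncated at
#: a carrying-capacity ceiling of 150 — the upstream density rasters are
#: produced by an NPP -> carrying-capacity map that saturates at a cap K.
DEFAULT_DENSITY_PARAMS = {"mu": float(np.log(15.0)), "sigma": 1.0, "cap": 150.0}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic landscape-plus-sites realisation.

    ``density_law`` is one of ``lognormal`` (params ``mu``, ``sigma``),
    ``gamma`` (``shape``, ``scale``) or ``mixture`` (two lognormals with
    ``weight``, ``mu1``, ``sigma1``, ``mu2``, ``sigma2``).
    ``generating_model`` names the observation model producing the sites;
    ``model_params`` is a :class:`ModelParams` for the epidemiological
    family, or ``{"zeta": ..., "epsilon": ...}`` / ``{"k": ...}`` dicts
    for the rivals.
    """

    n_cells: int = 100_000
    n_steps: int = 1
    density_law: str = "lognormal"
    density_params: dict = field(default_factory=lambda: dict(DEFAULT_DENSITY_PARAMS))
    sea_fraction: float = 0.0
    generating_model: str = "epidemiological"
    model_params: object = field(
        default_factory=lambda: ModelParams(gamma=3.5, zeta=1e-5, epsilon=1e-6, phi=2.0)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0 or self.n_steps <= 0:
            raise ValueError("n_cells and n_steps must be positive")
        if self.density_law not in _DENSITY_LAWS:
            raise ValueError(f"unknown density_law {self.density_law!r}")
        if not 0.0 <= self.sea_fraction < 1.0:
            raise ValueError("sea_fraction must lie in [0, 1)")
        if self.generating_model not in _GENERATORS:
            raise ValueError(f"unknown generating_model {self.generating_model!r}")

    def detection_function(self):
        """Vectorised density -> site probability map of the generating model."""
        if self.generating_model == "epidemiological":
            params = self.model_params
            if not isinstance(params, ModelParams):
                params = ModelParams(**params)
            return lambda rho: detection_ratio_epidemiological(rho, params)
        if self.generating_model == "proportional":
            p = dict(self.model_params)
            return lambda rho: detection_ratio_proportional(
                rho, p["zeta"], p.get("epsilon", 0.0)
            )
        p = dict(self.model_params)
        return lambda rho: detection_ratio_null(p["k"], rho)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.model_params, ModelParams):
            d["model_params"] = dataclasses.asdict(self.model_params)
        return d


def _draw_densities(spec: SyntheticSpec, rng: np.random.Generator, size) -> np.ndarray:
    p = spec.density_params
    if spec.density_law == "lognormal":
        out = rng.lognormal(p["mu"], p["sigma"], size)
    elif spec.density_law == "gamma":
        out = rng.gamma(p["shape"], p["scale"], size)
    else:
        pick = rng.random(size) < p["weight"]
        a = rng.lognormal(p["mu1"], p["sigma1"], size)
        b = rng.lognormal(p["mu2"], p["sigma2"], size)
        out = np.where(pick, a, b)
    cap = p.get("cap")
    if cap is not None:
        np.minimum(out, cap, out=out)
    return out


def generate_landscape(spec: SyntheticSpec) -> PopulationGrid:
    """Draw a population grid from the spec's density law.

    Densities are i.i.d. across cells and windows; ``sea_fraction`` of
    cells are marked missing (NaN) in every window.  Cell centroids are
    scattered uniformly over the non-equatorial latitude bands the real
    analyses use, so geographic filters remain exercisable.  Deterministic
    under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    density = _draw_densities(spec, rng, (spec.n_cells, spec.n_steps))
    sea = rng.random(spec.n_cells) < spec.sea_fraction
    density[sea, :] = np.nan

    # centroids over the two mid-latitude bands, uniform in sin(lat) per band
    north = rng.random(spec.n_cells) < 0.5
    lo = np.where(north, 20.0, -40.0)
    hi = np.where(north, 60.0, -10.0)
    u = rng.random(spec.n_cells)
    sin_lat = np.sin(np.radians(lo)) + u * (np.sin(np.radians(hi)) - np.sin(np.radians(lo)))
    latitude = np.degrees(np.arcsin(sin_lat))
    longitude = rng.uniform(-180.0, 180.0, spec.n_cells)

    time_bp = 25.0 * np.arange(spec.n_steps)
    return PopulationGrid(
        latitude=latitude, longitude=longitude, time_bp=time_bp, density=density
    )


def generate_sites(grid: PopulationGrid, spec: SyntheticSpec) -> SampleSet:
    """Draw site events on a grid under the spec's observation model.

    Each non-missing (cell, window) pair becomes a sample; it is a site
    with probability equal to the generating model's detection ratio at
    that pair's density.  Site draws use a dedicated stream (the spec's
    seed + 1) so the same landscape can host independent site
    realisations.  Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    detect = spec.detection_function()

    mask = ~np.isnan(grid.density)
    idx_cell, idx_step = np.nonzero(mask)
    density = grid.density[mask]
    p = np.asarray(detect(density), dtype=float)
    is_site = rng.random(density.size) < p

    return SampleSet(
        density=density,
        is_site=is_site,
        cell_id=idx_cell,
        time_index=idx_step,
        latitude=grid.latitude[idx_cell],
        longitude=grid.longitude[idx_cell],
        log={
            "generating_model": spec.generating_model,
            "seed": spec.seed,
            "n_samples": int(density.size),
            "n_sites": int(is_site.sum()),
        },
    )


def synthetic_survey_path() -> Path:
    """Path to the bundled *synthetic* raw survey table.

    A fully synthetic stand-in for a 190-record rock-art literature
    survey: coordinates, dates and bookkeeping flags are fabricated, but
    the cleaning arithmetic (190 records reducing to 133 across eight
    exclusion categories) and the date marginals (80 of 133 records
    Holocene, 5 outside the non-equatorial 46,300-year window) follow
    the published survey's printed structure.  Regenerated by
    ``scripts/make_synthetic_survey.py``.
    """
    from importlib import resources

    return Path(str(resources.files("cultepi").joinpath(
        "data", "synthetic_survey_raw.csv")))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture(name: str, out_dir, spec: SyntheticSpec | None = None) -> dict:
    """Write a versioned synthetic dataset (grid + samples + manifest).

    The default recipe is a 100k-cell epidemiological landscape with
    gamma=3.5, zeta=2e-4, epsilon=1e-6, phi=2 — roughly 100 sites, the
    order of magnitude of the real survey.  The JSON manifest records the
    spec, seed and file checksums; regeneration with the same spec is
    byte-identical.
    """
    if spec is None:
        spec = SyntheticSpec(
            n_cells=100_000,
            model_params=ModelParams(gamma=3.5, zeta=2e-4, epsilon=1e-6, phi=2.0),
            seed=20210317,
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = generate_landscape(spec)
    samples = generate_sites(grid, spec)

    grid_path = out / f"{name}_grid.csv"
    samples_path = out / f"{name}_samples.csv"
    grid.to_long_csv(grid_path)
    samples.to_csv(samples_path)

    manifest = {
        "name": name,
        "spec": spec.to_jsonable(),
        "n_samples": len(samples),
        "n_sites": samples.n_sites,
        "files": {
            grid_path.name: _sha256(grid_path),
            samples_path.name: _sha256(samples_path),
        },
    }
    manifest_path = out / f"{name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
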