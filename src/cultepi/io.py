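"""Reading, cleaning and sampling: site tables, density grids, cell samples.

The analysis consumes two inputs: a table of dated rock-art sites
(coordinates, earliest/latest dates in years before 1950, dating
metadata) and a population-density raster on an equal-area lattice of
~100 km cells with 25-year time steps.  This module parses both, cleans
and merges the site table the way a literature survey is deduplicated,
maps sites onto lattice cells by nearest centroid, and produces the
(density, is_site) cell samples that the likelihood machinery consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteRecord",
    "PopulationGrid",
    "FilterSpec",
    "CellSample",
    "SampleSet",
    "SiteTableError",
    "read_site_table",
    "clean_and_merge",
    "lookup_density",
    "nearest_cell",
    "build_samples",
    "region_rectangle_filter",
]

EARTH_RADIUS_KM = 6371.0

_METHODS = {"radiocarbon", "luminescence", "uranium-thorium", "other"}
_DATE_KINDS = {"exact", "minimum", "maximum", "mixed"}


class SiteTableError(ValueError):
    """Raised when site-table rows fail validation; carries per-row messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("site table validation failed:\n" + "\n".join(errors))


@dataclass
class SiteRecord:
    """One dated rock-art site from the literature survey.

    Dates are calendar years before 1950 (BP); ``earliest_date`` is the
    oldest art at the site and anchors the site to a single lattice
    cell-window.  Optional survey bookkeeping flags (``unreliable_source``,
    ``retracted``, ``meets_criteria``, ``modern``) drive the cleaning step.
    """

    name: str
    latitude: float | None
    longitude: float | None
    earliest_date: float
    latest_date: float | None = None
    country: str = ""
    method: str = "other"
    direct: bool = False
    date_kind: str = "exact"
    calibrated_by_authors: bool = False
    disputed: bool = False
    unreliable_source: bool = False
    retracted: bool = False
    meets_criteria: bool = True
    modern: bool = False
    report_year: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            problems.append(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            problems.append(f"longitude {self.longitude} outside [-180, 180]")
        if self.earliest_date is None or math.isnan(self.earliest_date):
            problems.append("earliest_date missing")
        elif self.earliest_date < 0 and not self.modern:
            problems.append(f"earliest_date {self.earliest_date} negative (BP)")
        if (
            self.latest_date is not None
            and self.earliest_date is not None
            and not math.isnan(self.earliest_date)
            and self.latest_date > self.earliest_date
        ):
            problems.append(
                f"latest_date {self.latest_date} after earliest_date "
                f"{self.earliest_date}"
            )
        if self.method not in _METHODS:
            problems.append(f"unknown dating method {self.method!r}")
        if self.date_kind not in _DATE_KINDS:
            problems.append(f"unknown date_kind {self.date_kind!r}")
        return problems

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None

    @property
    def high_quality_date(self) -> bool:
        """Exact, directly dated, and (for radiocarbon) calibrated by the authors."""
        if self.date_kind != "exact" or not self.direct:
            return False
        if self.method == "radiocarbon" and not self.calibrated_by_authors:
            return False
        return True


_BOOL_COLS = (
    "direct",
    "calibrated_by_authors",
    "disputed",
    "unreliable_source",
    "retracted",
    "meets_criteria",
    "modern",
)


def _as_bool(value, default: bool) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes", "y"}:
        return True
    if s in {"0", "false", "f", "no", "n", ""}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def read_site_table(path, on_error: str = "raise"):
    """Read a site table CSV into :class:`SiteRecord` objects.

    The CSV must carry a header with at least ``name``, ``latitude``,
    ``longitude``, ``earliest_date``; the remaining :class:`SiteRecord`
    columns are optional and default sensibly.  Every row is either
    parsed or reported: with ``on_error="raise"`` any invalid row aborts
    with a :class:`SiteTableError` naming the offending rows, with
    ``on_error="report"`` the function returns ``(records, errors)``.
    """
    if on_error not in {"raise", "report"}:
        raise ValueError("on_error must be 'raise' or 'report'")
    df = pd.read_csv(path)
    required = {"name", "earliest_date"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SiteTableError([f"missing required columns: {sorted(missing_cols)}"])

    records: list[SiteRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based + header line
        try:
            lat = row.get("latitude")
            lon = row.get("longitude")
            lat = None if pd.isna(lat) else float(lat)
            lon = None if pd.isna(lon) else float(lon)
            latest = row.get("latest_date")
            latest = None if pd.isna(latest) else float(latest)
            report_year = row.get("report_year")
            report_year = None if pd.isna(report_year) else float(report_year)
            kwargs = {c: _as_bool(row.get(c), c == "meets_criteria") for c in _BOOL_COLS}
            rec = SiteRecord(
                name=str(row["name"]),
                latitude=lat,
                longitude=lon,
                earliest_date=float(row["earliest_date"]),
                latest_date=latest,
                country=str(row.get("country", "") or ""),
                method=str(row.get("method", "other") or "other").strip().lower(),
                date_kind=str(row.get("date_kind", "exact") or "exact").strip().lower(),
                report_year=report_year,
                **kwargs,
            )
        except (ValueError, TypeError, KeyError) as exc:
            errors.append(f"row {rownum}: {exc}")
            continue
        problems = rec.validate()
        if problems:
            errors.extend(f"row {rownum}: {p}" for p in problems)
        else:
            records.append(rec)
    if errors and on_error == "raise":
        raise SiteTableError(errors)
    if on_error == "report":
        return records, errors
    return records


def _intervals_overlap(a: SiteRecord, b: SiteRecord) -> bool:
    a_lo = a.latest_date if a.latest_date is not None else a.earliest_date
    b_lo = b.latest_date if b.latest_date is not None else b.earliest_date
    return a_lo <= b.earliest_date and b_lo <= a.earliest_date


_EXCLUSION_CATEGORIES = (
    "no_coordinates",
    "retracted",
    "unreliable",
    "disputed",
    "criteria",
    "modern",
    "duplicate",
    "merged",
)


def clean_and_merge(
    records: list[SiteRecord],
    exclusions: dict[str, bool] | None = None,
) -> tuple[list[SiteRecord], dict[str, int]]:
    """Clean a raw survey table and merge same-location overlapping records.

    Removal categories (each may be toggled off via ``exclusions``):
    rows without coordinates, retracted sources, unreliable sources,
    disputed dates, inclusion-criteria failures, modern sites, exact
    duplicates, and finally records sharing identical coordinates with
    overlapping [latest, earliest] date intervals, which are merged
    keeping the most recent report's dates.

    Returns ``(clean_records, audit)`` where ``audit`` counts removals per
    category; the counts always sum to ``len(records) - len(clean_records)``.
    """
    enabled = {c: True for c in _EXCLUSION_CATEGORIES}
    if exclusions:
        unknown = set(exclusions) - set(_EXCLUSION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown exclusion categories: {sorted(unknown)}")
        enabled.update(exclusions)

    audit = {c: 0 for c in _EXCLUSION_CATEGORIES}
    current = list(records)

    def drop(predicate, category):
        nonlocal current
        if not enabled[category]:
            return
        kept = [r for r in current if not predicate(r)]
        audit[category] = len(current) - len(kept)
        current = kept

    drop(lambda r: not r.has_coordinates, "no_coordinates")
    drop(lambda r: r.retracted, "retracted")
    drop(lambda r: r.unreliable_source, "unreliable")
    drop(lambda r: r.disputed, "disputed")
    drop(lambda r: not r.meets_criteria, "criteria")
    drop(lambda r: r.modern, "modern")

    if enabled["duplicate"]:
        seen = set()
        kept = []
        for r in current:
            key = (r.name, r.latitude, r.longitude, r.earliest_date, r.latest_date)
            if key in seen:
                audit["duplicate"] += 1
            else:
                seen.add(key)
                kept.append(r)
        current = kept

    if enabled["merged"]:
        by_coord: dict[tuple, list[SiteRecord]] = {}
        for r in current:
            by_coord.setdefault((r.latitude, r.longitude), []).append(r)
        merged: list[SiteRecord] = []
        for group in by_coord.values():
            # union-find over overlapping date intervals within one location
            clusters: list[list[SiteRecord]] = []
            for r in group:
                hits = [c for c in clusters if any(_intervals_overlap(r, o) for o in c)]
                if hits:
                    new = [r] + [o for c in hits for o in c]
                    clusters = [c for c in clusters if c not in hits]
                    clusters.append(new)
                else:
                    clusters.append([r])
            for cluster in clusters:
                rep = max(
                    cluster,
                    key=lambda r: (-math.inf if r.report_year is None else r.report_year),
                )
                audit["merged"] += len(cluster) - 1
                merged.append(rep)
        # preserve input ordering
        order = {id(r): i for i, r in enumerate(current)}
        merged.sort(key=lambda r: order[id(r)])
        current = merged

    assert sum(audit.values()) == len(records) - len(current)
    return current, audit


@dataclass
class PopulationGrid:
    """Population densities on an equal-area lattice over time.

    ``density[i, j]`` is the density (individuals / 100 km^2) of cell
    ``i`` during the 25-year window starting at ``time_bp[j]`` years
    before 1950; sea / no-data cells carry NaN.  The lattice itself is
    consumed, not constructed: only the cell centroids matter, and
    queries resolve to the nearest centroid by great-circle distance.
    """

    latitude: np.ndarray
    longitude: np.ndarray
    time_bp: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        self.time_bp = np.asarray(self.time_bp, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        n_cells, n_steps = len(self.latitude), len(self.time_bp)
        if self.longitude.shape != (n_cells,):
            raise ValueError("latitude and longitude must have equal length")
        if self.density.shape != (n_cells, n_steps):
            raise ValueError(
                f"density must have shape (n_cells, n_steps) = ({n_cells}, {n_steps})"
            )
        if n_steps > 1:
            steps = np.diff(self.time_bp)
            if not np.allclose(steps, steps[0]):
                raise ValueError("time steps must be uniform")
            if steps[0] <= 0:
                raise ValueError("time_bp must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.density < 0):
                raise ValueError("densities must be >= 0 or NaN")

    @property
    def n_cells(self) -> int:
        return len(self.latitude)

    @property
    def n_steps(self) -> int:
        return len(self.time_bp)

    @property
    def step_years(self) -> float:
        return float(self.time_bp[1] - self.time_bp[0]) if self.n_steps > 1 else 25.0

    def time_index(self, date_bp: float) -> int:
        """Index of the time window containing ``date_bp`` (years before 1950)."""
        start = float(self.time_bp[0])
        step = self.step_years
        idx = int(np.floor((date_bp - start) / step))
        if date_bp == start + self.n_steps * step:  # closed upper edge
            idx = self.n_steps - 1
        if not 0 <= idx < self.n_steps:
            raise ValueError(
                f"date {date_bp} BP outside grid span "
                f"[{start}, {start + self.n_steps * step}]"
            )
        return idx

    # --- serialization ---------------------------------------------------

    @classmethod
    def from_long_csv(cls, path) -> "PopulationGrid":
        """Read a long-format CSV with columns cell_id, lat, lon, time_bp, density."""
        df = pd.read_csv(path)
        required = {"cell_id", "lat", "lon", "time_bp", "density"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"grid CSV missing columns: {sorted(missing)}")
        wide = df.pivot(index="cell_id", columns="time_bp", values="density")
        coords = df.drop_duplicates("cell_id").set_index("cell_id")[["lat", "lon"]]
        coords = coords.loc[wide.index]
        return cls(
            latitude=coords["lat"].to_numpy(),
            longitude=coords["lon"].to_numpy(),
            time_bp=wide.columns.to_numpy(dtype=float),
            density=wide.to_numpy(dtype=float),
        )

    def to_long_csv(self, path) -> None:
        n_cells, n_steps = self.density.shape
        df = pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n_cells), n_steps),
                "lat": np.repeat(self.latitude, n_steps),
                "lon": np.repeat(self.longitude, n_steps),
                "time_bp": np.tile(self.time_bp, n_cells),
                "density": self.density.ravel(),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_netcdf(cls, path) -> "PopulationGrid":
        """Read a NetCDF grid (dimensions cell x time; variables latitude,
        longitude, density)."""
        import xarray as xr

        with xr.open_dataset(path) as ds:
            return cls(
                latitude=ds["latitude"].values,
                longitude=ds["longitude"].values,
                time_bp=ds["time_bp"].values,
                density=ds["density"].values,
            )

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {
                "density": (("cell", "time"), self.density),
                "latitude": (("cell",), self.latitude),
                "longitude": (("cell",), self.longitude),
                "time_bp": (("time",), self.time_bp),
            }
        )
        ds.to_netcdf(path, engine="scipy")


def _haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; lat/lon in degrees, arrays broadcast."""
    lat1, lon1 = np.radians(lat1), np.radians(lon1)
    lat2, lon2 = np.radians(lat2), np.radians(lon2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def nearest_cell(grid: PopulationGrid, latitude: float, longitude: float) -> int:
    """Index of the grid cell whose centroid is nearest by great-circle distance."""
    d = _haversine_km(latitude, longitude, grid.latitude, grid.longitude)
    return int(np.argmin(d))


def lookup_density(
    grid: PopulationGrid, latitude: float, longitude: float, date_bp: float
) -> float | None:
    """Density at the nearest cell centroid, in the time window holding ``date_bp``.

    Returns ``None`` for sea / no-data cells; raises ``ValueError`` when
    the date falls outside the grid's time span.
    """
    j = grid.time_index(date_bp)
    i = nearest_cell(grid, latitude, longitude)
    value = grid.density[i, j]
    return None if np.isnan(value) else float(value)


@dataclass(frozen=True)
class CellSample:
    """One (density, is_site) observation unit — the atom of the likelihood."""

    density: float
    is_site: bool
    cell_id: int | None = None
    time_index: int | None = None

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be nonnegative")


@dataclass
class SampleSet:
    """Array-backed collection of cell samples.

    Holds one entry per (cell, time-window) pair that passed the filter;
    optional provenance arrays keep cell/step identity and coordinates so
    that geographic sub-filters can be applied downstream.
    """

    density: np.ndarray
    is_site: np.ndarray
    cell_id: np.ndarray | None = None
    time_index: np.ndarray | None = None
    latitude: np.ndarray | None = None
    longitude: np.ndarray | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        self.is_site = np.asarray(self.is_site, dtype=bool)
        if self.density.shape != self.is_site.shape:
            raise ValueError("density and is_site must have equal length")
        if np.any(self.density < 0):
            raise ValueError("densities must be nonnegative")
        for name in ("cell_id", "time_index", "latitude", "longitude"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.density.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.density.size

    @property
    def n_sites(self) -> int:
        return int(self.is_site.sum())

    @property
    def n_nonsites(self) -> int:
        return int((~self.is_site).sum())

    def site_densities(self) -> np.ndarray:
        return self.density[self.is_site]

    def nonsite_densities(self) -> np.ndarray:
        return self.density[~self.is_site]

    def subset(self, mask: np.ndarray) -> "SampleSet":
        take = lambda a: None if a is None else a[mask]
        return SampleSet(
            density=self.density[mask],
            is_site=self.is_site[mask],
            cell_id=take(self.cell_id),
            time_index=take(self.time_index),
            latitude=take(self.latitude),
            longitude=take(self.longitude),
            log=dict(self.log),
        )

    def to_records(self) -> list[CellSample]:
        cid = self.cell_id if self.cell_id is not None else [None] * len(self)
        tid = self.time_index if self.time_index is not None else [None] * len(self)
        return [
            CellSample(float(d), bool(s), None if c is None else int(c),
                       None if t is None else int(t))
            for d, s, c, t in zip(self.density, self.is_site, cid, tid)
        ]

    def to_csv(self, path) -> None:
        pd.DataFrame({"density": self.density, "is_site": self.is_site.astype(int)}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        df = pd.read_csv(path)
        return cls(density=df["density"].to_numpy(),
                   is_site=df["is_site"].to_numpy().astype(bool))


@dataclass
class FilterSpec:
    """Declarative description of which (cell, window) pairs enter an analysis.

    ``latitude_bands`` is a list of ``[south, north]`` intervals (degrees);
    ``date_range`` is ``[min_bp, max_bp]`` in years before 1950;
    ``rectangle`` an optional ``((nw_lat, nw_lon), (se_lat, se_lon))``
    bounding box; ``quality_only`` restricts sites to exact, direct,
    author-calibrated dates.
    """

    latitude_bands: list[tuple[float, float]] | None = None
    date_range: tuple[float, float] | None = None
    rectangle: tuple[tuple[float, float], tuple[float, float]] | None = None
    include_zero_density: bool = False
    quality_only: bool = False

    def __post_init__(self):
        if self.latitude_bands:
            for south, north in self.latitude_bands:
                if south > north:
                    raise ValueError(f"band [{south}, {north}] ill-ordered")
        if self.date_range and self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range ill-ordered")


def _in_rectangle(lat, lon, nw, se):
    return (se[0] <= lat) & (lat <= nw[0]) & (nw[1] <= lon) & (lon <= se[1])


def build_samples(
    grid: PopulationGrid,
    sites: list[SiteRecord],
    spec: FilterSpec | None = None,
) -> SampleSet:
    """Turn a grid plus a site list into the cell samples of one analysis.

    Every (cell, time-window) pair passing the filter becomes one sample.
    A sample is a site iff some site's *earliest* date falls in that cell
    and window — each site contributes exactly one site-sample, anchoring
    it to a single population density.  Sites that fail the filter or map
    to sea / no-data (or zero-density, when those are excluded) cells are
    flagged, excluded and counted in the returned log.
    """
    spec = spec or FilterSpec()

    cell_ok = np.ones(grid.n_cells, dtype=bool)
    if spec.latitude_bands:
        in_band = np.zeros(grid.n_cells, dtype=bool)
        for south, north in spec.latitude_bands:
            in_band |= (grid.latitude >= south) & (grid.latitude <= north)
        cell_ok &= in_band
    if spec.rectangle:
        nw, se = spec.rectangle
        cell_ok &= _in_rectangle(grid.latitude, grid.longitude, nw, se)

    step_ok = np.ones(grid.n_steps, dtype=bool)
    if spec.date_range:
        lo, hi = spec.date_range
        # a window [t, t+step) is in range when its start date is
        step_ok &= (grid.time_bp >= lo) & (grid.time_bp <= hi)

    mask = cell_ok[:, None] & step_ok[None, :]
    mask &= ~np.isnan(grid.density)
    if not spec.include_zero_density:
        with np.errstate(invalid="ignore"):
            mask &= grid.density > 0

    log = {
        "n_sites_input": len(sites),
        "n_sites_quality_excluded": 0,
        "n_sites_filter_excluded": 0,
        "n_sites_nodata_excluded": 0,
        "n_sites_out_of_time_span": 0,
    }

    is_site = np.zeros(grid.density.shape, dtype=bool)
    for site in sites:
        if spec.quality_only and not site.high_quality_date:
            log["n_sites_quality_excluded"] += 1
            continue
        try:
            j = grid.time_index(site.earliest_date)
        except ValueError:
            log["n_sites_out_of_time_span"] += 1
            continue
        i = nearest_cell(grid, site.latitude, site.longitude)
        if not (cell_ok[i] and step_ok[j]):
            log["n_sites_filter_excluded"] += 1
            continue
        if not mask[i, j]:
            log["n_sites_nodata_excluded"] += 1
            continue
        is_site[i, j] = True

    idx_cell, idx_step = np.nonzero(mask)
    samples = SampleSet(
        density=grid.density[mask],
        is_site=is_site[mask],
        cell_id=idx_cell,
        time_index=idx_step,
        latitude=grid.latitude[idx_cell],
        longitude=grid.longitude[idx_cell],
        log=log,
    )
    samples.log["n_samples"] = len(samples)
    samples.log["n_sites"] = samples.n_sites
    return samples


def region_rectangle_filter(
    samples: SampleSet,
    nw_corner: tuple[float, float],
    se_corner: tuple[float, float],
    invert: bool = False,
) -> SampleSet:
    """Retain samples inside (or, with ``invert``, outside) a lat/lon rectangle.

    A sample is inside when its latitude lies in [SE.lat, NW.lat] and its
    longitude in [NW.lon, SE.lon].
    """
    if samples.latitude is None or samples.longitude is None:
        raise ValueError("samples carry no coordinates; rebuild with provenance")
    inside = _in_rectangle(samples.latitude, samples.longitude, nw_corner, se_corner)
    return samples.subset(~inside if invert else inside)
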