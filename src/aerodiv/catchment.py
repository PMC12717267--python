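"""Back-trajectory summaries, catchment statistics and receptor models.

The monitoring station samples air whose history is reconstructed by
back-trajectories (endpoints: hours back in time, position, height).  This
module bins endpoints into eight cardinal direction sectors and eleven
distance classes, estimates uncertainty of the weekly direction/distance
mass with a moving-block bootstrap, finds the radius enclosing a given
cumulative mass fraction by Monte Carlo, and builds a simplified
quantitative transport bias analysis (SQTBA) source field: grid cells are
scored by trajectory residence time weighted with the observed weekly
concentration series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryEndpointSet",
    "CatchmentSummary",
    "SourceField",
    "DISTANCE_CLASS_EDGES_KM",
    "SECTOR_NAMES",
    "haversine_km",
    "initial_bearing_deg",
    "bin_endpoints",
    "block_bootstrap_se",
    "cumulative_mass_radius",
    "sqtba_field",
    "catchment_covariates",
]

EARTH_RADIUS_KM = 6371.0

#: upper edges of the distance classes (km); mass beyond the last edge is
#: kept in a 12th overflow bucket so binning conserves total weight
DISTANCE_CLASS_EDGES_KM = (2, 5, 10, 20, 31, 50, 100, 180, 310, 520, 860)

SECTOR_NAMES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a spherical Earth (radius 6371 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def initial_bearing_deg(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2) - np.radians(lon1)
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_point(lat, lon, bearing_deg, distance_km):
    """Destination reached from (lat, lon) along a bearing for a distance."""
    delta = np.asarray(distance_km) / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    p1 = np.radians(lat)
    l1 = np.radians(lon)
    p2 = np.arcsin(
        np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(theta)
    )
    l2 = l1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(p1),
        np.cos(delta) - np.sin(p1) * np.sin(p2),
    )
    return np.degrees(p2), (np.degrees(l2) + 540) % 360 - 180


@dataclass
class TrajectoryEndpointSet:
    """Back-trajectory endpoints for each sampled week.

    ``endpoints`` columns: week (label), traj (id within week), hours_back,
    lat, lon, height (m), start_height (m).  ``station`` is (lat, lon).
    """

    endpoints: pd.DataFrame
    station: tuple[float, float]

    def to_tdump(self, path: str | Path) -> None:
        """Write endpoints as HYSPLIT tdump-style whitespace columns."""
        df = self.endpoints
        with open(path, "w") as fh:
            fh.write(f"# station {self.station[0]} {self.station[1]}\n")
            fh.write("week traj hours_back lat lon height start_height\n")
            df.to_csv(fh, sep=" ", index=False, header=False)

    @classmethod
    def from_tdump(cls, path: str | Path) -> "TrajectoryEndpointSet":
        with open(path) as fh:
            header = fh.readline().split()
            station = (float(header[2]), float(header[3]))
            fh.readline()
            df = pd.read_csv(
                fh,
                sep=r"\s+",
                names=["week", "traj", "hours_back", "lat", "lon", "height", "start_height"],
            )
        return cls(endpoints=df, station=station)


@dataclass
class CatchmentSummary:
    """Week x 8 direction x 12 distance-class endpoint mass sums.

    The 12th class collects mass beyond the last configured edge so that
    total binned weight equals total endpoint weight.
    """

    mass: np.ndarray  # (n_weeks, 8, 12)
    weeks: pd.Index
    edges_km: tuple = DISTANCE_CLASS_EDGES_KM

    def __post_init__(self) -> None:
        if (self.mass < 0).any():
            raise ValueError("mass sums must be nonnegative")
        if list(self.edges_km) != sorted(set(self.edges_km)):
            raise ValueError("distance class edges must be strictly increasing")

    def by_distance(self) -> np.ndarray:
        """(n_weeks, 12) mass summed over directions."""
        return self.mass.sum(axis=1)

    def by_direction(self) -> np.ndarray:
        """(n_weeks, 8) mass summed over distance classes."""
        return self.mass.sum(axis=2)


@dataclass
class SourceField:
    """SQTBA concentration field on a lat/lon grid plus a wind rose.

    Cells never visited by a trajectory are NaN (missing), not zero.
    ``wind_rose`` holds the 8-sector residence-weighted concentration,
    normalized so the strongest sector equals 1.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    values: np.ndarray  # (n_lat, n_lon), NaN where unvisited
    wind_rose: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        lat_mid = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        lon_mid = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        pd.DataFrame(self.values, index=lat_mid, columns=lon_mid).to_csv(path)


def _sector_index(bearing_deg: np.ndarray) -> np.ndarray:
    """Sector 0 = N centered at 0 deg, 45-degree sectors clockwise."""
    return (np.floor(((np.asarray(bearing_deg) + 22.5) % 360.0) / 45.0)).astype(int)


def _distance_class(dist_km: np.ndarray, edges) -> np.ndarray:
    """Smallest edge >= distance; beyond the last edge -> overflow class."""
    return np.searchsorted(np.asarray(edges, dtype=float), dist_km, side="left")


def bin_endpoints(
    endpoints: TrajectoryEndpointSet,
    weights: np.ndarray | None = None,
    edges=DISTANCE_CLASS_EDGES_KM,
) -> CatchmentSummary:
    """Sum endpoint weight per week into direction sectors x distance classes.

    Each endpoint is assigned by great-circle distance from the station
    (class = smallest edge at or beyond the distance; farther than the last
    edge goes into the overflow class) and by initial bearing (N sector
    centered at 0 deg, 45-degree sectors).  ``weights`` default to 1 per
    endpoint (residence hours).
    """
    df = endpoints.endpoints
    slat, slon = endpoints.station
    dist = haversine_km(slat, slon, df["lat"].to_numpy(), df["lon"].to_numpy())
    bear = initial_bearing_deg(slat, slon, df["lat"].to_numpy(), df["lon"].to_numpy())
    sec = _sector_index(bear)
    dcl = _distance_class(dist, edges)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)

    weeks = pd.Index(pd.unique(df["week"]))
    widx = weeks.get_indexer(df["week"])
    mass = np.zeros((len(weeks), 8, len(edges) + 1))
    np.add.at(mass, (widx, sec, dcl), w)
    return CatchmentSummary(mass=mass, weeks=weeks, edges_km=tuple(edges))


def block_bootstrap_se(
    summary: CatchmentSummary,
    n_boot: int = 1000,
    block_weeks: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Moving-block bootstrap SE of the per-cell weekly mean mass.

    Resamples whole blocks of ``block_weeks`` consecutive weeks (wrapping
    blocks not used; start positions 0..n-block) to respect the roughly
    monthly autocorrelation of synoptic weather, then reports the standard
    deviation of the resampled means per (direction, distance) cell.
    """
    x = summary.mass
    n = x.shape[0]
    if n < block_weeks:
        raise ValueError("need at least block_weeks weeks")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block_weeks))
    starts_max = n - block_weeks + 1
    means = np.empty((n_boot,) + x.shape[1:])
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        idx = (starts[:, None] + np.arange(block_weeks)[None, :]).ravel()[:n]
        means[b] = x[idx].mean(axis=0)
    return means.std(axis=0, ddof=1)


def cumulative_mass_radius(
    normalized_sums: np.ndarray,
    ses: np.ndarray,
    quantile: float = 0.5,
    n_draws: int = 1000,
    seed: int = 0,
    edges=DISTANCE_CLASS_EDGES_KM,
) -> dict:
    """Monte-Carlo distribution of the radius enclosing ``quantile`` of mass.

    Per draw, distance-class masses are perturbed by Gaussian noise with the
    given SEs (truncated at zero), re-normalized, and the smallest class
    edge at which cumulative mass reaches the quantile is recorded.  Mass in
    the overflow class maps to infinity.  Returns the median and the
    2.5/97.5 percentiles of the radius across draws.
    """
    m = np.asarray(normalized_sums, dtype=float)
    s = np.broadcast_to(np.asarray(ses, dtype=float), m.shape)
    if m.sum() <= 0:
        raise ValueError("all-zero mass vector")
    edge_vals = np.array(list(edges) + [np.inf])
    rng = np.random.default_rng(seed)
    radii = np.empty(n_draws)
    for d in range(n_draws):
        draw = np.clip(m + rng.normal(0.0, 1.0, size=m.shape) * s, 0.0, None)
        if draw.sum() == 0:
            draw = m
        cum = np.cumsum(draw / draw.sum())
        k = int(np.searchsorted(cum, quantile - 1e-12, side="left"))
        radii[d] = edge_vals[min(k, len(edge_vals) - 1)]
    return {
        "median": float(np.median(radii)),
        "ci_low": float(np.percentile(radii, 2.5)),
        "ci_high": float(np.percentile(radii, 97.5)),
        "draws": radii,
    }


def sqtba_field(
    weekly_concentration: pd.Series,
    endpoints: TrajectoryEndpointSet,
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    cell_deg: float = 1.0,
) -> SourceField:
    """Simplified quantitative transport bias analysis source field.

    Cell value = sum_w C_w * tau_w(cell) / sum_w tau_w(cell), where
    tau_w(cell) counts endpoint hours of week w falling in the cell.  Weeks
    present in only one input are excluded.  The wind rose is the
    sector-summed residence-weighted concentration normalized to max 1.
    """
    df = endpoints.endpoints
    conc = weekly_concentration.dropna()
    shared = conc.index.intersection(pd.unique(df["week"]))
    if len(shared) == 0:
        raise ValueError("no shared weeks between concentrations and endpoints")
    df = df[df["week"].isin(shared)]
    cvals = conc.loc[df["week"]].to_numpy(dtype=float)

    lat_edges = np.arange(lat_range[0], lat_range[1] + cell_deg / 2, cell_deg)
    lon_edges = np.arange(lon_range[0], lon_range[1] + cell_deg / 2, cell_deg)
    li = np.digitize(df["lat"].to_numpy(), lat_edges) - 1
    lj = np.digitize(df["lon"].to_numpy(), lon_edges) - 1
    inside = (li >= 0) & (li < len(lat_edges) - 1) & (lj >= 0) & (lj < len(lon_edges) - 1)

    shape = (len(lat_edges) - 1, len(lon_edges) - 1)
    tau = np.zeros(shape)
    ctau = np.zeros(shape)
    np.add.at(tau, (li[inside], lj[inside]), 1.0)
    np.add.at(ctau, (li[inside], lj[inside]), cvals[inside])
    with np.errstate(invalid="ignore"):
        values = np.where(tau > 0, ctau / np.maximum(tau, 1), np.nan)

    slat, slon = endpoints.station
    bear = initial_bearing_deg(slat, slon, df["lat"].to_numpy(), df["lon"].to_numpy())
    sec = _sector_index(bear)
    rose = np.zeros(8)
    rose_tau = np.zeros(8)
    np.add.at(rose, sec, cvals)
    np.add.at(rose_tau, sec, 1.0)
    with np.errstate(invalid="ignore"):
        rose = np.where(rose_tau > 0, rose / np.maximum(rose_tau, 1), 0.0)
    if np.nanmax(rose) > 0:
        rose = rose / np.nanmax(rose)
    return SourceField(
        lat_edges=lat_edges,
        lon_edges=lon_edges,
        values=values,
        wind_rose=pd.Series(rose, index=list(SECTOR_NAMES)),
    )


def catchment_covariates(summary: CatchmentSummary) -> pd.DataFrame:
    """25 weekly covariates describing catchment-area variation.

    8 directions x 3 coarse distance bands (local: classes up to 31 km,
    regional: up to 310 km, distant: beyond) = 24 aggregates, plus total
    weekly mass, all log1p-transformed.  Intended as a regression block for
    the state-space trend models.
    """
    edges = np.array(summary.edges_km)
    local = edges <= 31
    regional = (edges > 31) & (edges <= 310)
    bands = [
        np.concatenate([local, [False]]),
        np.concatenate([regional, [False]]),
        np.concatenate([edges > 310, [True]]),
    ]
    cols = {}
    for d, dname in enumerate(SECTOR_NAMES):
        for b, bname in enumerate(("local", "regional", "distant")):
            cols[f"{dname}_{bname}"] = summary.mass[:, d, bands[b]].sum(axis=1)
    cols["total_mass"] = summary.mass.sum(axis=(1, 2))
    return np.log1p(pd.DataFrame(cols, index=summary.weeks))
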