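"""Synthetic airborne-eDNA study generator with retrievable ground truth.

Emulates the statistical structure the analysis pipeline assumes: genera in
temporal clusters sharing a seasonal-harmonic plus long-term latent trend,
multinomial read sampling with library-size, read-length and filter-batch
biases, spurious "false positive" genera with degraded classification-metric
profiles and far-away occurrence records, directionally biased back-
trajectories, and route x year survey counts coupled to the latent
abundances through route-specific AR(1) noise.

Every generator draws from an rng derived from ``config.seed`` plus a
per-generator constant, so each output is deterministic under a fixed seed
regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catchment import TrajectoryEndpointSet, destination_point
from .trends import SurveySeries
from .compositional import CountMatrix

__all__ = [
    "SyntheticConfig",
    "CommunityTruth",
    "SpikeResult",
    "make_community",
    "sample_reads",
    "spike_false_positives",
    "make_trajectories",
    "make_survey",
]

STATION = (67.84, 20.42)  # boreal monitoring station (lat, lon)

_STREAMS = {
    "community": 11,
    "reads": 22,
    "spike": 33,
    "trajectories": 44,
    "survey": 55,
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Effect sizes follow the phenomena the pipeline must detect: a seasonal
    amplitude of 1.0 log unit, a dominant genus surging from a 40% to an 80%
    community share before declining, spurious genera at roughly 1% of the
    median genuine genus count, and a filter-type batch change partway
    through the series.
    """

    n_genera: int = 300
    n_weeks: int = 300
    start_year: int = 1974
    weeks_per_year: int = 52
    observed_week_mask: bool = False  # non-winter weeks, even years only
    nonwinter_weeks: tuple[int, int] = (16, 47)
    n_clusters: int = 5
    n_harmonics: int = 2
    seasonal_amplitude: float = 1.0  # log units
    noise_sd: float = 0.5  # per-genus AR(1) innovation sd, log units
    noise_ar: float = 0.5
    offset_sd: float = 1.0
    surge: bool = True  # one dominant genus follows a logistic surge-decline
    surge_shares: tuple[float, float, float] = (0.40, 0.80, 0.60)
    library_size_mean: float = 100_000.0
    library_size_dispersion: float = 0.2
    read_length_mean: float = 120.0
    read_length_drift: float = 60.0  # total bp change over the series
    read_length_sd: float = 5.0
    read_length_bias_sd: float = 0.3  # genus-specific log-scale coefficient sd
    batch_change_week: int | None = None  # default: 2/3 through the series
    batch_effect_sd: float = 0.3
    n_spurious_genera: int = 50
    spurious_count_scale: float = 0.01  # vs median genuine weekly count
    trajectory_bias_bearing: float = 180.0
    trajectory_bias_concentration: float = 0.0  # von Mises kappa; 0 = isotropic
    trajectories_per_week: int = 28
    n_survey_routes: int = 3
    survey_ar: float = 0.4
    survey_noise_sd: float = 0.2
    survey_genera: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genera", "n_weeks", "n_clusters", "n_harmonics"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_clusters > self.n_genera:
            raise ValueError("n_clusters may not exceed n_genera")
        if self.n_spurious_genera < 0:
            raise ValueError("n_spurious_genera must be >= 0")
        if self.trajectory_bias_concentration < 0:
            raise ValueError("trajectory bias concentration must be >= 0")
        if self.batch_change_week is None:
            self.batch_change_week = 2 * self.n_weeks // 3
        if not 0 < self.batch_change_week < self.n_weeks:
            raise ValueError("batch_change_week must fall inside the series")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )


@dataclass
class CommunityTruth:
    """Planted community: latent log-abundances and everything that made them."""

    genera: list[str]
    cluster_of: pd.Series  # genus -> cluster id (1..k)
    latent: pd.DataFrame  # genera x weeks, log units
    seasonal_amplitude: pd.Series
    seasonal_phase: pd.Series
    trend_type: pd.Series  # flat | linear | logistic-surge
    surge_genus: str | None
    reference_composition: pd.Series  # mean softmax share over the first era
    week_labels: list[str]
    week_year: np.ndarray
    week_calendar: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.latent.to_numpy()).all():
            raise ValueError("latent series must be finite")
        ids = np.sort(self.cluster_of.unique())
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous from 1")

    def softmax_shares(self) -> pd.DataFrame:
        lam = self.latent.to_numpy()
        lam = lam - lam.max(axis=0, keepdims=True)
        ex = np.exp(lam)
        return pd.DataFrame(
            ex / ex.sum(axis=0, keepdims=True),
            index=self.latent.index,
            columns=self.latent.columns,
        )


def _week_grid(config: SyntheticConfig):
    t = np.arange(config.n_weeks)
    year = config.start_year + t // config.weeks_per_year
    cal = t % config.weeks_per_year + 1
    labels = [f"{y}-W{c:02d}" for y, c in zip(year, cal)]
    return labels, year, cal


def make_community(config: SyntheticConfig) -> CommunityTruth:
    """Draw the latent community: cluster trends, harmonics, offsets, noise.

    Genera in the same cluster share one seasonal + long-term signal and
    differ by a constant offset plus independent AR(1) noise; with zero
    noise, within-cluster latent series are identical up to that offset.
    One designated dominant genus may follow a logistic surge-and-decline in
    community share (computed exactly on the softmax scale).
    """
    rng = config.rng("community")
    labels, year, cal = _week_grid(config)
    t = np.arange(config.n_weeks)
    k = config.n_clusters
    genera = [f"g{i:04d}" for i in range(config.n_genera)]
    cluster_of = pd.Series(
        (np.arange(config.n_genera) % k) + 1, index=genera, name="cluster"
    )

    period = float(config.weeks_per_year)
    trend_cycle = ["flat", "linear"]
    cluster_signal = np.zeros((k, config.n_weeks))
    cluster_amp = np.empty(k)
    cluster_phase = np.empty(k)
    cluster_trend = []
    for c in range(k):
        # the first harmonic carries at least half the seasonal amplitude and
        # its phase is evenly spaced (with jitter) across clusters, so the
        # planted clusters are seasonally distinct; higher harmonics are free
        amps = rng.dirichlet(np.ones(config.n_harmonics)) * config.seasonal_amplitude
        amps[0] = max(amps[0], 0.5 * config.seasonal_amplitude)
        amps *= config.seasonal_amplitude / max(amps.sum(), 1e-12)
        phases = rng.uniform(0, 2 * np.pi, config.n_harmonics)
        phases[0] = 2 * np.pi * c / k + rng.uniform(-np.pi / (2 * k), np.pi / (2 * k))
        sig = np.zeros(config.n_weeks)
        for h in range(config.n_harmonics):
            sig += amps[h] * np.sin(2 * np.pi * (h + 1) * t / period + phases[h])
        trend = trend_cycle[c % len(trend_cycle)]
        if trend == "linear":
            slope = rng.normal(0.0, 1.0) * 1.5 / config.n_weeks
            sig += slope * (t - t.mean())
        cluster_signal[c] = sig
        cluster_amp[c] = amps.sum()
        cluster_phase[c] = phases[0]
        cluster_trend.append(trend)

    offsets = rng.normal(0.0, config.offset_sd, config.n_genera)
    lam = np.empty((config.n_genera, config.n_weeks))
    phi, sd = config.noise_ar, config.noise_sd
    stat_sd = sd / np.sqrt(1 - phi**2) if sd > 0 else 0.0
    for g in range(config.n_genera):
        c = cluster_of.iloc[g] - 1
        eps = np.zeros(config.n_weeks)
        if sd > 0:
            innov = rng.normal(0.0, sd, config.n_weeks)
            eps[0] = rng.normal(0.0, stat_sd)
            for j in range(1, config.n_weeks):
                eps[j] = phi * eps[j - 1] + innov[j]
        elif config.noise_sd == 0:
            rng.normal(0.0, 1.0, config.n_weeks + 1)  # keep stream alignment
        lam[g] = cluster_signal[c] + offsets[g] + eps

    trend_type = pd.Series(
        [cluster_trend[c - 1] for c in cluster_of], index=genera, name="trend"
    )
    surge_genus = None
    if config.surge:
        surge_genus = genera[0]
        s0, s1, s2 = config.surge_shares
        t_rise, t_fall = 0.4 * config.n_weeks, 0.75 * config.n_weeks
        tau = config.n_weeks / 25.0
        share = (
            s0
            + (s1 - s0) / (1 + np.exp(-(t - t_rise) / tau))
            - (s1 - s2) / (1 + np.exp(-(t - t_fall) / tau))
        )
        others = np.delete(lam, 0, axis=0)
        log_e = np.log(np.exp(others - others.max(axis=0)).sum(axis=0)) + others.max(
            axis=0
        )
        lam[0] = log_e + np.log(share / (1 - share))
        trend_type.iloc[0] = "logistic-surge"

    latent = pd.DataFrame(lam, index=genera, columns=labels)
    era = slice(0, max(1, config.n_weeks // 3))
    lam_era = lam[:, era] - lam[:, era].max(axis=0, keepdims=True)
    ref = np.exp(lam_era) / np.exp(lam_era).sum(axis=0, keepdims=True)
    return CommunityTruth(
        genera=genera,
        cluster_of=cluster_of,
        latent=latent,
        seasonal_amplitude=pd.Series(
            cluster_amp[cluster_of.to_numpy() - 1], index=genera
        ),
        seasonal_phase=pd.Series(cluster_phase[cluster_of.to_numpy() - 1], index=genera),
        trend_type=trend_type,
        surge_genus=surge_genus,
        reference_composition=pd.Series(ref.mean(axis=1), index=genera),
        week_labels=labels,
        week_year=year,
        week_calendar=cal,
    )


def _read_length_series(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(config.n_weeks)
    drift = config.read_length_drift * (t / max(config.n_weeks - 1, 1) - 0.5)
    return config.read_length_mean + drift + rng.normal(0, config.read_length_sd, len(t))


def sample_reads(
    truth: CommunityTruth,
    config: SyntheticConfig,
    read_length_bias: pd.Series | None = None,
) -> CountMatrix:
    """Multinomial read sampling with library-size, read-length and batch biases.

    Weekly proportions are softmax(latent + b_g * z_t + batch offset) where
    z_t is the standardized weekly mean read length and the batch offset is
    a genus-specific constant switched on at the filter change week.  The
    library size is a gamma-Poisson (negative binomial) draw per week.
    """
    if truth.latent.shape[1] != config.n_weeks:
        raise ValueError("truth weeks do not match config")
    rng = config.rng("reads")
    rl = _read_length_series(config, rng)
    z = (rl - rl.mean()) / rl.std() if rl.std() > 0 else np.zeros_like(rl)
    if read_length_bias is None:
        b = rng.normal(0.0, config.read_length_bias_sd, config.n_genera)
    else:
        b = read_length_bias.reindex(truth.latent.index).to_numpy()
    batch = rng.normal(0.0, config.batch_effect_sd, config.n_genera)
    after = np.arange(config.n_weeks) >= config.batch_change_week

    lam = truth.latent.to_numpy() + np.outer(b, z) + np.outer(batch, after)
    lam -= lam.max(axis=0, keepdims=True)
    p = np.exp(lam)
    p /= p.sum(axis=0, keepdims=True)

    disp = config.library_size_dispersion
    if disp > 0:
        lam_lib = rng.gamma(1.0 / disp, config.library_size_mean * disp, config.n_weeks)
    else:
        lam_lib = np.full(config.n_weeks, config.library_size_mean)
    lib = rng.poisson(lam_lib).astype(int)
    lib = np.maximum(lib, 1)

    counts = np.empty((config.n_genera, config.n_weeks), dtype=int)
    for w in range(config.n_weeks):
        counts[:, w] = rng.multinomial(lib[w], p[:, w])

    metadata = pd.DataFrame(
        {
            "year": truth.week_year,
            "calendar_week": truth.week_calendar,
            "mean_read_length": rl,
            "filter_type": np.where(after, "HB5773", "CS5.0"),
            "human_read_fraction": np.clip(rng.beta(6, 14, config.n_weeks), 0, 1),
            "total_reads": lib,
        },
        index=pd.Index(truth.week_labels, name="week"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=truth.latent.index, columns=truth.week_labels
        ),
        metadata=metadata,
    )
    if config.observed_week_mask:
        lo, hi = config.nonwinter_weeks
        keep = (
            (metadata["calendar_week"] >= lo)
            & (metadata["calendar_week"] <= hi)
            & (metadata["year"] % 2 == 0)
        )
        cm = CountMatrix(
            counts=cm.counts.loc[:, keep.to_numpy()],
            metadata=cm.metadata.loc[keep],
        )
    return cm


@dataclass
class SpikeResult:
    """Ground truth accompanying spiked false positives."""

    labels: pd.Series  # genus -> "positive" | "negative"
    summaries: pd.DataFrame  # ReadClassSummary-style per-genus metrics
    occurrences: pd.DataFrame  # Darwin-Core-style records


def _make_summaries(
    counts: pd.DataFrame, spurious: set[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Per-genus read-classification summary metrics.

    Genuine genera get concentrated minimizer profiles (high distinct ratio,
    confident reads); spurious genera get degraded ones and sit in lineages
    with more reference sequence and larger genomes.
    """
    rows = []
    for g in counts.index:
        total = int(counts.loc[g].sum())
        spur = g in spurious
        dm_ratio = rng.beta(2, 8) if spur else rng.beta(8, 2)
        total_min = max(1, int(total * rng.uniform(1.2, 1.8)))
        rows.append(
            {
                "genus": g,
                "total_reads": total,
                "clade_reads": total,
                "direct_reads": int(total * (rng.beta(2, 6) if spur else rng.beta(6, 2))),
                "total_minimizers": total_min,
                "distinct_minimizers": max(1, int(total_min * dm_ratio)),
                "mean_confidence": rng.beta(2, 10) if spur else rng.beta(6, 4),
                "lineage_seq_bytes": float(
                    np.exp(rng.normal(22.0 if spur else 19.0, 1.0))
                ),
                "genome_size_proxy": float(
                    np.exp(rng.normal(21.5 if spur else 19.5, 1.0))
                ),
                "kingdom": rng.choice(["Fungi", "Viridiplantae", "Metazoa", "Bacteria"]),
            }
        )
    return pd.DataFrame(rows).set_index("genus")


def _make_occurrences(
    labels: pd.Series, rng: np.random.Generator, start_year: int, end_year: int
) -> pd.DataFrame:
    """Occurrence records: genuine genera near the station, spurious far away."""
    recs = []
    for g, lab in labels.items():
        if lab == "positive":
            n = 4 + rng.poisson(6)
            dist = rng.uniform(1, 35, n)
            bear = rng.uniform(0, 360, n)
        else:
            n = rng.poisson(3)
            dist = rng.uniform(6000, 15000, n)
            bear = rng.uniform(0, 360, n)
        lat, lon = destination_point(STATION[0], STATION[1], bear, dist)
        for i in range(n):
            recs.append(
                {
                    "taxon": g,
                    "decimalLatitude": float(np.atleast_1d(lat)[i]),
                    "decimalLongitude": float(np.atleast_1d(lon)[i]),
                    "year": int(rng.integers(start_year, end_year + 1)),
                }
            )
    return pd.DataFrame(recs, columns=["taxon", "decimalLatitude", "decimalLongitude", "year"])


def spike_false_positives(
    counts: CountMatrix, truth: CommunityTruth, config: SyntheticConfig
) -> tuple[CountMatrix, SpikeResult]:
    """Append spurious genera with the signatures of classification artifacts.

    Spurious genera get low counts (a configured fraction of the median
    genuine weekly count), either sporadic or near-ubiquitous detection,
    degraded classification-metric profiles (low distinct-minimizer ratios,
    low confidence, sequence-rich lineages) and occurrence records placed
    far (> 5000 km) from the station.  Returns the spiked counts and the
    ground-truth labels plus generated summaries/occurrences.
    """
    rng = config.rng("spike")
    c = counts.counts
    n_sp = config.n_spurious_genera
    if n_sp == 0:
        labels = pd.Series("positive", index=c.index, name="label")
        result = SpikeResult(
            labels=labels,
            summaries=_make_summaries(c, set(), rng),
            occurrences=_make_occurrences(
                labels, rng, counts.metadata["year"].min(), counts.metadata["year"].max()
            ),
        )
        return counts, result

    nonzero = c.to_numpy()[c.to_numpy() > 0]
    rate = max(config.spurious_count_scale * np.median(nonzero), 0.5)
    n_weeks = c.shape[1]
    sp_names = [f"spur{i:03d}" for i in range(n_sp)]
    sp_counts = np.zeros((n_sp, n_weeks), dtype=int)
    for i in range(n_sp):
        sporadic = i % 2 == 0
        p_detect = rng.uniform(0.02, 0.10) if sporadic else rng.uniform(0.7, 0.95)
        present = rng.random(n_weeks) < p_detect
        lam = rate * (rng.uniform(2, 6) if sporadic else rng.uniform(0.5, 1.5))
        sp_counts[i, present] = rng.poisson(lam, present.sum()) + 1

    new_counts = pd.concat(
        [c, pd.DataFrame(sp_counts, index=sp_names, columns=c.columns)]
    )
    metadata = counts.metadata.copy()
    metadata["total_reads"] = new_counts.sum(axis=0).to_numpy()
    spiked = CountMatrix(counts=new_counts, metadata=metadata)

    labels = pd.Series(
        ["positive"] * len(c.index) + ["negative"] * n_sp,
        index=new_counts.index,
        name="label",
    )
    result = SpikeResult(
        labels=labels,
        summaries=_make_summaries(new_counts, set(sp_names), rng),
        occurrences=_make_occurrences(
            labels, rng, counts.metadata["year"].min(), counts.metadata["year"].max()
        ),
    )
    return spiked, result


def make_trajectories(config: SyntheticConfig) -> TrajectoryEndpointSet:
    """Back-trajectory endpoints with a configurable directional bias.

    Each trajectory draws a mean bearing from a von Mises distribution
    (concentration 0 = isotropic), a start height from {10, 100, 300, 500} m
    and a duration from {24, 48, 72} h, then random-walks outward from the
    station with hourly endpoints.
    """
    rng = config.rng("trajectories")
    labels, _, _ = _week_grid(config)
    heights = np.array([10.0, 100.0, 300.0, 500.0])
    durations = np.array([24, 48, 72])
    mu = np.radians(config.trajectory_bias_bearing)
    kappa = config.trajectory_bias_concentration

    rows = []
    for w, week in enumerate(labels):
        for j in range(config.trajectories_per_week):
            theta = np.degrees(rng.vonmises(mu, kappa)) % 360.0 if kappa > 0 else rng.uniform(0, 360)
            dur = int(rng.choice(durations))
            h0 = float(rng.choice(heights))
            speed = rng.gamma(4.0, 5.0)  # km/h, mean 20
            bear_walk = theta + np.cumsum(rng.normal(0, 4.0, dur))
            step = np.maximum(speed + rng.normal(0, 3.0, dur), 0.5)
            dist = np.cumsum(step)
            lat, lon = destination_point(STATION[0], STATION[1], bear_walk, dist)
            hts = np.maximum(h0 + np.cumsum(rng.normal(0, 20.0, dur)), 5.0)
            for h in range(dur):
                rows.append(
                    (week, j, h + 1, float(lat[h]), float(lon[h]), float(hts[h]), h0)
                )
    df = pd.DataFrame(
        rows, columns=["week", "traj", "hours_back", "lat", "lon", "height", "start_height"]
    )
    return TrajectoryEndpointSet(endpoints=df, station=STATION)


def make_survey(truth: CommunityTruth, config: SyntheticConfig) -> SurveySeries:
    """Route x year survey counts coupled to the latent genus abundances.

    counts[r, y] = round(exp(base + latent annual mean + route offset +
    AR(1) noise)); the first route's offset is 0.  Ground-truth latent
    annual means are retained for recovery tests.
    """
    rng = config.rng("survey")
    if config.survey_genera > len(truth.latent.index):
        raise ValueError("not enough genera in truth for the survey")
    years = np.unique(truth.week_year)
    annual_all = truth.latent.T.groupby(truth.week_year).mean().T  # genera x years
    # designated survey genera: the ones whose latent actually moves between
    # years (mirrors picking taxa with population dynamics worth surveying)
    genera = annual_all.var(axis=1).nlargest(config.survey_genera).index
    annual = annual_all.loc[genera]

    offsets = np.concatenate([[0.0], rng.normal(0, 0.3, config.n_survey_routes - 1)])
    phi, sd = config.survey_ar, config.survey_noise_sd
    base = 3.5
    rows = []
    for g in genera:
        a = annual.loc[g].to_numpy()
        a = a - a.mean()
        for r in range(config.n_survey_routes):
            e = np.zeros(len(years))
            if sd > 0:
                innov = rng.normal(0, sd, len(years))
                e[0] = rng.normal(0, sd / np.sqrt(1 - phi**2))
                for j in range(1, len(years)):
                    e[j] = phi * e[j - 1] + innov[j]
            cnt = np.round(np.exp(base + a + offsets[r] + e)).astype(int)
            for y, k in zip(years, cnt):
                rows.append((f"route{r + 1}", int(y), g, int(k)))
    counts = pd.DataFrame(rows, columns=["route", "year", "genus", "count"])
    latent_annual = pd.DataFrame(
        annual.to_numpy() - annual.to_numpy().mean(axis=1, keepdims=True) + base,
        index=genera,
        columns=years,
    )
    return SurveySeries(
        counts=counts,
        latent_annual=latent_annual,
        route_offsets=pd.Series(
            offsets, index=[f"route{r + 1}" for r in range(config.n_survey_routes)]
        ),
        ar_coefficient=phi,
    )


def write_survey_csv(survey: SurveySeries, path: str | Path) -> None:
    survey.counts.to_csv(path, index=False)
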