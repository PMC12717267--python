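"""End-to-end orchestration with flat-file handoff between stages.

Every stage reads its inputs from, and writes its outputs to, the run
directory as TSV/CSV/JSON, so any stage can be re-run independently.  A
manifest records the content hash of every output plus the seed and
parameters, making reruns byte-reproducible under a fixed seed.  Stage
order follows the analysis: simulate -> filter -> transform -> detrend ->
cluster -> diversity -> trends -> catchment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblage, catchment, detrend, diversity, synthetic, taxon_filter, trends
from .compositional import (
    CountMatrix,
    CompositionMatrix,
    impute_zeros,
    logratio_transform,
    plr_abundances,
    prevalence_filter,
    variation_matrix,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("aerodiv")

STAGES = (
    "simulate",
    "filter",
    "transform",
    "detrend",
    "cluster",
    "diversity",
    "trends",
    "catchment",
)


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run; unknown keys rejected."""

    outdir: str = "aerodiv_run"
    seed: int = 0
    stages: tuple = STAGES
    synthetic: dict = field(default_factory=dict)
    filter_threshold: float = 0.75
    filter_holdout_fraction: float = 0.13
    max_zero_fraction: float = 2.0 / 3.0
    cluster_k: int = 17
    cluster_linkage: str = "ward"
    diversity_orders: tuple = (1, 2, 3)
    trend_structure: str = "llt"
    trend_iterations: int = 800
    trend_burn: int = 200
    catchment_grid_deg: float = 1.0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        syn_known = {f.name for f in dataclasses.fields(synthetic.SyntheticConfig)}
        syn_unknown = set(cfg.synthetic) - syn_known
        if syn_unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(syn_unknown)}")
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    def synthetic_config(self) -> synthetic.SyntheticConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", self.seed)
        return synthetic.SyntheticConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_counts(out: Path, name: str) -> CountMatrix:
    return CountMatrix.from_tsv(out / f"{name}_counts.tsv", out / f"{name}_metadata.tsv")


def _save_counts(cm: CountMatrix, out: Path, name: str) -> list[Path]:
    p1, p2 = out / f"{name}_counts.tsv", out / f"{name}_metadata.tsv"
    cm.to_tsv(p1, p2)
    return [p1, p2]


def _load_composition(out: Path, name: str) -> CompositionMatrix:
    return CompositionMatrix(
        proportions=pd.read_csv(out / f"{name}.tsv", sep="\t", index_col=0)
    )


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    sc = cfg.synthetic_config()
    truth = synthetic.make_community(sc)
    counts = synthetic.sample_reads(truth, sc)
    spiked, spike = synthetic.spike_false_positives(counts, truth, sc)
    written = _save_counts(spiked, out, "raw")
    for name, df in (
        ("labels", spike.labels.to_frame()),
        ("read_summaries", spike.summaries),
        ("truth_clusters", truth.cluster_of.to_frame()),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t")
        written.append(p)
    p = out / "occurrences.csv"
    spike.occurrences.to_csv(p, index=False)
    written.append(p)
    return written


def _stage_filter(cfg: PipelineConfig, out: Path) -> list[Path]:
    counts = _load_counts(out, "raw")
    summaries = pd.read_csv(out / "read_summaries.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(out / "labels.tsv", sep="\t", index_col=0)["label"]
    comp = impute_zeros(counts)
    plr = plr_abundances(comp)
    features = taxon_filter.build_features(counts, summaries, plr)
    label_set = taxon_filter.LabelSet(
        labels=labels, provenance=pd.Series("synthetic truth", index=labels.index)
    )
    model = taxon_filter.train_filter(
        features,
        label_set,
        holdout_fraction=cfg.filter_holdout_fraction,
        seed=cfg.seed,
        threshold=cfg.filter_threshold,
    )
    calls = taxon_filter.classify_genera(model, features)
    p = out / "filter_calls.tsv"
    calls.to_csv(p, sep="\t")
    metrics = {
        "holdout_precision": model.holdout_precision,
        "holdout_recall": model.holdout_recall,
        "holdout_error_rate": model.holdout_error_rate,
        "n_retained": int(calls["retained"].sum()),
    }
    pm = out / "filter_metrics.json"
    pm.write_text(json.dumps(metrics, indent=1))
    return [p, pm]


def _stage_transform(cfg: PipelineConfig, out: Path) -> list[Path]:
    counts = _load_counts(out, "raw")
    calls_path = out / "filter_calls.tsv"
    if calls_path.exists() and "filter" in cfg.stages:
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        keep = calls.index[calls["retained"]]
        counts = CountMatrix(
            counts=counts.counts.loc[counts.counts.index.intersection(keep)],
            metadata=counts.metadata,
        )
    counts = prevalence_filter(counts, cfg.max_zero_fraction)
    comp = impute_zeros(counts)
    p = out / "composition.tsv"
    comp.proportions.to_csv(p, sep="\t")
    written = [p]
    _save_counts(counts, out, "filtered")
    written += [out / "filtered_counts.tsv", out / "filtered_metadata.tsv"]
    clr = logratio_transform(comp, "clr")
    p2 = out / "clr.tsv"
    clr.coords.to_csv(p2, sep="\t")
    written.append(p2)
    return written


def _stage_detrend(cfg: PipelineConfig, out: Path) -> list[Path]:
    comp = _load_composition(out, "composition")
    meta = pd.read_csv(out / "filtered_metadata.tsv", sep="\t", index_col=0)
    detrended, record = detrend.detrend_pipeline(
        comp,
        meta["mean_read_length"],
        meta[["filter_type", "human_read_fraction"]],
    )
    p = out / "detrended.tsv"
    detrended.proportions.to_csv(p, sep="\t")
    pr = out / "detrend_record.json"
    record.to_json(pr)
    return [p, pr]


def _stage_cluster(cfg: PipelineConfig, out: Path) -> list[Path]:
    comp = _load_composition(out, "detrended")
    vm = variation_matrix(comp)
    k = min(cfg.cluster_k, len(vm) - 1)
    sol = assemblage.cluster_genera(vm, k=k, linkage=cfg.cluster_linkage)
    shares = assemblage.aggregate_clusters(sol, comp)
    p1 = out / "cluster_membership.tsv"
    sol.assignments.to_csv(p1, sep="\t")
    p2 = out / "cluster_shares.tsv"
    shares.to_csv(p2, sep="\t")
    p3 = out / "dendrogram.nwk"
    p3.write_text(sol.to_newick())
    return [p1, p2, p3]


def _stage_diversity(cfg: PipelineConfig, out: Path) -> list[Path]:
    comp = _load_composition(out, "detrended")
    meta = pd.read_csv(out / "filtered_metadata.tsv", sep="\t", index_col=0)
    profile = diversity.partition_diversity(comp, q_list=cfg.diversity_orders)
    written = []
    for name, df in (("alpha", profile.alpha), ("beta", profile.beta), ("gamma", profile.gamma)):
        p = out / f"diversity_{name}.tsv"
        df.to_csv(p, sep="\t")
        written.append(p)
    contribs = diversity.gamma_contributions(comp, profile.reference)
    years = meta["year"]
    span = years.max() - years.min()
    if span >= 2:
        era_a = (int(years.min()), int(years.min() + span // 3))
        era_b = (int(years.max() - span // 3), int(years.max()))
        contrast = diversity.contrast_periods(
            contribs, meta["calendar_week"], years, era_a, era_b
        )
        p = out / "gamma_contrast.tsv"
        contrast.table.to_csv(p, sep="\t")
        written.append(p)
    return written


def _stage_trends(cfg: PipelineConfig, out: Path) -> list[Path]:
    shares = pd.read_csv(out / "cluster_shares.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(out / "filtered_metadata.tsv", sep="\t", index_col=0)
    # most abundant cluster's share, logit-ish log-ratio vs the rest
    top = shares.mean(axis=1).idxmax()
    y = np.log(shares.loc[top] / (1 - shares.loc[top]).clip(lower=1e-9))
    X = trends.seasonal_regressors(np.arange(len(y)))
    X.index = y.index
    spec = trends.SSMSpec(
        trend=cfg.trend_structure,
        regressors=X,
        n_iter=cfg.trend_iterations,
        burn=cfg.trend_burn,
        seed=cfg.seed,
    )
    fit = trends.fit_ssm(pd.Series(y.to_numpy(), index=y.index), spec)
    diag = trends.ssm_diagnostics(fit)
    p1 = out / "trend_median.tsv"
    fit.trend_median.to_csv(p1, sep="\t")
    p2 = out / "trend_diagnostics.json"
    p2.write_text(
        json.dumps(
            {
                k: (v if not isinstance(v, np.ndarray) else v.tolist())
                for k, v in diag.items()
            },
            indent=1,
            default=float,
        )
    )
    return [p1, p2]


def _stage_catchment(cfg: PipelineConfig, out: Path) -> list[Path]:
    sc = cfg.synthetic_config()
    endpoints = synthetic.make_trajectories(sc)
    p0 = out / "trajectories.tdump"
    endpoints.to_tdump(p0)
    summary = catchment.bin_endpoints(endpoints)
    ses = catchment.block_bootstrap_se(summary, n_boot=200, seed=cfg.seed)
    dist_mass = summary.by_distance().mean(axis=0)
    dist_mass = dist_mass / dist_mass.sum()
    dist_se = ses.mean(axis=0)
    radius = catchment.cumulative_mass_radius(
        dist_mass, dist_se / max(summary.mass.sum(), 1), seed=cfg.seed
    )
    clr = pd.read_csv(out / "clr.tsv", sep="\t", index_col=0)
    conc = clr.iloc[:, 0]
    conc.index = clr.index
    shared_weeks = [w for w in conc.index if w in set(endpoints.endpoints["week"])]
    field_ = catchment.sqtba_field(
        conc.loc[shared_weeks],
        endpoints,
        lat_range=(55.0, 80.0),
        lon_range=(0.0, 45.0),
        cell_deg=cfg.catchment_grid_deg,
    )
    p1 = out / "sqtba_field.csv"
    field_.to_csv(p1)
    p2 = out / "catchment_summary.json"
    p2.write_text(
        json.dumps(
            {
                "half_mass_radius_km": radius["median"],
                "radius_ci": [radius["ci_low"], radius["ci_high"]],
                "wind_rose": field_.wind_rose.to_dict(),
            },
            indent=1,
        )
    )
    covs = catchment.catchment_covariates(summary)
    p3 = out / "catchment_covariates.tsv"
    covs.to_csv(p3, sep="\t")
    return [p0, p1, p2, p3]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "transform": _stage_transform,
    "detrend": _stage_detrend,
    "cluster": _stage_cluster,
    "diversity": _stage_diversity,
    "trends": _stage_trends,
    "catchment": _stage_catchment,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the output manifest.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained.  The manifest maps every output file to
    its SHA-256 content hash and records seed and parameters.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "stages"
        },
        "stages_run": [],
        "outputs": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            written = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages_run"].append(stage)
        for p in written:
            manifest["outputs"][p.name] = _sha256(p)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
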