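"""Gradient-boosted filtering of spurious genus detections.

Shotgun read classifiers produce impossible detections (the platypus-in-
every-substrate problem).  Rather than excluding obvious artifacts by hand,
a gradient boosting machine learns to separate genuine from spurious genera
from 31 summary statistics built on the expectation that false positives
have lower read counts, are detected rarely or unusually frequently, carry
degraded per-read classification-quality profiles, and concentrate in
lineages with more reference sequence and larger genomes — plus one-hot
kingdoms and the PLR-transformed weekly abundances.  Training labels are
curated from occurrence records: genera repeatedly observed near the
station are positives; genera never reported within 5000 km, whose family
is not shared with any unsequenced European taxon, are negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import GridSearchCV, train_test_split
from xgboost import XGBClassifier

from .catchment import haversine_km

__all__ = [
    "FeatureTable",
    "LabelSet",
    "FilterModel",
    "FEATURE_STATISTICS",
    "select_stringency",
    "curate_labels",
    "build_features",
    "train_filter",
    "classify_genera",
    "read_kraken_report",
    "read_occurrences",
]

#: the 31 per-genus summary statistics, by family of expectation
FEATURE_STATISTICS = (
    # abundance level
    "total_reads_log",
    "mean_count_log",
    "max_count_log",
    "median_nonzero_count_log",
    "plr_mean",
    "plr_median",
    "plr_max",
    "plr_sd",
    # detection-frequency shape
    "zero_week_fraction",
    "n_detected_weeks",
    "longest_detection_run",
    "longest_absence_run",
    "n_presence_switches",
    "detection_lag1_autocorr",
    "count_dispersion",
    "detection_cv",
    "seasonal_concentration",
    # classification quality
    "mean_confidence",
    "distinct_minimizer_ratio",
    "minimizers_per_read",
    "distinct_minimizers_per_read",
    "direct_clade_ratio",
    "clade_reads_log",
    "direct_reads_log",
    "reads_per_distinct_minimizer_log",
    # database / genome size
    "lineage_seq_bytes_log",
    "genome_size_proxy_log",
    "reads_per_db_byte_log",
    "reads_per_genome_unit_log",
    "db_bytes_per_genome_log",
    "minimizer_db_density_log",
)

#: full-scale search optimum used as the final booster defaults
DEFAULT_BOOSTER_PARAMS = {
    "learning_rate": 0.3,
    "max_depth": 5,
    "min_child_weight": 2,
    "subsample": 0.7,
    "colsample_bytree": 0.4,
    "reg_alpha": 1e-05,
    "gamma": 0.3,
    "reg_lambda": 1.5,
}

#: desk-scale search grid (16 combinations, 5-fold CV)
DEFAULT_GRID = {
    "learning_rate": [0.1, 0.3],
    "max_depth": [3, 5],
    "subsample": [0.7, 1.0],
    "colsample_bytree": [0.4, 0.7],
}


def full_grid() -> dict:
    """The 3^8 = 6561-combination hyperparameter grid (full scale)."""
    return {
        "learning_rate": [0.1, 0.3, 0.5],
        "max_depth": [3, 5, 7],
        "min_child_weight": [1, 2, 4],
        "subsample": [0.5, 0.7, 1.0],
        "colsample_bytree": [0.4, 0.7, 1.0],
        "reg_alpha": [0.0, 1e-5, 1e-2],
        "gamma": [0.0, 0.3, 1.0],
        "reg_lambda": [0.5, 1.0, 1.5],
    }


@dataclass
class FeatureTable:
    """Per-genus features: 31 statistics + kingdom one-hots + PLR weeks."""

    table: pd.DataFrame
    statistic_names: tuple = FEATURE_STATISTICS

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            bad = self.table.columns[self.table.isna().any()].tolist()
            raise ValueError(f"feature table has missing values in {bad}")


@dataclass
class LabelSet:
    """Genus -> positive/negative with per-label provenance."""

    labels: pd.Series
    provenance: pd.Series
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        if not set(self.labels.unique()) <= {"positive", "negative"}:
            raise ValueError("labels must be 'positive' or 'negative'")
        if not self.labels.index.equals(self.provenance.index):
            raise ValueError("every label needs provenance")


@dataclass
class FilterModel:
    """Trained booster with threshold, CV record and holdout metrics."""

    booster: XGBClassifier
    threshold: float
    feature_columns: list[str]
    cv_results: pd.DataFrame | None
    holdout_precision: float
    holdout_recall: float
    holdout_error_rate: float
    holdout_genera: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def select_stringency(
    per_threshold_stats: pd.DataFrame, min_classified_share: float = 0.5
) -> tuple[float, int]:
    """Pick the classification stringency from a stringency-response curve.

    ``per_threshold_stats`` columns: confidence, min_hit_groups,
    frac_classified, frac_regional.  Among settings retaining at least
    ``min_classified_share`` of the maximum total classified fraction, the
    one maximizing the regional fraction wins; ties go to the least
    stringent setting (lowest confidence, then fewest hit groups).
    """
    df = per_threshold_stats
    if len(df) == 0:
        raise ValueError("empty stringency grid")
    required = {"confidence", "min_hit_groups", "frac_classified", "frac_regional"}
    if not required <= set(df.columns):
        raise ValueError(f"grid must have columns {sorted(required)}")
    eligible = df[df["frac_classified"] >= min_classified_share * df["frac_classified"].max()]
    best = eligible.sort_values(
        ["frac_regional", "confidence", "min_hit_groups"],
        ascending=[False, True, True],
    ).iloc[0]
    return float(best["confidence"]), int(best["min_hit_groups"])


def curate_labels(
    occurrences: pd.DataFrame,
    station: tuple[float, float],
    genus_family: pd.Series | None = None,
    unsequenced_european_families: set | None = None,
    genera: pd.Index | None = None,
    study_window: tuple[int, int] | None = None,
    always_positive: tuple = (),
    near_km: float = 40.0,
    near_min_records: int = 4,
    far_km: float = 5000.0,
) -> LabelSet:
    """Curate positive/negative training labels from occurrence records.

    Positive: at least ``near_min_records`` occurrences within ``near_km``
    of the station during the study window (plus configured always-positive
    taxa).  Negative: zero occurrences within ``far_km`` AND no family
    shared with a European taxon lacking a reference genome.  Everything
    else stays unlabeled.  Records without coordinates are skipped and
    counted.  The result is order-independent over records.
    """
    occ = occurrences.copy()
    has_coords = occ["decimalLatitude"].notna() & occ["decimalLongitude"].notna()
    n_skipped = int((~has_coords).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} occurrence records without coordinates")
    occ = occ[has_coords]
    if study_window is not None and "year" in occ.columns:
        occ = occ[(occ["year"] >= study_window[0]) & (occ["year"] <= study_window[1])]

    occ = occ.assign(
        dist_km=haversine_km(
            station[0],
            station[1],
            occ["decimalLatitude"].to_numpy(dtype=float),
            occ["decimalLongitude"].to_numpy(dtype=float),
        )
    )
    near_counts = occ[occ["dist_km"] <= near_km].groupby("taxon").size()
    far_counts = occ[occ["dist_km"] <= far_km].groupby("taxon").size()

    universe = pd.Index(sorted(set(occ["taxon"]).union(always_positive)))
    if genera is not None:
        universe = pd.Index(sorted(set(universe).union(genera)))
    unseq = unsequenced_european_families or set()

    labels, prov = {}, {}
    for g in universe:
        if g in always_positive:
            labels[g], prov[g] = "positive", "always-positive list"
        elif near_counts.get(g, 0) >= near_min_records:
            labels[g] = "positive"
            prov[g] = f">={near_min_records} records within {near_km:g} km"
        elif far_counts.get(g, 0) == 0:
            fam = genus_family.get(g) if genus_family is not None else None
            if fam is not None and fam in unseq:
                continue  # unlabeled: family conflict with unsequenced taxon
            labels[g] = "negative"
            prov[g] = f"no records within {far_km:g} km, no family conflict"
    idx = pd.Index(sorted(labels))
    return LabelSet(
        labels=pd.Series([labels[g] for g in idx], index=idx, name="label"),
        provenance=pd.Series([prov[g] for g in idx], index=idx, name="provenance"),
        n_skipped_records=n_skipped,
    )


def _runs(mask: np.ndarray) -> tuple[int, int, int]:
    """Longest run of True, longest run of False, number of switches."""
    longest_t = longest_f = run = 0
    switches = 0
    prev = None
    for v in mask:
        if v == prev:
            run += 1
        else:
            if prev is not None:
                switches += 1
            run = 1
            prev = v
        if v:
            longest_t = max(longest_t, run)
        else:
            longest_f = max(longest_f, run)
    return longest_t, longest_f, switches


def build_features(
    counts, summaries: pd.DataFrame, plr: pd.DataFrame
) -> FeatureTable:
    """Assemble the 31-statistic feature table plus kingdoms and PLR weeks.

    ``counts`` is a CountMatrix, ``summaries`` a per-genus read-class
    summary (clade/direct reads, minimizers, confidence, database bytes,
    genome proxy, kingdom), ``plr`` the genera x weeks per-genus pivot
    log-ratio abundances.  Raises listing the genera missing a summary.
    """
    c = counts.counts
    missing = c.index.difference(summaries.index)
    if len(missing):
        raise ValueError(f"missing read-class summaries for genera: {list(missing)}")
    missing_plr = c.index.difference(plr.index)
    if len(missing_plr):
        raise ValueError(f"missing PLR rows for genera: {list(missing_plr)}")
    summaries = summaries.loc[c.index]
    plr = plr.loc[c.index]
    cal = counts.metadata["calendar_week"].to_numpy(dtype=float)
    period = max(cal.max(), 52.0)

    rows = []
    for g in c.index:
        x = c.loc[g].to_numpy(dtype=float)
        present = x > 0
        nz = x[present]
        pv = plr.loc[g].to_numpy(dtype=float)
        s = summaries.loc[g]
        run_t, run_f, switches = _runs(present)
        a, b = present[:-1].astype(float), present[1:].astype(float)
        if a.std() > 0 and b.std() > 0:
            lag1 = float(np.corrcoef(a, b)[0, 1])
        else:
            lag1 = 1.0 if present.all() or not present.any() else 0.0
        if present.any():
            ang = 2 * np.pi * cal[present] / period
            resultant = float(
                np.hypot(np.cos(ang).mean(), np.sin(ang).mean())
            )
        else:
            resultant = 0.0
        total = float(s["total_reads"])
        tmin = float(s["total_minimizers"])
        dmin = float(s["distinct_minimizers"])
        bytes_ = float(s["lineage_seq_bytes"])
        genome = float(s["genome_size_proxy"])
        rows.append(
            {
                "total_reads_log": np.log1p(total),
                "mean_count_log": np.log1p(x.mean()),
                "max_count_log": np.log1p(x.max()),
                "median_nonzero_count_log": np.log1p(np.median(nz) if len(nz) else 0.0),
                "plr_mean": pv.mean(),
                "plr_median": float(np.median(pv)),
                "plr_max": pv.max(),
                "plr_sd": pv.std(ddof=0),
                "zero_week_fraction": float((~present).mean()),
                "n_detected_weeks": int(present.sum()),
                "longest_detection_run": run_t,
                "longest_absence_run": run_f,
                "n_presence_switches": switches,
                "detection_lag1_autocorr": lag1,
                "count_dispersion": float(x.var() / x.mean()) if x.mean() > 0 else 0.0,
                "detection_cv": float(nz.std() / nz.mean()) if len(nz) and nz.mean() > 0 else 0.0,
                "seasonal_concentration": resultant,
                "mean_confidence": float(s["mean_confidence"]),
                "distinct_minimizer_ratio": dmin / max(tmin, 1.0),
                "minimizers_per_read": tmin / max(total, 1.0),
                "distinct_minimizers_per_read": dmin / max(total, 1.0),
                "direct_clade_ratio": float(s["direct_reads"]) / max(float(s["clade_reads"]), 1.0),
                "clade_reads_log": np.log1p(float(s["clade_reads"])),
                "direct_reads_log": np.log1p(float(s["direct_reads"])),
                "reads_per_distinct_minimizer_log": np.log1p(total / max(dmin, 1.0)),
                "lineage_seq_bytes_log": np.log1p(bytes_),
                "genome_size_proxy_log": np.log1p(genome),
                "reads_per_db_byte_log": np.log((total + 1.0) / (bytes_ + 1.0)),
                "reads_per_genome_unit_log": np.log((total + 1.0) / (genome + 1.0)),
                "db_bytes_per_genome_log": np.log((bytes_ + 1.0) / (genome + 1.0)),
                "minimizer_db_density_log": np.log((dmin + 1.0) / (bytes_ + 1.0)),
            }
        )
    stats31 = pd.DataFrame(rows, index=c.index)[list(FEATURE_STATISTICS)]

    kingdoms = pd.get_dummies(
        summaries["kingdom"].astype(str), prefix="kingdom", dtype=float
    ) if "kingdom" in summaries.columns else pd.DataFrame(index=c.index)
    plr_cols = plr.copy()
    plr_cols.columns = [f"plr_{w}" for w in plr_cols.columns]
    table = pd.concat([stats31, kingdoms, plr_cols], axis=1)
    return FeatureTable(table=table)


def train_filter(
    features: FeatureTable,
    labels: LabelSet,
    holdout_fraction: float = 0.13,
    seed: int = 0,
    threshold: float = 0.75,
    grid: dict | None = None,
    n_estimators: int = 100,
) -> FilterModel:
    """Grid-searched, cross-validated booster with a stratified holdout.

    A stratified ``holdout_fraction`` of labeled genera is reserved before
    any tuning; 5-fold CV over the grid (desk-scale default; ``full_grid()``
    for the 6561-combination search) picks hyperparameters by error rate;
    the winner refits on all training genera; precision/recall/error come
    from the untouched holdout.
    """
    lab = labels.labels
    common = features.table.index.intersection(lab.index)
    lab = lab.loc[common]
    if lab.nunique() < 2:
        raise ValueError("training labels must contain both classes")
    X = features.table.loc[common].to_numpy(dtype=float)
    y = (lab == "positive").to_numpy(dtype=int)

    idx_train, idx_hold = train_test_split(
        np.arange(len(y)),
        test_size=holdout_fraction,
        stratify=y,
        random_state=seed,
    )
    params = dict(DEFAULT_BOOSTER_PARAMS)
    base = XGBClassifier(
        n_estimators=n_estimators,
        tree_method="hist",
        eval_metric="logloss",
        random_state=seed,
        n_jobs=1,
        **params,
    )
    search = GridSearchCV(
        base,
        grid if grid is not None else DEFAULT_GRID,
        scoring="accuracy",
        cv=5,
        n_jobs=1,
    )
    search.fit(X[idx_train], y[idx_train])
    booster = search.best_estimator_

    prob_hold = booster.predict_proba(X[idx_hold])[:, 1]
    call = (prob_hold >= threshold).astype(int)
    precision = float(precision_score(y[idx_hold], call, zero_division=0))
    recall = float(recall_score(y[idx_hold], call, zero_division=0))
    error = float((call != y[idx_hold]).mean())
    return FilterModel(
        booster=booster,
        threshold=threshold,
        feature_columns=list(features.table.columns),
        cv_results=pd.DataFrame(search.cv_results_),
        holdout_precision=precision,
        holdout_recall=recall,
        holdout_error_rate=error,
        holdout_genera=list(common[idx_hold]),
    )


def classify_genera(model: FilterModel, features: FeatureTable) -> pd.DataFrame:
    """Per-genus probability and binary call (probability >= threshold).

    The feature schema must match training; mismatches raise naming the
    offending columns.
    """
    cols = list(features.table.columns)
    if cols != model.feature_columns:
        extra = sorted(set(cols) - set(model.feature_columns))
        miss = sorted(set(model.feature_columns) - set(cols))
        raise ValueError(
            f"feature schema mismatch; unexpected={extra}, missing={miss}"
        )
    prob = model.booster.predict_proba(features.table.to_numpy(dtype=float))[:, 1]
    return pd.DataFrame(
        {
            "probability": prob,
            "retained": prob >= model.threshold,
        },
        index=features.table.index,
    )


def read_kraken_report(path: str | Path) -> pd.DataFrame:
    """Parse a Kraken2-style report with minimizer columns.

    Expected whitespace-separated columns: percent, clade reads, direct
    reads, total minimizers, distinct minimizers, rank code, taxid, name.
    Returns genus-rank rows indexed by name.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 7)
        if len(parts) < 8:
            continue
        pct, clade, direct, tmin, dmin, rank, taxid, name = parts[:8]
        rows.append(
            {
                "percent": float(pct),
                "clade_reads": int(clade),
                "direct_reads": int(direct),
                "total_minimizers": int(tmin),
                "distinct_minimizers": int(dmin),
                "rank": rank.strip(),
                "taxid": int(taxid),
                "name": name.strip(),
            }
        )
    df = pd.DataFrame(rows)
    return df[df["rank"].str.startswith("G")].set_index("name")


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read a Darwin-Core-style occurrence CSV (taxon, decimalLatitude,
    decimalLongitude, year)."""
    return pd.read_csv(path)


def write_probabilities(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t")
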