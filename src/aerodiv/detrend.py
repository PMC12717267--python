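"""Removal of read-length and filter-batch artifacts from compositions.

Sequencing chemistry changed over the decades, so weekly mean read length is
a technical covariate that leaks into relative abundances (short fragments
classify differently).  Each ILR coordinate is modeled as a Gaussian GLM of
weekly mean read length under log, identity and inverse links; residuals
from the AIC-best link, with the coordinate mean re-added, replace the
coordinate.  The 1996 air-filter manufacturer change and the human-read
fraction are then removed by the conditioning step of a partial redundancy
analysis: CLR coordinates are regressed on the covariates and the residuals
(plus means) are back-transformed.  The whole pipeline is idempotent up to
numerical tolerance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .compositional import (
    CompositionMatrix,
    LogRatioMatrix,
    inverse_logratio,
    logratio_transform,
)

__all__ = [
    "DetrendRecord",
    "fit_readlength_glm",
    "backtransform_detrended",
    "rda_condition",
    "detrend_pipeline",
]

_LINKS = {
    "log": sm.families.links.Log,
    "identity": sm.families.links.Identity,
    "inverse": sm.families.links.InversePower,
}


@dataclass
class DetrendRecord:
    """Per-coordinate link choice and fit statistics, plus conditioning info."""

    per_coordinate: pd.DataFrame  # link, aic, coefficient, skipped variants
    covariates: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_coordinate": self.per_coordinate.to_dict(orient="index"),
            "covariates": self.covariates,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def fit_readlength_glm(
    ilr: LogRatioMatrix, read_lengths: pd.Series, aic_margin: float = 2.0
) -> tuple[DetrendRecord, LogRatioMatrix]:
    """Regress each ILR coordinate on weekly mean read length; keep residuals.

    For every coordinate, Gaussian GLMs with log, identity and inverse links
    are fit and the best by AIC wins, with a parsimony rule: a nonlinear
    link must improve on the identity link by more than ``aic_margin``
    (default 2) to be chosen, so noise-chasing curvature does not displace
    the linear fit.  The winner's residuals plus the coordinate mean replace
    the coordinate.  Link variants that cannot produce a valid fit (e.g. a
    log link forced onto sign-changing responses) are skipped and recorded.
    Re-adding the mean makes the residual coordinate mean equal the original
    mean exactly.
    """
    rl = read_lengths.reindex(ilr.coords.index).to_numpy(dtype=float)
    if not np.isfinite(rl).all():
        raise ValueError("missing read lengths")
    X = sm.add_constant(rl)

    rows = []
    resid = ilr.coords.copy()
    for col in ilr.coords.columns:
        yv = ilr.coords[col].to_numpy(dtype=float)
        fits = {}
        skipped = []
        for name, link_cls in _LINKS.items():
            if name in ("log", "inverse") and (rl <= 0).any():
                skipped.append(name)
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.GLM(
                        yv, X, family=sm.families.Gaussian(link=link_cls())
                    ).fit()
                if not np.isfinite(fit.aic) or not np.isfinite(fit.fittedvalues).all():
                    raise ValueError
            except Exception:
                skipped.append(name)
                continue
            fits[name] = fit
        if not fits:
            raise RuntimeError(f"no link variant converged for coordinate {col}")
        if "identity" in fits:
            name = "identity"
            for alt in ("log", "inverse"):
                if alt in fits and fits[alt].aic < fits[name].aic - aic_margin:
                    name = alt
        else:
            name = min(fits, key=lambda k: fits[k].aic)
        fit = fits[name]
        r = yv - fit.fittedvalues
        resid[col] = r - r.mean() + yv.mean()
        rows.append(
            {
                "coordinate": col,
                "link": name,
                "aic": float(fit.aic),
                "coefficient": float(fit.params[1]),
                "coefficient_se": float(fit.bse[1]),
                "skipped": ",".join(skipped),
            }
        )
    record = DetrendRecord(
        per_coordinate=pd.DataFrame(rows).set_index("coordinate")
    )
    out = LogRatioMatrix(
        kind=ilr.kind,
        coords=resid,
        genera=ilr.genera,
        contrast=ilr.contrast,
        ordering=ilr.ordering,
        pivot=ilr.pivot,
    )
    return record, out


def backtransform_detrended(residual_ilr: LogRatioMatrix) -> CompositionMatrix:
    """Map residual ILR coordinates back to closed, strictly positive
    compositions using the stored basis."""
    return inverse_logratio(residual_ilr)


def _covariate_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = []
    names = []
    for c in covariates.columns:
        v = covariates[c]
        if v.dtype == object or str(v.dtype) == "category":
            dummies = pd.get_dummies(v, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy())
                names.append(dc)
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
    keep_cols, keep_names = [], []
    for arr, name in zip(cols, names):
        if np.std(arr) == 0:
            warnings.warn(f"dropping constant covariate {name!r}")
            continue
        keep_cols.append(arr)
        keep_names.append(name)
    X = np.column_stack(keep_cols) if keep_cols else np.zeros((len(covariates), 0))
    return X, keep_names


def rda_condition(
    comp: CompositionMatrix, covariates: pd.DataFrame, geometry: str = "clr"
) -> CompositionMatrix:
    """Partial-RDA conditioning: remove covariate-explained variation.

    Each response column (CLR coordinates by default; ``geometry='raw'``
    conditions the proportions directly) is regressed by least squares on
    the covariate matrix (filter manufacturer, human-read fraction, ...);
    residuals plus column means are back-transformed.  Residuals are exactly
    orthogonal to the centered covariates.
    """
    covariates = covariates.reindex(comp.weeks)
    X, names = _covariate_design(covariates)
    if X.shape[1] == 0:
        return comp
    Xc = X - X.mean(axis=0)

    if geometry == "clr":
        lr = logratio_transform(comp, "clr")
        Y = lr.coords.to_numpy(dtype=float)
    elif geometry == "raw":
        Y = comp.proportions.to_numpy(dtype=float).T
    else:
        raise ValueError("geometry must be 'clr' or 'raw'")
    mean = Y.mean(axis=0, keepdims=True)
    Yc = Y - mean
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yc - Xc @ coef + mean

    if geometry == "clr":
        out = LogRatioMatrix(
            kind="clr",
            coords=pd.DataFrame(resid, index=comp.weeks, columns=comp.genera),
            genera=comp.genera,
        )
        return inverse_logratio(out)
    resid = np.clip(resid, 1e-12, None).T
    resid = resid / resid.sum(axis=0, keepdims=True)
    return CompositionMatrix(
        proportions=pd.DataFrame(resid, index=comp.genera, columns=comp.weeks)
    )


def detrend_pipeline(
    comp: CompositionMatrix,
    read_lengths: pd.Series,
    covariates: pd.DataFrame,
) -> tuple[CompositionMatrix, DetrendRecord]:
    """Full artifact removal: read-length GLM on ILR, then joint conditioning.

    The link-selected GLM sweep captures any curvature in the read-length
    response.  Its residuals are then residualized against the combined
    linear design (read length + conditioning covariates) in a single
    least-squares projection — the limit of backfitting the two stages.
    Sequential projections alone are not idempotent when read length
    correlates with the filter-change step; the joint projection is, and it
    leaves the output orthogonal to every covariate.
    """
    ilr = logratio_transform(comp, "ilr")
    record, resid = fit_readlength_glm(ilr, read_lengths)

    rl = read_lengths.reindex(comp.weeks).to_numpy(dtype=float)
    X, names = _covariate_design(covariates.reindex(comp.weeks))
    design = np.column_stack([rl.reshape(-1, 1)] + ([X] if X.shape[1] else []))
    design = design - design.mean(axis=0)
    Y = resid.coords.to_numpy(dtype=float)
    mean = Y.mean(axis=0, keepdims=True)
    Yc = Y - mean
    coef, *_ = np.linalg.lstsq(design, Yc, rcond=None)
    out_coords = pd.DataFrame(
        Yc - design @ coef + mean, index=resid.coords.index, columns=resid.coords.columns
    )
    conditioned = inverse_logratio(
        LogRatioMatrix(
            kind=resid.kind,
            coords=out_coords,
            genera=resid.genera,
            contrast=resid.contrast,
            ordering=resid.ordering,
            pivot=resid.pivot,
        )
    )
    record.covariates = ["mean_read_length"] + names
    return conditioned, record
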