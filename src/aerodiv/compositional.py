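"""Zero handling and log-ratio geometry for weekly genus count tables.

Weekly read counts are compositional: only the relative abundances carry
information, because total library size is an artifact of sequencing effort.
All downstream stages therefore work in log-ratio coordinates.  This module
provides the containers (:class:`CountMatrix`, :class:`CompositionMatrix`,
:class:`LogRatioMatrix`), prevalence filtering, Bayesian-multiplicative zero
replacement, the CLR/ILR/PLR transforms with stored (hence invertible) bases,
and the pairwise log-ratio variation matrix used for temporal clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "CompositionMatrix",
    "LogRatioMatrix",
    "relative_abundance",
    "prevalence_filter",
    "impute_zeros",
    "logratio_transform",
    "inverse_logratio",
    "variation_matrix",
    "pivot_basis",
]

TransformKind = Literal["clr", "ilr", "plr"]

#: metadata columns a CountMatrix is expected to carry (one row per week)
METADATA_COLUMNS = (
    "year",
    "calendar_week",
    "mean_read_length",
    "filter_type",
    "human_read_fraction",
    "total_reads",
)


@dataclass
class CountMatrix:
    """Genus x week nonnegative read counts plus per-week metadata.

    ``counts`` has genera as rows and ISO-week labels (e.g. ``1974-W23``) as
    columns.  ``metadata`` is indexed by the same week labels.  ``taxonomy``
    (optional) is indexed by genus with rank columns kingdom..genus.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if not self.counts.columns.equals(self.metadata.index):
            raise ValueError("metadata rows must match week columns")
        if self.counts.index.has_duplicates:
            raise ValueError("genus ids must be unique")

    @property
    def genera(self) -> pd.Index:
        return self.counts.index

    @property
    def weeks(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        metadata_path: str | Path,
        taxonomy_path: str | Path | None = None,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        taxonomy = (
            pd.read_csv(taxonomy_path, sep="\t", index_col=0)
            if taxonomy_path is not None
            else None
        )
        return cls(counts=counts, metadata=metadata, taxonomy=taxonomy)


@dataclass
class CompositionMatrix:
    """Strictly positive weekly relative abundances (genera x weeks).

    ``imputed`` records which cells were zero-replaced and the value used,
    as a long DataFrame with columns (genus, week, value).
    """

    proportions: pd.DataFrame
    imputed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["genus", "week", "value"])
    )

    def __post_init__(self) -> None:
        x = self.proportions.to_numpy()
        if (x <= 0).any():
            raise ValueError("composition entries must be strictly positive")
        if not np.allclose(x.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("weekly compositions must close to 1")

    @property
    def genera(self) -> pd.Index:
        return self.proportions.index

    @property
    def weeks(self) -> pd.Index:
        return self.proportions.columns


@dataclass
class LogRatioMatrix:
    """Log-ratio coordinates (weeks x D for CLR, weeks x D-1 for ILR/PLR).

    The basis (genus ordering defining the sequential binary partition, and
    the contrast matrix) is stored so every transform is invertible.
    """

    kind: TransformKind
    coords: pd.DataFrame  # weeks x coordinates
    genera: pd.Index
    contrast: np.ndarray | None = None  # D x (D-1), None for CLR
    ordering: list[str] | None = None  # SBP / pivot ordering of genera
    pivot: str | None = None

    def basis_to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "genera": list(map(str, self.genera)),
            "ordering": self.ordering,
            "pivot": self.pivot,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def relative_abundance(counts: CountMatrix) -> pd.DataFrame:
    """Weekly proportions: reads assigned to a genus over total reads that week.

    Zeros are preserved; an all-zero week raises, naming the week.
    """
    c = counts.counts
    totals = c.sum(axis=0)
    dead = totals.index[totals == 0]
    if len(dead):
        raise ValueError(f"weeks with zero total reads: {list(dead)}")
    return c / totals


def prevalence_filter(
    counts: CountMatrix, max_zero_fraction: float = 2.0 / 3.0
) -> CountMatrix:
    """Drop genera absent in at least ``max_zero_fraction`` of the weeks.

    A genus is retained iff its zero-week fraction is strictly below the
    threshold (a genus at exactly 2/3 zero weeks is removed).  Genus order
    is preserved.
    """
    if not 0 < max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    zero_frac = (counts.counts == 0).mean(axis=1)
    keep = zero_frac < max_zero_fraction
    if not keep.any():
        raise ValueError("prevalence filter removed every genus")
    taxonomy = (
        counts.taxonomy.loc[counts.genera[keep]] if counts.taxonomy is not None else None
    )
    return CountMatrix(
        counts=counts.counts.loc[keep],
        metadata=counts.metadata,
        taxonomy=taxonomy,
    )


def impute_zeros(counts: CountMatrix, prior_mass: float = 0.5) -> CompositionMatrix:
    """Geometric Bayesian-multiplicative replacement of count zeros.

    Each week is treated as a multinomial draw; zero cells are replaced by
    the posterior-mean Dirichlet estimate under a prior whose mean ``t`` is
    the (normalized) genus-wise geometric mean of the positive proportions
    across weeks — the geometric prior variant — with total prior strength
    ``s = D * prior_mass``.  For a week with library size ``n`` a zero cell
    ``j`` becomes ``t_j * s / (n + s)``.  Nonzero cells are then shrunk by a
    common multiplicative factor so the week re-closes to 1, which preserves
    all ratios (and hence rankings) among observed parts.  Any replacement
    at or above the week's smallest observed proportion is pulled down to
    0.65 times that minimum before re-closure.
    """
    props = relative_abundance(counts)
    x = props.to_numpy(dtype=float)
    n_tot = counts.counts.sum(axis=0).to_numpy(dtype=float)
    d, w = x.shape

    # geometric-mean prior over genera, from positive proportions
    with np.errstate(divide="ignore"):
        logx = np.where(x > 0, np.log(x), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # genera with no detections
        gmean = np.exp(np.nanmean(logx, axis=1))
    gmean = np.where(np.isfinite(gmean), gmean, np.nanmin(gmean[np.isfinite(gmean)]))
    t = gmean / gmean.sum()

    s = d * prior_mass
    out = x.copy()
    records: list[tuple[str, str, float]] = []
    for k in range(w):
        col = x[:, k]
        zero = col == 0
        if not zero.any():
            continue
        if zero.all():
            raise ValueError(f"week {props.columns[k]} has no nonzero counts")
        repl = t[zero] * s / (n_tot[k] + s)
        min_obs = col[~zero].min()
        repl = np.where(repl >= min_obs, 0.65 * min_obs, repl)
        shrink = 1.0 - repl.sum()
        out[zero, k] = repl
        out[~zero, k] = col[~zero] * shrink
        for g, v in zip(props.index[zero], repl):
            records.append((g, props.columns[k], float(v)))

    return CompositionMatrix(
        proportions=pd.DataFrame(out, index=props.index, columns=props.columns),
        imputed=pd.DataFrame(records, columns=["genus", "week", "value"]),
    )


def pivot_basis(order_idx: np.ndarray, d: int) -> np.ndarray:
    """Contrast matrix of the pivot sequential binary partition.

    ``order_idx[j]`` is the genus (row) index occupying position j of the
    ordering.  Coordinate j balances genus order_idx[j] against all genera
    later in the ordering; columns are orthonormal w.r.t. the CLR inner
    product, so ``coords = log(x) @ V`` and ``clr = coords @ V.T``.
    """
    v = np.zeros((d, d - 1))
    for j in range(d - 1):
        r = d - j - 1  # number of parts in the denominator group
        v[order_idx[j], j] = np.sqrt(r / (r + 1))
        v[order_idx[j + 1 :], j] = -1.0 / np.sqrt(r * (r + 1))
    return v


def _default_ordering(comp: CompositionMatrix, pivot: str | None) -> list[str]:
    mean_ab = comp.proportions.mean(axis=1).sort_values(ascending=False)
    order = list(mean_ab.index)
    if pivot is not None:
        if pivot not in comp.genera:
            raise ValueError(f"pivot genus {pivot!r} not present")
        order.remove(pivot)
        order.insert(0, pivot)
    return order


def logratio_transform(
    comp: CompositionMatrix,
    kind: TransformKind = "clr",
    ordering: Sequence[str] | None = None,
    pivot: str | None = None,
) -> LogRatioMatrix:
    """CLR, ILR or PLR transform of a strictly positive composition.

    CLR:  clr_j = ln x_j - mean_k ln x_k  (weeks x D, rows sum to 0).
    ILR:  orthonormal balances of a sequential binary partition; the default
    partition is the pivot ordering by descending mean abundance.
    PLR:  the ILR whose ordering puts the pivot genus first, so the first
    coordinate is sqrt((D-1)/D) * ln(x_pivot / gmean(others)).
    """
    kind = kind.lower()  # type: ignore[assignment]
    x = comp.proportions.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("log-ratio transforms require strictly positive input")
    logx = np.log(x).T  # weeks x D
    clr = logx - logx.mean(axis=1, keepdims=True)

    if kind == "clr":
        coords = pd.DataFrame(clr, index=comp.weeks, columns=comp.genera)
        return LogRatioMatrix(kind="clr", coords=coords, genera=comp.genera)

    if kind == "plr" and pivot is None:
        raise ValueError("PLR requires a pivot genus")
    if kind not in ("ilr", "plr"):
        raise ValueError(f"unknown transform kind {kind!r}")

    order = list(ordering) if ordering is not None else _default_ordering(comp, pivot)
    if set(order) != set(comp.genera):
        raise ValueError("ordering must be a permutation of the genera")
    pos = {g: i for i, g in enumerate(comp.genera)}
    order_idx = np.array([pos[g] for g in order])
    v = pivot_basis(order_idx, len(order))
    coords = pd.DataFrame(
        clr @ v,
        index=comp.weeks,
        columns=[f"z{j + 1}" for j in range(v.shape[1])],
    )
    return LogRatioMatrix(
        kind=kind,
        coords=coords,
        genera=comp.genera,
        contrast=v,
        ordering=order,
        pivot=pivot if kind == "plr" else None,
    )


def inverse_logratio(lr: LogRatioMatrix) -> CompositionMatrix:
    """Invert a log-ratio matrix back to closed compositions (softmax)."""
    z = lr.coords.to_numpy(dtype=float)
    if lr.kind == "clr":
        logx = z
    elif lr.kind in ("ilr", "plr"):
        if lr.contrast is None:
            raise ValueError("basis missing; cannot invert")
        logx = z @ lr.contrast.T
    else:
        raise ValueError(f"unknown transform kind {lr.kind!r}")
    logx = logx - logx.max(axis=1, keepdims=True)
    ex = np.exp(logx)
    props = (ex / ex.sum(axis=1, keepdims=True)).T  # genera x weeks
    return CompositionMatrix(
        proportions=pd.DataFrame(props, index=lr.genera, columns=lr.coords.index)
    )


def plr_abundances(comp: CompositionMatrix) -> pd.DataFrame:
    """Per-genus pivot coordinate for every genus (genera x weeks).

    Row g is sqrt((D-1)/D) * ln(x_g / gmean(others)), i.e. the first PLR
    coordinate with g as pivot; equal to sqrt(D/(D-1)) * CLR_g.
    """
    d = len(comp.genera)
    clr = logratio_transform(comp, "clr").coords.to_numpy().T
    return pd.DataFrame(
        np.sqrt(d / (d - 1.0)) * clr, index=comp.genera, columns=comp.weeks
    )


def variation_matrix(comp: CompositionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Genus x genus matrix of var(ln(x_i / x_j)) across weeks.

    Symmetric with zero diagonal; invariant to re-closure of the weeks since
    ratios cancel any weekly total.  Uses the unbiased (n-1) estimator.
    """
    x = comp.proportions.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("variation matrix needs at least 3 weeks")
    logx = np.log(x)
    cov = np.cov(logx, ddof=ddof)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2 * cov
    np.fill_diagonal(t, 0.0)
    t = np.maximum(t, 0.0)
    return pd.DataFrame(t, index=comp.genera, columns=comp.genera)
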