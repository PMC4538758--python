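"""Two-channel microarray preprocessing.

Turns probe-level Cy3/Cy5 intensities into the analysis-ready gene x sample
log-ratio matrix.  The canonical stage order is

    (optional lowess) -> background filter -> ratio orientation
    -> missing-data filter -> KNN imputation -> probe collapsing
    -> gene-wise median centering

Each :class:`ExpressionMatrix` carries a ``stage`` marker and the stage
functions refuse to run out of order, so a matrix that reaches the analysis
modules is guaranteed to have passed through the whole chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

log = logging.getLogger(__name__)

__all__ = [
    "PipelineOrderError",
    "ProbeMatrix",
    "ExpressionMatrix",
    "lowess_normalize",
    "filter_background",
    "orient_ratios",
    "probe_to_expression",
    "filter_missing",
    "knn_impute",
    "collapse_probes",
    "median_center",
    "preprocess_pipeline",
]

# Ratio orientation flags: raw scanner output is log2(Cy5/Cy3); analysis is
# done on log2(Cy3/Cy5), i.e. every value negated once.
CY5_OVER_CY3 = "Cy5/Cy3"
CY3_OVER_CY5 = "Cy3/Cy5"

_STAGES = ("raw", "missing_filtered", "imputed", "collapsed", "centered")


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was invoked out of its canonical order."""


@dataclass
class ProbeMatrix:
    """Probe-level two-channel data.

    All frames are probe x sample with identical indices/columns.  ``log_ratio``
    holds log2 channel ratios in the orientation named by ``orientation``.
    Background-filter failures appear as NaN in ``log_ratio``.
    """

    cy3: pd.DataFrame
    cy5: pd.DataFrame
    cy3_bg: pd.DataFrame
    cy5_bg: pd.DataFrame
    log_ratio: pd.DataFrame
    annotation: pd.Series  # probe id -> gene symbol
    orientation: str = CY5_OVER_CY3
    background_filtered: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in (CY5_OVER_CY3, CY3_OVER_CY5):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        shape = self.log_ratio.shape
        for name in ("cy3", "cy5", "cy3_bg", "cy5_bg"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape differs from log_ratio")

    @property
    def probe_ids(self) -> pd.Index:
        return self.log_ratio.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.log_ratio.columns


@dataclass
class ExpressionMatrix:
    """Gene (or probe) x sample log2(Cy3/Cy5) matrix with sample metadata.

    ``sample_meta`` (optional) is indexed by sample id and may carry
    ``patient``, ``visit`` and ``response`` columns used downstream.
    ``stage`` tracks preprocessing progress; ``level`` is ``"probe"`` or
    ``"gene"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    level: str = "gene"
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.level not in ("probe", "gene"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.sample_meta is not None:
            missing = [s for s in self.values.columns if s not in self.sample_meta.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing[:5]}")

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def _require_stage(self, allowed: tuple[str, ...], op: str) -> None:
        if self.stage not in allowed:
            raise PipelineOrderError(
                f"{op} expects stage in {allowed}, matrix is at {self.stage!r}"
            )


def lowess_normalize(pm: ProbeMatrix, span: float = 0.3, iterations: int = 3) -> ProbeMatrix:
    """Per-sample intensity-dependent normalization of the log ratios.

    For each sample, M = log2(ch1/ch2) is regressed on the mean log intensity
    A = 0.5*log2(ch1*ch2) with a robust locally weighted fit (window fraction
    ``span``, ``iterations`` robustifying passes), and the fitted trend is
    subtracted from M.  A values are untouched.  Probes lacking a complete
    intensity quadruple in a sample are left unchanged there.
    """
    if pm.background_filtered:
        raise PipelineOrderError("lowess normalization must precede background filtering")
    if pm.orientation == CY5_OVER_CY3:
        ch1, ch2 = pm.cy5, pm.cy3
    else:
        ch1, ch2 = pm.cy3, pm.cy5
    new_ratio = pm.log_ratio.copy()
    for s in pm.sample_ids:
        i1 = ch1[s].to_numpy(dtype=float)
        i2 = ch2[s].to_numpy(dtype=float)
        ok = np.isfinite(i1) & np.isfinite(i2) & (i1 > 0) & (i2 > 0)
        if ok.sum() < 10:
            raise ValueError(f"sample {s}: fewer than 10 probes with complete intensities")
        m = np.log2(i1[ok] / i2[ok])
        a = 0.5 * np.log2(i1[ok] * i2[ok])
        if np.ptp(a) == 0:
            # Degenerate A axis: the intensity trend is a single point; the
            # best local fit is the (robust) mean of M.
            fit = np.full_like(m, np.median(m))
        else:
            fit = _sm_lowess(m, a, frac=span, it=iterations, return_sorted=False)
        col = new_ratio[s].to_numpy(dtype=float)
        col[ok] = m - fit
        new_ratio[s] = col
    return replace(pm, log_ratio=new_ratio)


def filter_background(pm: ProbeMatrix, fold: float = 1.5) -> ProbeMatrix:
    """Remove probe measurements not clearly above local background.

    A probe is retained in a sample when Cy3 >= fold * Cy3 background OR
    Cy5 >= fold * Cy5 background (boundary inclusive).  Failing measurements
    become missing; probes failing in every sample are dropped outright.
    """
    for name, bg in (("cy3", pm.cy3_bg), ("cy5", pm.cy5_bg)):
        bad = (bg <= 0) & bg.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-positive {name} background for probe {bg.index[r]!r}, sample {bg.columns[c]!r}"
            )
    keep = (pm.cy3 >= fold * pm.cy3_bg) | (pm.cy5 >= fold * pm.cy5_bg)
    ratio = pm.log_ratio.where(keep)
    alive = ratio.notna().any(axis=1)
    n_dropped = int((~alive).sum())
    if n_dropped:
        log.info("background filter dropped %d probe(s) failing in all samples", n_dropped)
    idx = ratio.index[alive]
    return replace(
        pm,
        cy3=pm.cy3.loc[idx],
        cy5=pm.cy5.loc[idx],
        cy3_bg=pm.cy3_bg.loc[idx],
        cy5_bg=pm.cy5_bg.loc[idx],
        log_ratio=ratio.loc[idx],
        annotation=pm.annotation.reindex(idx).dropna(),
        background_filtered=True,
    )


def orient_ratios(pm: ProbeMatrix) -> ProbeMatrix:
    """Flip log2(Cy5/Cy3) ratios to the analysis orientation log2(Cy3/Cy5).

    Negates every log ratio exactly once; calling it on an already-oriented
    matrix raises rather than silently double-flipping.
    """
    if pm.orientation == CY3_OVER_CY5:
        raise PipelineOrderError("ratios already oriented as Cy3/Cy5")
    return replace(pm, log_ratio=-pm.log_ratio, orientation=CY3_OVER_CY5)


def probe_to_expression(
    pm: ProbeMatrix, sample_meta: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Lift an oriented, background-filtered probe matrix into the
    probe-level :class:`ExpressionMatrix` that starts the matrix pipeline."""
    if pm.orientation != CY3_OVER_CY5:
        raise PipelineOrderError("orient_ratios must run before matrix extraction")
    if not pm.background_filtered:
        raise PipelineOrderError("filter_background must run before matrix extraction")
    return ExpressionMatrix(pm.log_ratio.copy(), sample_meta=sample_meta, level="probe", stage="raw")


def filter_missing(
    em: ExpressionMatrix, max_missing: float = 0.20
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop rows whose missing fraction strictly exceeds ``max_missing``.

    A row at exactly the threshold is kept.  Returns the filtered matrix and
    the list of removed row ids.
    """
    em._require_stage(("raw",), "filter_missing")
    frac = em.values.isna().mean(axis=1)
    removed = list(em.values.index[frac > max_missing])
    kept = em.values.loc[frac <= max_missing]
    if kept.empty:
        raise ValueError("missing-data filter removed every row")
    if removed:
        log.info("missing-data filter removed %d row(s)", len(removed))
    return replace(em, values=kept, stage="missing_filtered"), removed


def knn_impute(em: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing entries from the k nearest rows.

    Row-to-row distance is root-mean-square difference over the columns
    observed in both rows (so rows with different missingness patterns remain
    comparable).  A missing cell takes the mean of that column's values over
    the k nearest rows observed at the column; when no candidate neighbor
    shares any observed column, the row's own mean is used and the fallback
    is logged.  Observed values are never altered.
    """
    em._require_stage(("missing_filtered",), "knn_impute")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = em.values.to_numpy(dtype=float)
    obs = np.isfinite(X)
    if not (~obs).any():
        return replace(em, stage="imputed")
    if (~obs).all(axis=1).any():
        raise ValueError("a row is entirely missing; run filter_missing first")

    Z = np.where(obs, X, 0.0)
    S = obs.astype(float)
    shared = S @ S.T
    sq = Z * Z
    # sum over shared columns of (x_i - x_j)^2
    d2 = sq @ S.T + S @ sq.T - 2.0 * (Z @ Z.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(d2, 0.0) / shared)  # scaled by shared-column count
    np.fill_diagonal(dist, np.inf)
    dist[shared == 0] = np.inf

    out = X.copy()
    fallbacks = 0
    for i, j in np.argwhere(~obs):
        cand = np.flatnonzero(obs[:, j] & np.isfinite(dist[i]))
        if cand.size == 0:
            out[i, j] = X[i, obs[i]].mean()
            fallbacks += 1
            continue
        order = cand[np.argsort(dist[i, cand], kind="stable")]
        nbrs = order[: min(k, order.size)]
        out[i, j] = X[nbrs, j].mean()
    if fallbacks:
        log.warning("knn_impute: %d cell(s) fell back to the row mean", fallbacks)
    values = pd.DataFrame(out, index=em.values.index, columns=em.values.columns)
    return replace(em, values=values, stage="imputed")


def collapse_probes(em: ExpressionMatrix, annotation: pd.Series, mode: str = "max") -> ExpressionMatrix:
    """Collapse probe rows to unique gene symbols.

    ``annotation`` maps probe id -> symbol; unannotated probes are dropped
    (count logged).  For genes measured by several probes the per-sample
    maximum is taken by default (``mode="max"``); ``mode="median"`` is the
    alternative.  Symbols are uppercased.
    """
    em._require_stage(("imputed",), "collapse_probes")
    if em.level != "probe":
        raise PipelineOrderError("collapse_probes expects a probe-level matrix")
    if len(annotation) == 0:
        raise ValueError("empty probe annotation")
    if mode not in ("max", "median"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    ann = annotation.reindex(em.values.index)
    unannotated = int(ann.isna().sum())
    if unannotated:
        log.info("collapse_probes: dropping %d unannotated probe(s)", unannotated)
    keep = ann.notna()
    vals = em.values.loc[keep]
    symbols = ann[keep].str.upper()
    grouped = vals.groupby(symbols.to_numpy())
    collapsed = grouped.max() if mode == "max" else grouped.median()
    collapsed = collapsed.sort_index()
    return replace(em, values=collapsed, level="gene", stage="collapsed")


def median_center(em: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each row's median (over observed entries) from the row.

    Idempotent; even-length rows use the mean of the two middle values.
    """
    em._require_stage(("collapsed", "centered"), "median_center")
    med = em.values.median(axis=1, skipna=True)
    return replace(em, values=em.values.sub(med, axis=0), stage="centered")


def preprocess_pipeline(
    pm: ProbeMatrix,
    sample_meta: pd.DataFrame | None = None,
    *,
    lowess: bool = False,
    span: float = 0.3,
    lowess_iterations: int = 3,
    fold: float = 1.5,
    max_missing: float = 0.20,
    knn_k: int = 10,
    collapse_mode: str = "max",
) -> ExpressionMatrix:
    """Run the full canonical preprocessing chain on raw probe data."""
    if lowess:
        pm = lowess_normalize(pm, span=span, iterations=lowess_iterations)
    pm = filter_background(pm, fold=fold)
    pm = orient_ratios(pm)
    em = probe_to_expression(pm, sample_meta=sample_meta)
    em, _ = filter_missing(em, max_missing=max_missing)
    em = knn_impute(em, k=knn_k)
    em = collapse_probes(em, pm.annotation, mode=collapse_mode)
    return median_center(em)
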