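"""Intrinsic-subset classification and hierarchical clustering.

Skin biopsies from systemic sclerosis patients fall into reproducible
gene-expression groups — fibroproliferative, inflammatory and normal-like —
defined by an externally curated "intrinsic" gene list.  A new sample is
classified by Spearman-correlating its intrinsic-gene expression against
per-subset centroids (per-gene means over the reference samples of each
subset) and taking the subset with the highest correlation; the lowest
p value is checked for concordance rather than used as a second key, since
for a fixed gene count p is a monotone function of |rho|.

Clustering of genes and arrays uses the uncentered correlation similarity
(cosine similarity, no mean subtraction) with average linkage, the classic
combination for displaying log-ratio heat maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "SUBSETS",
    "SubsetAssignment",
    "DendroTree",
    "restrict_to_intrinsic",
    "build_centroids",
    "spearman_to_centroid",
    "assign_subset",
    "classify_cohort",
    "uncentered_corr",
    "hcluster",
]

SUBSETS = ("fibroproliferative", "inflammatory", "normal-like")


@dataclass
class SubsetAssignment:
    """Classification of one sample against the subset centroids."""

    sample_id: str
    subset: str
    rho: dict[str, float]
    p: dict[str, float]
    concordant: bool  # argmax rho also attains the minimum p


@dataclass
class DendroTree:
    """Agglomerative clustering result: scipy linkage matrix + leaf order."""

    ids: list[str]
    merges: np.ndarray  # scipy linkage format (n-1, 4)
    leaf_order: list[int]

    def ordered_ids(self) -> list[str]:
        return [self.ids[i] for i in self.leaf_order]


def _values(em: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return em.values if isinstance(em, ExpressionMatrix) else em


def restrict_to_intrinsic(
    em: ExpressionMatrix | pd.DataFrame, intrinsic_genes: list[str]
) -> tuple[pd.DataFrame, dict]:
    """Restrict the matrix to the intrinsic gene list.

    Returns the restricted matrix together with an overlap report
    ``{"n_list", "n_found", "percent"}`` (percent rounded to one decimal).
    Warns below 50 % overlap; errors on zero overlap.
    """
    values = _values(em)
    wanted = [g.upper() for g in intrinsic_genes]
    have = {str(g).upper(): g for g in values.index}
    found = [have[g] for g in wanted if g in have]
    report = {
        "n_list": len(wanted),
        "n_found": len(found),
        "percent": round(100.0 * len(found) / len(wanted), 1) if wanted else 0.0,
    }
    if not found:
        raise ValueError("no intrinsic gene present in the expression matrix")
    if report["percent"] < 50.0:
        warnings.warn(
            f"only {report['percent']}% of the intrinsic list is present", stacklevel=2
        )
    return values.loc[found], report


def build_centroids(
    em: ExpressionMatrix | pd.DataFrame, subset_per_sample: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-gene mean expression within each named subset.

    ``subset_per_sample`` maps sample id -> subset name for the reference
    samples; samples absent from the mapping are ignored.  Returns a
    gene x subset DataFrame.  An empty subset is an error.
    """
    values = _values(em)
    mapping = pd.Series(dict(subset_per_sample))
    cols = {}
    for subset in sorted(mapping.unique()):
        members = [s for s in values.columns if mapping.get(s) == subset]
        if not members:
            raise ValueError(f"subset {subset!r} has no reference sample")
        cols[subset] = values[members].mean(axis=1)
    return pd.DataFrame(cols)


def spearman_to_centroid(sample: pd.Series, centroid: pd.Series) -> tuple[float, float]:
    """Spearman rho and two-sided p between a sample and one centroid.

    Average ranks handle ties; p comes from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)).  Requires >=5 shared genes and a
    non-constant sample vector.
    """
    common = sample.index.intersection(centroid.index)
    if len(common) < 5:
        raise ValueError(f"only {len(common)} genes shared with centroid; need >=5")
    x = sample.loc[common].to_numpy(dtype=float)
    y = centroid.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant sample vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def assign_subset(sample: pd.Series, centroids: pd.DataFrame) -> SubsetAssignment:
    """Assign one sample to the centroid with the highest Spearman rho.

    The concordance flag records whether that subset also attains the lowest
    p value; a discordance (possible when a competing rho is negative with a
    larger magnitude) is logged, not resolved.
    """
    rhos: dict[str, float] = {}
    ps: dict[str, float] = {}
    for subset in centroids.columns:
        rhos[subset], ps[subset] = spearman_to_centroid(sample, centroids[subset])
    best = max(rhos, key=lambda s: rhos[s])
    best_p = min(ps, key=lambda s: ps[s])
    concordant = best == best_p
    if not concordant:
        log.warning(
            "sample %s: max-rho subset %s disagrees with min-p subset %s",
            sample.name, best, best_p,
        )
    return SubsetAssignment(str(sample.name), best, rhos, ps, concordant)


def classify_cohort(
    em: ExpressionMatrix | pd.DataFrame,
    centroids: pd.DataFrame,
    sample_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Classify every sample; optionally tabulate baseline→post transitions.

    ``sample_meta`` (indexed by sample id) needs ``patient`` and ``visit``
    columns, with visits ``baseline`` and ``post``, to build the per-patient
    transition table; without it only assignments are returned.
    """
    values = _values(em)
    if isinstance(em, ExpressionMatrix) and sample_meta is None:
        sample_meta = em.sample_meta
    assignments = []
    for s in values.columns:
        a = assign_subset(values[s], centroids)
        row = {"sample": s, "subset": a.subset, "concordant": a.concordant}
        for subset in centroids.columns:
            row[f"rho_{subset}"] = a.rho[subset]
            row[f"p_{subset}"] = a.p[subset]
        assignments.append(row)
    adf = pd.DataFrame(assignments).set_index("sample")

    transitions = None
    if sample_meta is not None and {"patient", "visit"} <= set(sample_meta.columns):
        rows = []
        for patient, grp in sample_meta.loc[sample_meta.index.isin(adf.index)].groupby("patient"):
            by_visit = {v: s for s, v in grp["visit"].items()}
            if "baseline" in by_visit and "post" in by_visit:
                rows.append(
                    {
                        "patient": patient,
                        "baseline_subset": adf.loc[by_visit["baseline"], "subset"],
                        "post_subset": adf.loc[by_visit["post"], "subset"],
                    }
                )
        transitions = pd.DataFrame(rows).set_index("patient") if rows else None
    return adf, transitions


def uncentered_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Uncentered (cosine) correlation: sum(x*y)/sqrt(sum(x^2)*sum(y^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("vectors must share a length >= 2")
    nx, ny = np.dot(x, x), np.dot(y, y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm vector: uncentered correlation undefined")
    return float(np.dot(x, y) / np.sqrt(nx * ny))


def hcluster(items: pd.DataFrame, metric: str = "uncentered", method: str = "average") -> DendroTree:
    """Agglomerative clustering of the rows of ``items``.

    Distance is 1 - uncentered correlation (``metric="uncentered"``) or
    1 - Pearson correlation (``"correlation"``); linkage is average by
    default.  Returns a :class:`DendroTree` with the scipy merge list and the
    dendrogram leaf order.
    """
    if items.index.has_duplicates:
        raise ValueError("duplicate item ids")
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    X = items.to_numpy(dtype=float)
    if metric == "uncentered":
        dist = pdist(X, metric="cosine")  # cosine distance == 1 - uncentered corr
    elif metric == "correlation":
        dist = pdist(X, metric="correlation")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(dist, method=method)
    return DendroTree([str(i) for i in items.index], Z, [int(i) for i in leaves_list(Z)])
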