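"""Gene set enrichment analysis: weighted running-sum ES, a gene-set
permutation null with NES and FDR, and single-sample GSEA.

The enrichment score (ES) walks the ranked gene list from top to bottom,
stepping up by the gene's weighted ranking score when the gene belongs to the
set and down by a constant when it does not; the ES is the signed maximum
excursion of this running sum.  Significance comes from a *gene-set*
permutation null — random same-size gene sets drawn from the ranked list —
which is the appropriate null when the number of samples is far too small for
phenotype permutation.  NES divides each ES by the mean of its same-sign null
ES; FDR q uses the classical ratio-of-tails estimate over the pooled
normalized null, with positive and negative scores handled separately.

ssGSEA scores one sample at a time: genes are ranked by expression within the
sample and the (rank-weighted) cumulative hit distribution minus the miss
distribution is *integrated* over the whole list rather than maximized.
Scores are comparable across samples only after dividing the whole matrix by
its maximum score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .formats import ClsLabels, GeneSetCollection
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "rank_genes",
    "enrichment_score",
    "gsea",
    "ssgsea",
    "normalize_ssgsea",
    "core_enrichment",
    "SsgseaMatrix",
]


def _values(em: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return em.values if isinstance(em, ExpressionMatrix) else em


def rank_genes(
    em: ExpressionMatrix | pd.DataFrame,
    labels: ClsLabels,
    metric: str = "s2n",
    *,
    class_a: str | None = None,
    class_b: str | None = None,
) -> pd.Series:
    """Rank genes by a two-class differential metric, descending.

    ``"s2n"`` (default) is the signal-to-noise ratio
    (mean_A - mean_B) / (sd_A + sd_B) with each sd floored at
    max(0.2*|class mean|, 0.2); ``"t"`` is the Welch t statistic.  Ties are
    broken by gene symbol so the ordering is deterministic.  Returns a Series
    of scores indexed by gene in ranked order.
    """
    values = _values(em)
    if labels.n_samples != values.shape[1]:
        raise ValueError("CLS sample count does not match matrix columns")
    class_a = class_a or labels.class_names[0]
    class_b = class_b or labels.class_names[1]
    ia, ib = labels.indices_of(class_a), labels.indices_of(class_b)
    if min(len(ia), len(ib)) < 2:
        raise ValueError("each class needs >=2 samples")
    if min(len(ia), len(ib)) < 3:
        warnings.warn(
            "a phenotype class has fewer than 3 samples; ranking metric is noisy",
            stacklevel=2,
        )
    a = values.iloc[:, ia].to_numpy(dtype=float)
    b = values.iloc[:, ib].to_numpy(dtype=float)
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    if metric == "s2n":
        sa = a.std(axis=1, ddof=1)
        sb = b.std(axis=1, ddof=1)
        sa = np.maximum(sa, np.maximum(0.2 * np.abs(ma), 0.2))
        sb = np.maximum(sb, np.maximum(0.2 * np.abs(mb), 0.2))
        score = (ma - mb) / (sa + sb)
    elif metric == "t":
        from .diffexp import welch_ttest_arrays

        score, _ = welch_ttest_arrays(a, b)
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    ranked = pd.Series(score, index=values.index, name=metric)
    order = sorted(range(len(ranked)), key=lambda i: (-ranked.iloc[i], str(ranked.index[i])))
    return ranked.iloc[order]


def enrichment_score(
    ranked: pd.Series, gene_set: list[str] | set[str], weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted Kolmogorov–Smirnov-style enrichment score.

    ``ranked`` is the descending score Series from :func:`rank_genes`.
    Returns ``(ES, running_sum, hit_indices)`` where ``running_sum`` has one
    entry per ranked gene and ES is its signed maximum deviation from zero.
    Hit increments are |score|^exponent normalized by their total; every miss
    decrements by 1/(N - N_hits).  With all hit weights zero (degenerate flat
    scores) hits fall back to uniform weights.
    """
    genes = ranked.index
    members = {str(g).upper() for g in gene_set}
    hit = np.fromiter((str(g).upper() in members for g in genes), dtype=bool, count=len(genes))
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = hit.astype(float)
        total = float(n_hit)
    steps = hit_w / total - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, np.flatnonzero(hit)


def _es_from_positions(pos: np.ndarray, w_ranked: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many same-size gene sets given their hit positions.

    ``pos`` is (P, k) of 0-based rank indices (any order); ``w_ranked`` the
    length-N weight vector |score|^exponent.  The running sum is piecewise
    linear between hits, so its extrema occur immediately before or at a hit;
    evaluating those 2k candidates reproduces the full running-sum extremum.
    """
    pos = np.sort(pos, axis=1)
    k = pos.shape[1]
    wk = w_ranked[pos]
    tot = wk.sum(axis=1, keepdims=True)
    degenerate = tot[:, 0] == 0
    if degenerate.any():
        wk = np.where(degenerate[:, None], 1.0, wk)
        tot = np.where(degenerate[:, None], float(k), tot)
    W = np.cumsum(wk, axis=1) / tot
    j = np.arange(k)
    miss = n - k
    at_hit = W - (pos - j) / miss  # value just after hit j
    before = np.concatenate([np.zeros((pos.shape[0], 1)), W[:, :-1]], axis=1) - (pos - j) / miss
    cand = np.concatenate([at_hit, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(cand.shape[0]), idx]


def gsea(
    em: ExpressionMatrix | pd.DataFrame,
    labels: ClsLabels,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    weight_exponent: float = 1.0,
    metric: str = "s2n",
    min_size: int = 15,
    max_size: int = 500,
    class_a: str | None = None,
    class_b: str | None = None,
) -> pd.DataFrame:
    """Run GSEA with a gene-set permutation null.

    Sets are filtered to those with ``min_size``–``max_size`` members present
    in the matrix.  For each retained set, ``n_perm`` random same-size gene
    sets drawn from the ranked list form the null ES distribution; NES, the
    nominal p and the ratio-of-tails FDR q follow from it.  Results are
    sorted by NES descending; ``core_enrichment`` lists the leading-edge
    genes.  Fully deterministic for a fixed ``seed``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable FDR estimates", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranked = rank_genes(em, labels, metric=metric, class_a=class_a, class_b=class_b)
    gene_pos = {str(g).upper(): i for i, g in enumerate(ranked.index)}
    n = len(ranked)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent

    kept: list[tuple[str, list[str]]] = []
    for name, members in collection:
        present = [m for m in members if m in gene_pos]
        if min_size <= len(present) <= max_size:
            kept.append((name, present))
        else:
            log.info("gsea: set %s skipped (size %d outside [%d, %d])",
                     name, len(present), min_size, max_size)
    if not kept:
        raise ValueError("no gene set within the size window is present in the matrix")

    degenerate_ranking = bool(np.all(w == 0))
    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, present in kept:
        if degenerate_ranking:
            # flat ranking scores: the ES ordering is arbitrary and the
            # normalized null undefined; report the guard values
            es, running, _ = enrichment_score(ranked, present, weight_exponent)
            rows.append({"set": name, "size": len(present), "es": es, "nes": 0.0,
                         "p": 1.0, "core_enrichment": ""})
            continue
        es, running, hits = enrichment_score(ranked, present, weight_exponent)
        k = len(present)
        perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        null_es = _es_from_positions(perm_pos, w, n)
        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = neg_null.mean() if neg_null.size else np.nan

        if es >= 0:
            same = pos_null
            denom = mean_pos
        else:
            same = neg_null
            denom = mean_neg
        if same.size == 0 or not np.isfinite(denom) or denom == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / abs(denom)
            p = float(((np.abs(same) >= abs(es)).sum()) / same.size)
            p = max(p, 0.0)
        # normalize the whole null for the pooled FDR reference
        norm_null = np.where(
            null_es >= 0,
            null_es / abs(mean_pos) if pos_null.size and mean_pos else np.nan,
            null_es / abs(mean_neg) if neg_null.size and mean_neg else np.nan,
        )
        null_nes_pool.append(norm_null[np.isfinite(norm_null)])
        core = core_enrichment(ranked, present, running)
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "p": min(p, 1.0),
                "core_enrichment": ",".join(core),
            }
        )

    res = pd.DataFrame(rows).set_index("set")
    if degenerate_ranking:
        res["fdr_q"] = 1.0
        return res[["size", "es", "nes", "p", "fdr_q", "core_enrichment"]]
    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    res["fdr_q"] = _gsea_fdr(res["nes"].to_numpy(), pooled)
    res = res.sort_values("nes", ascending=False, kind="stable")
    return res[["size", "es", "nes", "p", "fdr_q", "core_enrichment"]]


def _gsea_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Ratio-of-tails FDR with separate positive and negative branches."""
    q = np.ones_like(obs_nes, dtype=float)
    n_null_pos = (null_nes >= 0).sum()
    n_null_neg = (null_nes < 0).sum()
    n_obs_pos = (obs_nes >= 0).sum()
    n_obs_neg = (obs_nes < 0).sum()
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            if n_null_pos == 0 or n_obs_pos == 0:
                continue
            num = (null_nes >= nes).sum() / n_null_pos
            den = (obs_nes >= nes).sum() / n_obs_pos
        else:
            if n_null_neg == 0 or n_obs_neg == 0:
                continue
            num = (null_nes <= nes).sum() / n_null_neg
            den = (obs_nes <= nes).sum() / n_obs_neg
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    # q(set) = min estimated FDR over thresholds that include the set, i.e.
    # cumulative min walking from the least extreme score outward per branch
    order_pos = np.argsort(obs_nes)  # ascending: least extreme positive first
    running = np.inf
    for i in order_pos:
        if obs_nes[i] < 0:
            continue
        running = min(running, q[i])
        q[i] = running
    order_neg = np.argsort(-obs_nes)  # ascending |NES| among negatives
    running = np.inf
    for i in order_neg:
        if obs_nes[i] >= 0:
            continue
        running = min(running, q[i])
        q[i] = running
    return q


def core_enrichment(
    ranked: pd.Series, gene_set: list[str] | set[str], running: np.ndarray
) -> list[str]:
    """Leading-edge genes of a set given its running sum.

    For a positive ES these are the set members ranked at or before the peak
    of the running sum; for a negative ES, at or after the trough.
    """
    members = {str(g).upper() for g in gene_set}
    genes = [str(g).upper() for g in ranked.index]
    peak = int(np.argmax(np.abs(running)))
    if running[peak] >= 0:
        return [g for i, g in enumerate(genes) if i <= peak and g in members]
    return [g for i, g in enumerate(genes) if i >= peak and g in members]


@dataclass
class SsgseaMatrix:
    """Set x sample ssGSEA scores; ``normalized`` marks dataset-max scaling."""

    scores: pd.DataFrame
    alpha: float
    normalized: bool = False


def ssgsea(
    em: ExpressionMatrix | pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.75,
) -> SsgseaMatrix:
    """Single-sample GSEA (integrated weighted cumulative difference).

    For each sample, genes are ordered by expression (descending; symbol
    breaks ties) and the gene at position i of N receives rank weight
    (N - i)^alpha.  The set score is the sum over the list of the cumulative
    normalized hit weight minus the cumulative miss fraction.  Sets with
    fewer than two members present are skipped.  Raw (unnormalized) scores
    are returned; see :func:`normalize_ssgsea`.
    """
    values = _values(em)
    if values.isna().to_numpy().any():
        raise ValueError("ssGSEA requires a complete (imputed) matrix")
    n = values.shape[0]
    genes_upper = np.array([str(g).upper() for g in values.index])
    sets_present: dict[str, np.ndarray] = {}
    for name, members in collection:
        mask = np.isin(genes_upper, list(members))
        if mask.sum() < 2:
            log.info("ssgsea: set %s skipped (<2 members present)", name)
            continue
        sets_present[name] = mask
    if not sets_present:
        raise ValueError("no gene set has >=2 members in the matrix")

    rank_w = (np.arange(n, 0, -1, dtype=float)) ** alpha  # weight by list position
    out = pd.DataFrame(index=list(sets_present), columns=values.columns, dtype=float)
    tie_break = np.array([str(g) for g in values.index])
    for s in values.columns:
        col = values[s].to_numpy(dtype=float)
        order = np.lexsort((tie_break, -col))
        for name, mask in sets_present.items():
            hit = mask[order]
            k = hit.sum()
            whit = np.where(hit, rank_w, 0.0)
            p_hit = np.cumsum(whit) / whit.sum()
            p_miss = np.cumsum(~hit) / (n - k)
            out.loc[name, s] = float(np.sum(p_hit - p_miss))
    return SsgseaMatrix(out, alpha=alpha, normalized=False)


def normalize_ssgsea(m: SsgseaMatrix) -> SsgseaMatrix:
    """Divide every score by the dataset maximum so the largest score is 1.

    Idempotent.  Errors when the maximum is not positive, since the scaling
    would then flip or explode score orientation.
    """
    mx = float(np.nanmax(m.scores.to_numpy()))
    if mx <= 0:
        raise ValueError("maximum ssGSEA score is not positive; cannot normalize")
    return replace(m, scores=m.scores / mx, normalized=True)
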