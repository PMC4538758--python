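"""Marker selection between phenotype classes.

Two comparisons drive the analysis: an unpaired t test between responder
classes at baseline, and a paired t test between baseline and post-treatment
biopsies within responders.  P-values are parametric (from the t
distribution) and deliberately left uncorrected for multiplicity — with only
a handful of arrays per class, per-gene correction is hopeless and pathway
level statistics carry the multiple-testing burden instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ClsLabels
from .preprocess import ExpressionMatrix

__all__ = [
    "PairMap",
    "unpaired_ttest",
    "paired_ttest",
    "select_markers",
    "signature_overlap",
    "welch_ttest_arrays",
]

_TINY_P = np.finfo(float).tiny


@dataclass
class PairMap:
    """patient -> (baseline sample id, post-treatment sample id)."""

    pairs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pat, (b, p) in self.pairs.items():
            for s in (b, p):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    def __len__(self) -> int:
        return len(self.pairs)

    def baseline_ids(self) -> list[str]:
        return [b for b, _ in self.pairs.values()]

    def post_ids(self) -> list[str]:
        return [p for _, p in self.pairs.values()]


def _values(em: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return em.values if isinstance(em, ExpressionMatrix) else em


def welch_ttest_arrays(
    a: np.ndarray, b: np.ndarray, *, pooled: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t test on 2-D arrays (rows = genes).

    Welch by default (Satterthwaite df); ``pooled=True`` uses the classical
    equal-variance statistic.  Degenerate rows (zero variance in both groups)
    yield t = 0, p = 1 when the means agree and p = machine-minimum when they
    differ.  Returns (t, p), both of length n_rows.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each class needs at least 2 samples")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(ma, na + nb - 2)
    else:
        se2 = va / na + vb / nb
        with np.errstate(invalid="ignore", divide="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    diff = ma - mb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (diff == 0), 0.0, t)
        p = np.where(zero_se & (diff == 0), 1.0, p)
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
        p = np.where(zero_se & (diff != 0), _TINY_P, p)
    return t, np.clip(p, _TINY_P, 1.0)


def unpaired_ttest(
    em: ExpressionMatrix | pd.DataFrame,
    labels: ClsLabels,
    *,
    class_a: str | None = None,
    class_b: str | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t test between two phenotype classes.

    ``labels`` must align with the matrix columns.  Classes default to the
    first two declared in the CLS.  Direction is the sign of
    mean(class A) - mean(class B).  Returns a DataFrame indexed by gene with
    columns t, p, direction, mean_a, mean_b, sd_a, sd_b.
    """
    values = _values(em)
    if labels.n_samples != values.shape[1]:
        raise ValueError(
            f"CLS declares {labels.n_samples} samples, matrix has {values.shape[1]} columns"
        )
    if labels.n_classes < 2:
        raise ValueError("need two phenotype classes")
    class_a = class_a or labels.class_names[0]
    class_b = class_b or labels.class_names[1]
    ia, ib = labels.indices_of(class_a), labels.indices_of(class_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(f"classes {class_a!r}/{class_b!r} need >=2 samples each")
    a = values.iloc[:, ia].to_numpy(dtype=float)
    b = values.iloc[:, ib].to_numpy(dtype=float)
    t, p = welch_ttest_arrays(a, b, pooled=pooled)
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "direction": np.sign(a.mean(axis=1) - b.mean(axis=1)),
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "sd_a": a.std(axis=1, ddof=1),
            "sd_b": b.std(axis=1, ddof=1),
        },
        index=values.index,
    )


def paired_ttest(em: ExpressionMatrix | pd.DataFrame, pairs: PairMap) -> pd.DataFrame:
    """Per-gene paired t test on post-treatment minus baseline differences.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n - 1; two-sided p.  Genes whose
    differences are exactly constant get p = 1 (constant zero) or the
    machine-minimum p with ``degenerate`` flagged (constant nonzero).
    Direction is the sign of the mean difference (post minus baseline), so
    genes falling with treatment have direction -1.
    """
    values = _values(em)
    for pat, (bl, po) in pairs.pairs.items():
        for s in (bl, po):
            if s not in values.columns:
                raise ValueError(f"pair member {s!r} (patient {pat}) not in matrix")
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")
    base = values[pairs.baseline_ids()].to_numpy(dtype=float)
    post = values[pairs.post_ids()].to_numpy(dtype=float)
    d = post - base
    n = d.shape[1]
    md = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = md / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    degenerate = (sd == 0) & (md != 0)
    with np.errstate(invalid="ignore"):
        t = np.where((sd == 0) & (md == 0), 0.0, t)
        p = np.where((sd == 0) & (md == 0), 1.0, p)
        t = np.where(degenerate, np.sign(md) * np.inf, t)
        p = np.where(degenerate, _TINY_P, p)
    return pd.DataFrame(
        {
            "t": t,
            "p": np.clip(p, _TINY_P, 1.0),
            "direction": np.sign(md),
            "mean_diff": md,
            "sd_diff": sd,
            "degenerate": degenerate,
        },
        index=values.index,
    )


def select_markers(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Retain genes with p strictly below ``alpha``; no multiplicity correction.

    A gene at exactly the threshold is excluded.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha == 1:
        return results.copy()
    return results[results["p"] < alpha].copy()


def signature_overlap(
    sig_a: pd.Series | dict, sig_b: pd.Series | dict
) -> tuple[list[str], int, int]:
    """Compare two directional gene signatures.

    Inputs map gene symbol -> direction (+1/-1).  Returns the shared genes
    (sorted) plus the counts of direction-concordant and discordant genes.
    """
    a = dict(sig_a)
    b = dict(sig_b)
    if not a or not b:
        raise ValueError("signatures must be non-empty")
    shared = sorted(set(a) & set(b))
    concordant = sum(1 for g in shared if np.sign(a[g]) == np.sign(b[g]))
    return shared, concordant, len(shared) - concordant
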