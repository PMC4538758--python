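"""Clinical-outcome statistics for the skin-score endpoint.

The modified Rodnan skin score (MRSS, 0–51) is measured at screening,
baseline and months 3/6/12.  Patients are *improvers* when their MRSS falls
by strictly more than 20 % from baseline at 12 months.  This module computes
the completer-level MRSS change summaries, the responder classification, the
chi-square test relating baseline intrinsic subset to response, subgroup
t tests, and the one-way ANOVA with Tukey adjustment used for gene-signature
trend comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import welch_ttest_arrays

__all__ = [
    "ClinicalTable",
    "read_clinical_table",
    "write_clinical_table",
    "mrss_change",
    "mrss_change_from_means",
    "classify_improver",
    "responder_labels",
    "chisq_subset_response",
    "subgroup_ttest",
    "signature_trend_anova",
]

MRSS_COLUMNS = ("mrss_screening", "mrss_baseline", "mrss_m3", "mrss_m6", "mrss_m12")
IMPROVER_CUT = 0.20  # strict >20 % decrease at 12 months


@dataclass
class ClinicalTable:
    """Per-patient clinical measurements.

    ``data`` is indexed by patient id with the MRSS visit columns, a boolean
    ``completer`` flag, antibody-status columns (``rna_pol3``, ``scl70``,
    ``ana``) and any secondary measures.  MRSS values must lie in [0, 51];
    completers must have 6- and 12-month scores.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("mrss_baseline", "completer"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        mrss = self.data[[c for c in MRSS_COLUMNS if c in self.data.columns]]
        vals = mrss.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if ((vals[finite] < 0) | (vals[finite] > 51)).any():
            raise ValueError("MRSS values must lie within [0, 51]")
        comp = self.data[self.data["completer"].astype(bool)]
        for col in ("mrss_m6", "mrss_m12"):
            if col in self.data.columns and comp[col].isna().any():
                bad = comp.index[comp[col].isna()].tolist()
                raise ValueError(f"completer(s) {bad} missing {col}")

    @property
    def completers(self) -> pd.DataFrame:
        return self.data[self.data["completer"].astype(bool)]

    def __len__(self) -> int:
        return len(self.data)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read the tab-delimited clinical table (first column = patient id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "completer" in df.columns:
        df["completer"] = df["completer"].astype(bool)
    return ClinicalTable(df)


def write_clinical_table(tbl: ClinicalTable, path: str | Path) -> Path:
    path = Path(path)
    out = tbl.data.copy()
    out["completer"] = out["completer"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index_label="patient", float_format="%.10g", lineterminator="\n")
    return path


@dataclass
class ChangeSummary:
    """Group-level change at one visit relative to baseline."""

    n: int
    baseline_mean: float
    visit_mean: float
    mean_change: float  # points, visit - baseline (negative = improvement)
    percent_change: float  # 100 * (baseline - visit)/baseline (positive = improvement)
    p: float

    def display(self) -> str:
        """Printed-precision rendering: points to 1 decimal, percent integer."""
        return f"{abs(self.mean_change):.1f} points ({round(self.percent_change):.0f} %)"


def mrss_change(tbl: ClinicalTable, visit: int) -> ChangeSummary:
    """Mean MRSS change from baseline at a visit month (3, 6 or 12) among
    completers with both measurements, plus the paired t-test p value.

    The percent change is computed on the group means — the convention used
    for trial-level summaries — while responder classification (see
    :func:`classify_improver`) is per-patient.
    """
    col = {3: "mrss_m3", 6: "mrss_m6", 12: "mrss_m12"}.get(visit)
    if col is None:
        raise ValueError("visit must be 3, 6 or 12 (months)")
    comp = tbl.completers.dropna(subset=["mrss_baseline", col])
    if len(comp) < 2:
        raise ValueError("need >=2 completers with both visits")
    base = comp["mrss_baseline"].to_numpy(dtype=float)
    late = comp[col].to_numpy(dtype=float)
    d = late - base
    if np.allclose(d, 0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(late, base).pvalue)
    return ChangeSummary(
        n=len(comp),
        baseline_mean=float(base.mean()),
        visit_mean=float(late.mean()),
        mean_change=float(d.mean()),
        percent_change=100.0 * (base.mean() - late.mean()) / base.mean(),
        p=p,
    )


def mrss_change_from_means(baseline_mean: float, visit_mean: float) -> tuple[float, float]:
    """Change summary from printed group means: (decrease in points,
    percent decrease relative to baseline)."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    drop = baseline_mean - visit_mean
    return drop, 100.0 * drop / baseline_mean


def classify_improver(baseline: float, m12: float) -> bool:
    """Improver = MRSS decrease strictly greater than 20 % at 12 months."""
    if not np.isfinite(baseline) or not np.isfinite(m12):
        raise ValueError("both baseline and 12-month MRSS are required")
    if baseline <= 0:
        raise ValueError("baseline MRSS must be positive to compute percent change")
    return (baseline - m12) / baseline > IMPROVER_CUT


def responder_labels(tbl: ClinicalTable) -> pd.DataFrame:
    """Per-patient improver flag and 12-month percent decrease (completers
    with a 12-month score only)."""
    comp = tbl.completers.dropna(subset=["mrss_baseline", "mrss_m12"])
    rows = {}
    for pat, row in comp.iterrows():
        pct = 100.0 * (row["mrss_baseline"] - row["mrss_m12"]) / row["mrss_baseline"]
        rows[pat] = {
            "improver": classify_improver(row["mrss_baseline"], row["mrss_m12"]),
            "percent_decrease": pct,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def chisq_subset_response(
    baseline_subset: dict[str, str] | pd.Series,
    improver: dict[str, bool] | pd.Series,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square (1 df, no continuity correction) for the 2x2 table
    (fibroproliferative vs other baseline subset) x (improver vs not).

    Patients present in both mappings are tabulated.  A zero margin leaves
    the test undefined and raises.
    """
    subset = pd.Series(dict(baseline_subset))
    resp = pd.Series(dict(improver)).astype(bool)
    common = subset.index.intersection(resp.index)
    if len(common) == 0:
        raise ValueError("no patient shared between subset assignments and responses")
    fp = subset.loc[common].str.lower().str.startswith("fibro")
    table = pd.DataFrame(
        {
            "fibroproliferative": [
                int((fp & resp.loc[common]).sum()),
                int((fp & ~resp.loc[common]).sum()),
            ],
            "other": [
                int((~fp & resp.loc[common]).sum()),
                int((~fp & ~resp.loc[common]).sum()),
            ],
        },
        index=["improver", "non-improver"],
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p), table


def subgroup_ttest(
    changes_a: list[float] | np.ndarray,
    changes_b: list[float] | np.ndarray,
    *,
    pooled: bool = False,
) -> tuple[float, float, float, float]:
    """Two-sided unpaired t test on per-patient changes between subgroups.

    Returns (mean_a, mean_b, t, p); Welch by default.
    """
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each subgroup needs >=2 patients")
    t, p = welch_ttest_arrays(a[None, :], b[None, :], pooled=pooled)
    return float(a.mean()), float(b.mean()), float(t[0]), float(p[0])


def signature_trend_anova(groups: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across >=3 groups with Tukey HSD pairwise adjustment.

    ``groups`` maps group name (e.g. improver-baseline, improver-post, ...)
    to per-sample signature scores.  Returns (F, p, pairwise table) where the
    pairwise table has columns group_a, group_b, diff, p_tukey using the
    studentized-range distribution with a single pooled variance.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 3:
        raise ValueError("need at least 3 groups for the trend ANOVA")
    for n, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {n!r} has fewer than 2 observations")
    if np.ptp(np.concatenate(arrays)) == 0:
        # identical values everywhere: F = 0 by definition
        f_stat, p = 0.0, 1.0
        rows = [
            {"group_a": names[i], "group_b": names[j], "diff": 0.0, "p_tukey": 1.0}
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return f_stat, p, pd.DataFrame(rows)
    f_stat, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_tukey": float(tukey.pvalue[i, j]),
                }
            )
    return float(f_stat), float(p), pd.DataFrame(rows)
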