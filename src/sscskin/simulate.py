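"""Synthetic probe-level expression, gene sets and clinical trajectories.

The generator emulates the structure of a small open-label skin-biopsy trial:

* each patient contributes a baseline and a post-treatment biopsy profiled
  on a two-channel array (Cy3 = sample, Cy5 = reference);
* patients carry one of three intrinsic subsets (fibroproliferative,
  inflammatory, normal-like), each marked by a block of genes shifted by
  ``centroid_effect`` log2 units in carriers at both visits;
* *improvers* additionally over-express two designated receptor-signaling
  gene sets (TGFBR-like, 19 genes; PDGFRB-like, 50 genes — the leading-edge
  sizes typical of such signatures) at baseline, and that elevation is
  removed post-treatment; non-improvers stay flat;
* probe intensities are back-computed from the target log ratios around a
  log-normal background, some genes carry two probes, a configurable probe
  fraction sits below background (to be removed by the intensity filter),
  and entries go missing at ``missing_rate``;
* MRSS trajectories interpolate linearly from baseline to a 12-month target
  drawn per responder class, with Gaussian noise on the interim visits only,
  so the >20 %-decrease rule recovers the planted labels exactly.

Every function is deterministic given ``cfg.seed``; independent calls use
per-stage substreams so stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import ClinicalTable
from .formats import GeneSetCollection
from .preprocess import CY5_OVER_CY3, ProbeMatrix

__all__ = [
    "SimulationConfig",
    "SynthTruth",
    "simulate_expression",
    "simulate_clinical",
    "simulate_gene_sets",
]

ACTIVE_SET_SIZES = {"TGFBR_SIGNALING_LIKE": 19, "PDGFRB_SIGNALING_LIKE": 50}

_STAGE_EXPR, _STAGE_CLIN, _STAGE_SETS = 1, 2, 3


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the standard conditions."""

    n_genes: int = 1500
    n_patients: int = 12
    improver_fraction: float = 0.5
    subset_names: tuple[str, ...] = ("fibroproliferative", "inflammatory", "normal-like")
    centroid_effect: float = 2.0  # log2 shift of subset-marker blocks
    treatment_effect: float = 1.5  # baseline elevation / post-treatment drop of active sets
    noise_sd: float = 0.4  # gene-wise Gaussian sd on log2 ratios
    missing_rate: float = 0.02
    background_level: float = 100.0
    seed: int = 17
    n_marker_genes: int = 60  # per subset
    two_probe_fraction: float = 0.10
    subbackground_rate: float = 0.01  # fraction of probes pinned below background
    visit_noise_sd: float = 1.0  # MRSS points at interim visits
    completer_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("improver_fraction", "missing_rate", "two_probe_fraction",
                     "subbackground_rate", "completer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_patients", "n_marker_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        if self.noise_sd < 0 or self.visit_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        demand = len(self.subset_names) * self.n_marker_genes + sum(ACTIVE_SET_SIZES.values())
        if self.n_genes < demand + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {demand} marker/active genes"
            )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class SynthTruth:
    """Ground truth behind one simulated dataset."""

    patients: pd.DataFrame  # index patient: subset, improver
    samples: pd.DataFrame  # index sample: patient, visit
    gene_roles: pd.Series  # gene -> "marker:<subset>" | "active:<set>" | "background"
    marker_blocks: dict[str, list[str]]
    active_sets: dict[str, list[str]]
    subbackground_probes: list[str]
    expression_truth: pd.DataFrame = field(repr=False)  # noiseless gene x sample targets

    def shifted_genes(self) -> set[str]:
        """Genes carrying any planted effect (marker blocks or active sets)."""
        out: set[str] = set()
        for genes in self.marker_blocks.values():
            out.update(genes)
        for genes in self.active_sets.values():
            out.update(genes)
        return out


def _patient_frame(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    # tile subsets for guaranteed coverage, then shuffle for exchangeability
    reps = -(-cfg.n_patients // len(cfg.subset_names))
    subsets = np.array((list(cfg.subset_names) * reps)[: cfg.n_patients])
    rng.shuffle(subsets)
    improver = rng.random(cfg.n_patients) < cfg.improver_fraction
    if cfg.treatment_effect != 0 and not improver.any():
        import warnings

        warnings.warn("no improver drawn; treatment effect will be unobservable", stacklevel=3)
    return pd.DataFrame({"subset": subsets, "improver": improver}, index=ids)


def simulate_expression(cfg: SimulationConfig) -> tuple[ProbeMatrix, SynthTruth]:
    """Generate the probe-level two-channel dataset plus its ground truth."""
    rng = cfg.rng(_STAGE_EXPR)
    patients = _patient_frame(cfg, rng)

    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    roles = pd.Series("background", index=genes, name="role")
    cursor = 0
    marker_blocks: dict[str, list[str]] = {}
    for subset in cfg.subset_names:
        block = genes[cursor: cursor + cfg.n_marker_genes]
        marker_blocks[subset] = block
        roles.loc[block] = f"marker:{subset}"
        cursor += cfg.n_marker_genes
    active_sets: dict[str, list[str]] = {}
    for set_name, size in ACTIVE_SET_SIZES.items():
        block = genes[cursor: cursor + size]
        active_sets[set_name] = block
        roles.loc[block] = f"active:{set_name}"
        cursor += size

    sample_rows = []
    for pat in patients.index:
        sample_rows.append({"sample": f"{pat}_BL", "patient": pat, "visit": "baseline"})
        sample_rows.append({"sample": f"{pat}_POST", "patient": pat, "visit": "post"})
    samples = pd.DataFrame(sample_rows).set_index("sample")

    # noiseless gene x sample targets (log2 Cy3/Cy5)
    target = pd.DataFrame(0.0, index=genes, columns=samples.index)
    active_genes = [g for block in active_sets.values() for g in block]
    for pat, row in patients.iterrows():
        for visit, sid in (("baseline", f"{pat}_BL"), ("post", f"{pat}_POST")):
            target.loc[marker_blocks[row["subset"]], sid] += cfg.centroid_effect
            if row["improver"] and visit == "baseline":
                target.loc[active_genes, sid] += cfg.treatment_effect

    # probe layout: 1 probe/gene, plus a second probe for a gene fraction
    n_two = int(round(cfg.two_probe_fraction * cfg.n_genes))
    two_probe_genes = rng.choice(genes, size=n_two, replace=False) if n_two else np.array([])
    probe_ids, probe_gene = [], []
    for g in genes:
        probe_ids.append(f"{g}_p1")
        probe_gene.append(g)
    for g in two_probe_genes:
        probe_ids.append(f"{g}_p2")
        probe_gene.append(g)
    annotation = pd.Series(probe_gene, index=probe_ids, name="gene_symbol")
    n_probes = len(probe_ids)
    n_samples = len(samples)

    probe_target = target.loc[probe_gene].to_numpy()
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_probes, n_samples)) if cfg.noise_sd else 0.0
    m = probe_target + noise  # analysis-orientation log ratio per probe

    # channel back-computation around a log-normal background
    bg3 = cfg.background_level * np.exp(rng.normal(0.0, 0.1, (n_probes, n_samples)))
    bg5 = cfg.background_level * np.exp(rng.normal(0.0, 0.1, (n_probes, n_samples)))
    # geometric-mean intensity at least ~2.8x background so one channel always
    # clears the 1.5x filter regardless of the ratio split
    u = np.clip(rng.normal(0.0, 0.4, (n_probes, n_samples)), -0.5, 1.5)
    gm = 4.0 * cfg.background_level * np.exp2(u)
    x = -m  # raw orientation: log2(Cy5/Cy3)
    cy5 = gm * np.exp2(x / 2.0)
    cy3 = gm * np.exp2(-x / 2.0)

    # sub-background probes: pinned below 1.5x background in both channels
    n_sub = int(round(cfg.subbackground_rate * n_probes))
    twoset = set(map(str, two_probe_genes))
    pos_of = {p: i for i, p in enumerate(probe_ids)}
    bg_probes = [p for p, g in zip(probe_ids, probe_gene)
                 if roles[g] == "background" and g not in twoset]
    sub_probes = list(rng.choice(bg_probes, size=min(n_sub, len(bg_probes)), replace=False))
    sub_idx = [pos_of[p] for p in sub_probes]
    cy3[sub_idx, :] = 1.2 * bg3[sub_idx, :]
    cy5[sub_idx, :] = 1.2 * bg5[sub_idx, :]
    x[sub_idx, :] = np.log2(cy5[sub_idx, :] / cy3[sub_idx, :])

    # missingness on measured entries
    if cfg.missing_rate > 0:
        miss = rng.random((n_probes, n_samples)) < cfg.missing_rate
        cy3 = np.where(miss, np.nan, cy3)
        cy5 = np.where(miss, np.nan, cy5)
        x = np.where(miss, np.nan, x)

    cols = samples.index
    pm = ProbeMatrix(
        cy3=pd.DataFrame(cy3, index=probe_ids, columns=cols),
        cy5=pd.DataFrame(cy5, index=probe_ids, columns=cols),
        cy3_bg=pd.DataFrame(bg3, index=probe_ids, columns=cols),
        cy5_bg=pd.DataFrame(bg5, index=probe_ids, columns=cols),
        log_ratio=pd.DataFrame(x, index=probe_ids, columns=cols),
        annotation=annotation,
        orientation=CY5_OVER_CY3,
    )
    truth = SynthTruth(
        patients=patients,
        samples=samples,
        gene_roles=roles,
        marker_blocks=marker_blocks,
        active_sets=active_sets,
        subbackground_probes=sub_probes,
        expression_truth=target,
    )
    return pm, truth


def simulate_clinical(cfg: SimulationConfig, truth: SynthTruth | None = None) -> ClinicalTable:
    """Generate per-patient MRSS trajectories and completer flags.

    When ``truth`` is given its patient ids and improver flags are reused so
    the clinical and expression datasets describe the same cohort.  Improver
    patients receive a 12-month percent decrease drawn from U(25, 50) %,
    non-improvers from U(-10, 15) %; the 12-month value is exact while months
    3 and 6 interpolate with ``visit_noise_sd`` points of noise, so the
    >20 % classification rule recovers the planted flags without error.
    """
    rng = cfg.rng(_STAGE_CLIN)
    if truth is not None:
        patients = truth.patients
    else:
        patients = _patient_frame(cfg, rng)
    n = len(patients)
    baseline = np.clip(rng.normal(30.1, 8.2, n), 16.0, 51.0)
    screening = np.clip(baseline - rng.normal(2.9, 3.4, n), 0.0, 51.0)
    improver = patients["improver"].to_numpy(dtype=bool)
    pct = np.where(improver, rng.uniform(0.25, 0.50, n), rng.uniform(-0.10, 0.15, n))
    m12 = np.clip(baseline * (1.0 - pct), 0.0, 51.0)
    frac3, frac6 = 3.0 / 12.0, 6.0 / 12.0
    m3 = np.clip(baseline + frac3 * (m12 - baseline) + rng.normal(0, cfg.visit_noise_sd, n), 0, 51)
    m6 = np.clip(baseline + frac6 * (m12 - baseline) + rng.normal(0, cfg.visit_noise_sd, n), 0, 51)
    completer = rng.random(n) < cfg.completer_fraction
    data = pd.DataFrame(
        {
            "mrss_screening": np.round(screening, 1),
            "mrss_baseline": np.round(baseline, 1),
            "mrss_m3": np.round(m3, 1),
            "mrss_m6": np.round(m6, 1),
            "mrss_m12": m12,  # unrounded: the responder rule uses this endpoint
            "completer": completer,
            "rna_pol3": rng.random(n) < 0.5,
            "scl70": rng.random(n) < 0.3,
            "ana": rng.random(n) < 0.9,
        },
        index=patients.index,
    )
    data.loc[~completer, ["mrss_m6", "mrss_m12"]] = np.nan
    # guard: rounding must not move a patient across the 20 % boundary
    data["mrss_m12"] = data["mrss_m12"].round(2)
    return ClinicalTable(data)


def simulate_gene_sets(
    cfg: SimulationConfig,
    truth: SynthTruth,
    n_decoys: int = 20,
    decoy_sizes: list[int] | None = None,
) -> GeneSetCollection:
    """The two planted active sets plus size-matched decoy sets.

    Decoys are drawn uniformly from genes without any planted shift, so an
    enrichment method should flag exactly the active sets.  Default decoy
    sizes alternate between the two active-set sizes.
    """
    rng = cfg.rng(_STAGE_SETS)
    background = [g for g, r in truth.gene_roles.items() if r == "background"]
    if decoy_sizes is None:
        base = list(ACTIVE_SET_SIZES.values())
        decoy_sizes = [base[i % len(base)] for i in range(n_decoys)]
    if max(decoy_sizes, default=0) > len(background):
        raise ValueError("requested decoy size exceeds available unshifted genes")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for name, members in truth.active_sets.items():
        sets[name] = [g.upper() for g in members]
        descriptions[name] = "planted responder-associated set"
    for i, size in enumerate(decoy_sizes):
        name = f"DECOY_{i + 1:03d}"
        sets[name] = [g.upper() for g in rng.choice(background, size=size, replace=False)]
        descriptions[name] = "unshifted decoy set"
    return GeneSetCollection(sets, descriptions)
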