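"""Preprocessing stages: normalization, filtering, imputation, collapsing."""

import numpy as np
import pandas as pd
import pytest

from sscskin.preprocess import (
    CY3_OVER_CY5,
    CY5_OVER_CY3,
    ExpressionMatrix,
    PipelineOrderError,
    ProbeMatrix,
    collapse_probes,
    filter_background,
    filter_missing,
    knn_impute,
    lowess_normalize,
    median_center,
    orient_ratios,
    preprocess_pipeline,
    probe_to_expression,
)
from sscskin.simulate import SimulationConfig, simulate_expression

from conftest import toy_matrix


def make_probe_matrix(m_values, cy3=None, cy3_bg=None, cy5=None, cy5_bg=None,
                      orientation=CY5_OVER_CY3, genes=None):
    """Build a ProbeMatrix around given raw log ratios (default: intensities
    comfortably above background so the filter keeps everything)."""
    m = np.atleast_2d(np.asarray(m_values, dtype=float))
    n, k = m.shape
    idx = [f"p{i}" for i in range(n)]
    cols = [f"s{j}" for j in range(k)]
    base = 1000.0
    cy5_arr = base * np.exp2(m / 2.0)
    cy3_arr = base * np.exp2(-m / 2.0)
    frame = lambda a: pd.DataFrame(np.broadcast_to(np.asarray(a, dtype=float), (n, k)).copy(),
                                   index=idx, columns=cols)
    genes = genes or [f"G{i}" for i in range(n)]
    return ProbeMatrix(
        cy3=frame(cy3 if cy3 is not None else cy3_arr),
        cy5=frame(cy5 if cy5 is not None else cy5_arr),
        cy3_bg=frame(cy3_bg if cy3_bg is not None else 100.0),
        cy5_bg=frame(cy5_bg if cy5_bg is not None else 100.0),
        log_ratio=pd.DataFrame(m, index=idx, columns=cols),
        annotation=pd.Series(genes, index=idx),
        orientation=orientation,
    )


class TestLowess:
    def test_zero_bias_fixed_point(self, rng):
        # M identically 0 with varying A must stay identically 0
        n = 60
        a = rng.uniform(6, 14, n)
        cy5 = np.exp2(a)  # M = 0 when both channels equal
        pm = make_probe_matrix(np.zeros((n, 1)), cy5=cy5[:, None], cy3=cy5[:, None])
        out = lowess_normalize(pm)
        assert np.allclose(out.log_ratio.to_numpy(), 0.0, atol=1e-12)

    def test_constant_offset_removed(self, rng):
        c = 1.3
        n = 120
        a = np.sort(rng.uniform(6, 14, n))
        cy5 = np.exp2(a + c / 2.0)
        cy3 = np.exp2(a - c / 2.0)
        pm = make_probe_matrix(np.full((n, 1), c), cy5=cy5[:, None], cy3=cy3[:, None])
        out = lowess_normalize(pm)
        interior = out.log_ratio.to_numpy()[10:-10, 0]
        assert np.all(np.abs(interior) < 1e-6)

    def test_a_values_invariant(self, rng):
        n = 50
        m = rng.normal(0, 0.5, (n, 2))
        pm = make_probe_matrix(m)
        out = lowess_normalize(pm)
        # A = 0.5*log2(cy3*cy5) depends only on channels, which are untouched
        for ch in ("cy3", "cy5"):
            assert getattr(out, ch).equals(getattr(pm, ch))

    def test_too_few_probes_errors(self):
        pm = make_probe_matrix(np.zeros((5, 1)))
        with pytest.raises(ValueError, match="fewer than 10"):
            lowess_normalize(pm)


class TestBackgroundFilter:
    def test_boundary_inclusive_or_rule(self):
        # Cy3 exactly at 1.5x background, Cy5 at 1.0x: retained
        pm = make_probe_matrix([[0.0]], cy3=150.0, cy3_bg=100.0, cy5=100.0, cy5_bg=100.0)
        out = filter_background(pm)
        assert not out.log_ratio.isna().any().any()

    def test_both_below_threshold_becomes_missing(self):
        pm = make_probe_matrix([[0.0], [0.0]], cy3=140.0, cy5=140.0,
                               cy3_bg=100.0, cy5_bg=100.0)
        # second probe clearly expressed in its channel
        pm.cy5.iloc[1, 0] = 1000.0
        out = filter_background(pm)
        assert out.log_ratio.shape[0] == 1  # all-missing probe dropped
        assert out.probe_ids[0] == "p1"

    def test_simulated_subbackground_probes_all_dropped(self):
        cfg = SimulationConfig(seed=5, missing_rate=0.0)
        pm, truth = simulate_expression(cfg)
        out = filter_background(pm)
        dropped = set(pm.probe_ids) - set(out.probe_ids)
        assert dropped == set(truth.subbackground_probes)
        assert len(dropped) > 0

    def test_non_positive_background_errors(self):
        pm = make_probe_matrix([[0.0]])
        pm.cy3_bg.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="background"):
            filter_background(pm)


class TestOrientation:
    def test_negation_and_fixed_point(self):
        pm = make_probe_matrix([[1.7], [0.0]])
        out = orient_ratios(pm)
        assert out.log_ratio.iloc[0, 0] == -1.7
        assert out.log_ratio.iloc[1, 0] == 0.0
        assert out.orientation == CY3_OVER_CY5

    def test_double_orientation_guarded(self):
        pm = orient_ratios(make_probe_matrix([[1.0]]))
        before = pm.log_ratio.copy()
        with pytest.raises(PipelineOrderError):
            orient_ratios(pm)
        assert pm.log_ratio.equals(before)


class TestMissingFilter:
    def make_em(self, values):
        return ExpressionMatrix(toy_matrix(values), level="probe", stage="raw")

    def test_boundary_strictly_greater(self):
        vals = np.zeros((2, 10))
        vals[0, :3] = np.nan  # 30 % -> removed
        vals[1, :2] = np.nan  # exactly 20 % -> retained
        em, removed = filter_missing(self.make_em(vals))
        assert removed == ["g0"]
        assert list(em.values.index) == ["g1"]

    def test_complete_rows_retained(self):
        em, removed = filter_missing(self.make_em(np.ones((3, 4))))
        assert removed == [] and em.values.shape == (3, 4)

    def test_all_rows_removed_errors(self):
        vals = np.full((2, 4), np.nan)
        vals[:, 0] = 1.0  # 75 % missing everywhere
        with pytest.raises(ValueError, match="every row"):
            filter_missing(self.make_em(vals))


def knn_impute_reference(X, k):
    """Exhaustive nearest-neighbor imputation oracle (plain loops)."""
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n = X.shape[0]
    for i in range(n):
        for j in range(X.shape[1]):
            if not np.isnan(X[i, j]):
                continue
            dists = []
            for r in range(n):
                if r == i or np.isnan(X[r, j]):
                    continue
                shared = [c for c in range(X.shape[1])
                          if not np.isnan(X[i, c]) and not np.isnan(X[r, c])]
                if not shared:
                    continue
                d = np.sqrt(sum((X[i, c] - X[r, c]) ** 2 for c in shared) / len(shared))
                dists.append((d, r))
            dists.sort(key=lambda t: t[0])
            nbrs = [r for _, r in dists[:k]]
            if nbrs:
                out[i, j] = np.mean([X[r, j] for r in nbrs])
            else:
                out[i, j] = np.nanmean(X[i])
    return out


class TestKnnImpute:
    def make_em(self, values):
        return ExpressionMatrix(toy_matrix(values), stage="missing_filtered")

    def test_no_missing_is_identity(self, rng):
        vals = rng.normal(size=(6, 4))
        out = knn_impute(self.make_em(vals))
        assert np.array_equal(out.values.to_numpy(), vals)

    def test_two_equal_nearest_rows(self):
        # target row is closest to rows 1 and 2, both holding v=7 at column 3
        vals = np.array([
            [1.0, 2.0, 3.0, np.nan],
            [1.0, 2.0, 3.1, 7.0],
            [1.0, 2.0, 2.9, 7.0],
            [9.0, 9.0, 9.0, 0.0],
            [9.5, 9.5, 9.5, 0.0],
        ])
        out = knn_impute(self.make_em(vals), k=2)
        assert out.values.iloc[0, 3] == pytest.approx(7.0)

    def test_k_exceeding_rows_uses_column_mean(self):
        vals = np.array([
            [0.0, 0.0, np.nan],
            [0.1, 0.0, 4.0],
            [0.0, 0.1, 6.0],
        ])
        out = knn_impute(self.make_em(vals), k=50)
        assert out.values.iloc[0, 2] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_reference_on_5x4(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(5, 4))
        mask = rng.random((5, 4)) < 0.25
        mask[mask.all(axis=1)] = False
        vals[mask] = np.nan
        expected = knn_impute_reference(vals, k=2)
        out = knn_impute(self.make_em(vals), k=2)
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-12)

    def test_observed_values_never_altered(self, rng):
        vals = rng.normal(size=(8, 5))
        mask = rng.random((8, 5)) < 0.2
        vals_miss = vals.copy()
        vals_miss[mask] = np.nan
        out = knn_impute(self.make_em(vals_miss))
        np.testing.assert_array_equal(out.values.to_numpy()[~mask], vals_miss[~mask])
        assert out.n_missing == 0


class TestCollapse:
    def make_em(self, values, genes=None):
        return ExpressionMatrix(toy_matrix(values, genes=genes), level="probe", stage="imputed")

    def test_single_probe_identity(self):
        em = self.make_em([[1.0, 2.0], [3.0, 4.0]])
        ann = pd.Series(["GA", "GB"], index=["g0", "g1"])
        out = collapse_probes(em, ann)
        assert list(out.values.index) == ["GA", "GB"]
        assert out.values.loc["GA"].tolist() == [1.0, 2.0]

    def test_per_sample_max(self):
        em = self.make_em([[1.0, 5.0], [2.0, 4.0]])
        ann = pd.Series(["GA", "GA"], index=["g0", "g1"])
        out = collapse_probes(em, ann)
        assert out.values.loc["GA"].tolist() == [2.0, 5.0]

    def test_unique_symbol_count(self, rng):
        vals = rng.normal(size=(12, 3))
        symbols = [f"G{i % 10}" for i in range(12)]  # 12 probes -> 10 symbols
        em = self.make_em(vals)
        ann = pd.Series(symbols, index=em.values.index)
        out = collapse_probes(em, ann)
        assert out.values.shape[0] == 10

    def test_empty_annotation_errors(self):
        em = self.make_em([[1.0]])
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(em, pd.Series(dtype=object))


class TestMedianCenter:
    def make_em(self, values):
        return ExpressionMatrix(toy_matrix(values), stage="collapsed")

    def test_odd_row(self):
        out = median_center(self.make_em([[1.0, 2.0, 3.0]]))
        assert out.values.iloc[0].tolist() == [-1.0, 0.0, 1.0]

    def test_even_row_uses_middle_mean(self):
        out = median_center(self.make_em([[1.0, 2.0, 3.0, 10.0]]))
        assert out.values.iloc[0].tolist() == [-1.5, -0.5, 0.5, 7.5]

    def test_idempotent_and_order_preserving(self, rng):
        vals = rng.normal(size=(5, 6))
        once = median_center(self.make_em(vals))
        twice = median_center(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy())
        orders = np.argsort(vals, axis=1)
        np.testing.assert_array_equal(np.argsort(once.values.to_numpy(), axis=1), orders)

    def test_row_medians_zero(self, rng):
        out = median_center(self.make_em(rng.normal(size=(10, 7))))
        assert np.allclose(out.values.median(axis=1), 0.0, atol=1e-9)


class TestPipelineOrder:
    def test_stage_enforcement(self, rng):
        em = ExpressionMatrix(toy_matrix(rng.normal(size=(4, 3))), stage="raw")
        with pytest.raises(PipelineOrderError):
            knn_impute(em)
        with pytest.raises(PipelineOrderError):
            median_center(em)
        em2 = ExpressionMatrix(toy_matrix(rng.normal(size=(4, 3))), level="gene",
                               stage="imputed")
        with pytest.raises(PipelineOrderError):
            collapse_probes(em2, pd.Series(["A"] * 4, index=em2.values.index))

    def test_unoriented_matrix_rejected(self):
        pm = make_probe_matrix([[1.0] * 12] * 12)
        pm = filter_background(pm)
        with pytest.raises(PipelineOrderError):
            probe_to_expression(pm)

    def test_filter_then_impute_leaves_no_missing(self):
        cfg = SimulationConfig(seed=9, missing_rate=0.05)
        pm, truth = simulate_expression(cfg)
        em = preprocess_pipeline(pm, sample_meta=truth.samples)
        assert em.n_missing == 0


def test_noiseless_pipeline_recovers_truth():
    """With zero noise and no missingness the pipeline must return the planted
    matrix exactly (up to the gene-wise median centering it applies)."""
    cfg = SimulationConfig(seed=21, noise_sd=0.0, missing_rate=0.0)
    pm, truth = simulate_expression(cfg)
    em = preprocess_pipeline(pm, sample_meta=truth.samples)
    expected = truth.expression_truth.loc[em.values.index]
    expected = expected.sub(expected.median(axis=1), axis=0)
    np.testing.assert_allclose(em.values.to_numpy(), expected.to_numpy(), atol=1e-9)
    # only the sub-background genes may be lost
    lost = set(truth.expression_truth.index) - set(em.values.index)
    sub_genes = {p.rsplit("_", 1)[0] for p in truth.subbackground_probes}
    assert lost == sub_genes
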