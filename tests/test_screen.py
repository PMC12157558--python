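"""Plate statistics: QC filters, well aggregation, B-score median polish
(against a brute-force oracle), robust Z, replicate merging and the hit
calling / exclusion / categorization rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centroscreen import screen as scr
from centroscreen import synthetic as syn


def median_polish_oracle(mat, max_iter=10, tol=1e-6):
    """Naive two-way median polish + robust scaling, all wells as library."""
    x = np.array(mat, dtype=float)
    x = x - np.median(x)
    for _ in range(max_iter):
        rm = np.array([np.median(x[i, :]) for i in range(x.shape[0])])
        for i in range(x.shape[0]):
            x[i, :] -= rm[i]
        cm = np.array([np.median(x[:, j]) for j in range(x.shape[1])])
        for j in range(x.shape[1]):
            x[:, j] -= cm[j]
        if max(np.abs(rm).max(), np.abs(cm).max()) < tol:
            break
    resid = x.ravel()
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad if mad > 0 else resid.std(ddof=1)
    return x / scale


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

class TestQCFilter:
    def _toy(self):
        return pd.DataFrame({
            "solidity": [0.80, 0.80, 0.95, 0.95, 0.95, 0.95, 0.95,
                         0.95, 0.95, 0.95],
            "area_um2": [100, 100, 25, 100, 100, 100, 100, 100, 100, 100],
        })

    def test_toy_counts(self):
        kept, counts = scr.qc_filter_cells(self._toy())
        assert len(kept) == 7
        assert counts["n_low_solidity"].sum() == 2
        assert counts["n_low_area"].sum() == 1

    def test_boundary_values_retained(self):
        table = pd.DataFrame({"solidity": [0.85], "area_um2": [30.0]})
        kept, _ = scr.qc_filter_cells(table)
        assert len(kept) == 1

    def test_empty_table(self):
        empty = pd.DataFrame({"solidity": [], "area_um2": []})
        kept, counts = scr.qc_filter_cells(empty)
        assert len(kept) == 0
        assert counts["n_excluded"].sum() == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="solidity"):
            scr.qc_filter_cells(pd.DataFrame({"area_um2": [50.0]}))

    def test_idempotent(self):
        once, _ = scr.qc_filter_cells(self._toy())
        twice, _ = scr.qc_filter_cells(once)
        pd.testing.assert_frame_equal(once, twice)


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

class TestAggregateWells:
    def _setup(self):
        pm = pd.DataFrame({
            "plate": [0, 0], "row": [0, 0], "col": [0, 1],
            "well": ["A01", "A02"],
            "perturbation": ["g1", "g2"],
            "control_class": ["library", "library"],
        })
        cells = pd.DataFrame({
            "plate": [0, 0, 0], "row": [0, 0, 0], "col": [0, 0, 0],
            "clustering_score": [1.0, 2.0, 3.0],
            "spot_count": [40, 41, 42],
            "mean_norm_radial": [0.6, 0.7, 0.65],
            "area_um2": [100.0, 110.0, 120.0],
        })
        return cells, pm

    def test_mean_of_three_cells(self):
        cells, pm = self._setup()
        ws = scr.aggregate_wells(cells, pm)
        row = ws[(ws["col"] == 0)].iloc[0]
        assert row["mean_clustering_score"] == 2.0
        assert row["n_cells_pass_qc"] == 3

    def test_empty_well_flagged_missing(self):
        cells, pm = self._setup()
        ws = scr.aggregate_wells(cells, pm)
        empty = ws[ws["col"] == 1].iloc[0]
        assert empty["empty_well_flag"]
        assert np.isnan(empty["mean_clustering_score"])

    def test_orphan_cells_rejected(self):
        cells, pm = self._setup()
        cells.loc[0, "col"] = 7
        with pytest.raises(ValueError, match="no well"):
            scr.aggregate_wells(cells, pm)

    def test_screen_well_means_match_planted_truth(self):
        design = syn.design_screen(n_genes=20, rows=4, cols=6, n_hits=2,
                                   hit_effect=5.0, cells_per_well=200,
                                   seed=9, controls_per_class=1)
        cells, pm, truth = syn.simulate_screen(design)
        kept, _ = scr.qc_filter_cells(cells)
        ws = scr.aggregate_wells(kept, pm)
        merged = ws.merge(truth, on="perturbation")
        s_clu = design.well_mean_sd(design.clustering_cell_sd,
                                    design.clustering_well_sd)
        neutral = merged[~merged["is_hit"]]
        planted = merged[merged["is_hit"]
                         & (merged["effect_clustering"] != 0)]
        base = neutral["mean_clustering_score"].mean()
        for rec in planted.itertuples(index=False):
            shift = (rec.mean_clustering_score - base) / s_clu
            assert shift == pytest.approx(rec.effect_clustering, abs=2.0)


# --------------------------------------------------------------------------
# B-score
# --------------------------------------------------------------------------

class TestBScore:
    def test_pure_row_offset_removed(self):
        plate = np.zeros((8, 12))
        plate[3, :] += 2.0
        plate += np.arange(12) * 0.5  # column trend too
        lib = np.ones_like(plate, dtype=bool)
        # noise floor so the scale is finite
        rng = np.random.default_rng(0)
        plate += rng.normal(0, 0.05, plate.shape)
        b = scr.bscore_normalize(plate, lib)
        # all structure removed: B-scores are pure standardized noise
        assert np.abs(np.median(b, axis=1)).max() < 0.5
        assert np.abs(np.median(b, axis=0)).max() < 0.5

    def test_single_spiked_well_recovered(self):
        plate = np.zeros((8, 12))
        plate[2, 5] = 5.0
        lib = np.ones_like(plate, dtype=bool)
        b = scr.bscore_normalize(plate, lib)
        background = np.delete(b.ravel(), 2 * 12 + 5)
        assert np.allclose(background, 0.0, atol=1e-9)
        assert b[2, 5] == b.max()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(0, 1, (6, 8)) + rng.normal(0, 2, (6, 1)) \
            + rng.normal(0, 2, (1, 8))
        lib = np.ones_like(mat, dtype=bool)
        b = scr.bscore_normalize(mat, lib)
        oracle = median_polish_oracle(mat)
        np.testing.assert_allclose(b, oracle, atol=1e-9)

    def test_residual_medians_converged(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(0, 1, (16, 24))
        lib = np.ones_like(mat, dtype=bool)
        b, scale = scr.bscore_normalize(mat, lib, max_iter=50,
                                        return_scale=True)
        resid = b * scale
        assert np.abs(np.median(resid, axis=1)).max() < 1e-4
        assert np.abs(np.median(resid, axis=0)).max() < 1e-4

    def test_control_wells_scored_but_not_driving(self):
        plate = np.zeros((4, 6))
        lib = np.ones_like(plate, dtype=bool)
        lib[:, 0] = False  # control column
        plate[:, 0] = 50.0  # extreme controls
        rng = np.random.default_rng(1)
        plate[:, 1:] += rng.normal(0, 1, (4, 5))
        b = scr.bscore_normalize(plate, lib)
        # library wells stay on the noise scale, far below the controls
        assert np.abs(b[:, 1:]).max() < 6.0
        assert b[:, 0].min() > 10.0

    def test_degenerate_plate_rejected(self):
        plate = np.zeros((4, 4))
        with pytest.raises(ValueError, match="degenerate"):
            scr.bscore_normalize(plate, np.ones_like(plate, dtype=bool))


# --------------------------------------------------------------------------
# robust Z
# --------------------------------------------------------------------------

class TestRobustZ:
    def test_value_at_median_scores_zero(self):
        ref = np.arange(20.0)
        assert scr.robust_z(np.array([np.median(ref)]), ref)[0] == 0.0

    def test_normal_reference_consistency(self):
        rng = np.random.default_rng(12)
        ref = rng.standard_normal(10_000)
        z = scr.robust_z(ref, ref)
        assert -0.05 < z.mean() < 0.05
        assert 0.95 < z.std() < 1.05

    def test_constant_reference_sd_fallback(self):
        ref = np.ones(10)
        with pytest.raises(ValueError, match="zero spread"):
            scr.robust_z(np.array([1.0]), ref)
        ref[0] = 2.0  # MAD still 0, SD > 0
        with pytest.warns(UserWarning, match="MAD is 0"):
            z = scr.robust_z(np.array([2.0]), ref)
        assert np.isfinite(z[0])

    def test_too_few_reference_wells(self):
        with pytest.raises(ValueError, match="at least 8"):
            scr.robust_z(np.array([0.0]), np.arange(5.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(-100.0, 100.0))
    def test_affine_equivariance(self, a, b):
        """Shifting/scaling data and reference together leaves Z unchanged."""
        rng = np.random.default_rng(7)
        ref = rng.standard_normal(50)
        x = rng.standard_normal(5)
        z0 = scr.robust_z(x, ref)
        z1 = scr.robust_z(a * x + b, a * ref + b)
        np.testing.assert_allclose(z0, z1, atol=1e-9)


# --------------------------------------------------------------------------
# replicate merging
# --------------------------------------------------------------------------

class TestMergeReplicates:
    def _tables(self, z1, z2):
        t1 = pd.DataFrame({"perturbation": ["g"],
                           "z_clustering_score": [z1]})
        t2 = pd.DataFrame({"perturbation": ["g"],
                           "z_clustering_score": [z2]})
        return [t1, t2]

    def test_two_point_mean_and_sd(self):
        merged = scr.merge_replicates(self._tables(2.0, 4.0),
                                      metrics=("clustering_score",))
        assert merged["mean_z_clustering_score"].iloc[0] == 3.0
        assert merged["z_sd_clustering_score"].iloc[0] == pytest.approx(
            np.sqrt(2.0))

    def test_equal_replicates_zero_sd(self):
        merged = scr.merge_replicates(self._tables(1.5, 1.5),
                                      metrics=("clustering_score",))
        assert merged["z_sd_clustering_score"].iloc[0] == 0.0

    def test_single_replicate_sd_flagged(self):
        merged = scr.merge_replicates([self._tables(2.0, 0.0)[0]],
                                      metrics=("clustering_score",))
        assert merged["mean_z_clustering_score"].iloc[0] == 2.0
        assert np.isnan(merged["z_sd_clustering_score"].iloc[0])

    def test_mismatched_keys_rejected(self):
        t1 = pd.DataFrame({"perturbation": ["a"], "z_clustering_score": [1.0]})
        t2 = pd.DataFrame({"perturbation": ["b"], "z_clustering_score": [1.0]})
        with pytest.raises(ValueError, match="disagree"):
            scr.merge_replicates([t1, t2], metrics=("clustering_score",))


# --------------------------------------------------------------------------
# hit calling and categories
# --------------------------------------------------------------------------

def _ztable(mean_clu, sd_clu, mean_cnt=0.0, sd_cnt=0.1, cell_z=0.0):
    return pd.DataFrame({
        "perturbation": ["g"],
        "control_class": ["library"],
        "mean_z_clustering_score": [mean_clu],
        "z_sd_clustering_score": [sd_clu],
        "mean_z_spot_count": [mean_cnt],
        "z_sd_spot_count": [sd_cnt],
        "mean_z_n_cells": [cell_z],
        "z_sd_n_cells": [0.1],
    })


class TestCallHits:
    def test_consistent_strong_clustering_hit(self):
        out = scr.call_hits(_ztable(3.1, 0.4, cell_z=-1.0))
        row = out.iloc[0]
        assert row["is_hit"]
        assert row["clustering_direction"] == "clustered"
        assert not row["excluded"]

    def test_inconsistent_replicates_excluded(self):
        out = scr.call_hits(_ztable(3.0, 3.5))
        row = out.iloc[0]
        assert not row["is_hit"]
        assert "inconsistent:clustering_score" in row["exclusion_reasons"]

    def test_cytotoxic_excluded_regardless_of_metric(self):
        out = scr.call_hits(_ztable(4.0, 0.2, cell_z=-3.0))
        row = out.iloc[0]
        assert not row["is_hit"]
        assert "cytotoxic" in row["exclusion_reasons"]

    def test_cytotoxic_threshold_strict(self):
        # exactly -2.5 is not below the threshold
        out = scr.call_hits(_ztable(4.0, 0.2, cell_z=-2.5))
        assert out.iloc[0]["is_hit"]

    def test_subthreshold_not_a_hit(self):
        out = scr.call_hits(_ztable(2.0, 0.2))
        assert not out.iloc[0]["is_hit"]

    def test_dysmorphic_excess_exclusion(self):
        frac = pd.Series({"g": 0.8})
        out = scr.call_hits(_ztable(4.0, 0.2), qc_fail_frac=frac)
        row = out.iloc[0]
        assert not row["is_hit"]
        assert "dysmorphic-excess" in row["exclusion_reasons"]

    def test_order_independent(self):
        tab = pd.concat([
            _ztable(3.1, 0.4), _ztable(-3.0, 0.2), _ztable(0.5, 0.1),
        ], ignore_index=True)
        tab["perturbation"] = ["a", "b", "c"]
        fwd = scr.call_hits(tab)
        rev = scr.call_hits(tab.iloc[::-1].reset_index(drop=True))
        merged = fwd.merge(rev, on="perturbation", suffixes=("_f", "_r"))
        assert (merged["is_hit_f"] == merged["is_hit_r"]).all()


class TestCategorizeHits:
    def _hits(self, z_clu, z_cnt):
        tab = _ztable(z_clu, 0.2, mean_cnt=z_cnt, sd_cnt=0.2)
        return scr.categorize_hits(scr.call_hits(tab))

    def test_higher_overall_clustering(self):
        out = self._hits(3.0, -3.0)
        assert out.iloc[0]["category"] == "higher overall clustering"

    def test_overall_dispersion(self):
        out = self._hits(-3.0, 3.0)
        assert out.iloc[0]["category"] == "overall dispersion"

    def test_global_dispersion_local_clustering(self):
        out = self._hits(-3.0, -3.0)
        assert out.iloc[0]["category"] == (
            "global dispersion, local clustering into fewer larger clusters")

    def test_single_metric_categories(self):
        assert self._hits(3.0, 0.0).iloc[0]["category"] == "clustering-only"
        assert self._hits(0.0, 3.0).iloc[0]["category"] == "count-only"


# --------------------------------------------------------------------------
# end-to-end
# --------------------------------------------------------------------------

class TestAnalyzeScreen:
    def test_artifact_immunity(self):
        """Hit calls with and without plate artifacts agree on >= 95% of
        genes (B-score removes additive row/column effects)."""
        common = dict(n_genes=300, rows=16, cols=20, n_hits=15,
                      hit_effect=4.0, cells_per_well=100, seed=14)
        calls = {}
        for art in (0.0, 1.0):
            design = syn.design_screen(artifact_sd=art, **common)
            cells, pm, truth = syn.simulate_screen(design)
            res = scr.analyze_screen(cells, pm, rows=16, cols=20)
            calls[art] = res["hits"].set_index("perturbation")["is_hit"]
        agree = (calls[0.0] == calls[1.0]).mean()
        assert agree >= 0.95

    def test_lethal_controls_score_cytotoxic(self):
        design = syn.design_screen(n_genes=100, rows=8, cols=14,
                                   cells_per_well=150, seed=15,
                                   controls_per_class=2)
        cells, pm, _ = syn.simulate_screen(design)
        res = scr.analyze_screen(cells, pm, rows=8, cols=14)
        merged = res["z_merged"]
        lethal = merged[merged["control_class"] == "lethal"]
        assert (lethal["mean_z_n_cells"] < -2.5).all()

    def test_clustering_control_scores_high(self):
        design = syn.design_screen(n_genes=100, rows=8, cols=14,
                                   cells_per_well=150, seed=16,
                                   controls_per_class=2)
        cells, pm, _ = syn.simulate_screen(design)
        res = scr.analyze_screen(cells, pm, rows=8, cols=14)
        merged = res["z_merged"]
        pos = merged[merged["control_class"] == "clustering"]
        assert (pos["mean_z_clustering_score"] > 2.5).mean() >= 0.75
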