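import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_count_matrix, make_obs
from follimap.preprocess import (
    EmptyOutputError,
    QCParams,
    lognormalize,
    qc_cells,
    qc_doublets,
    qc_genes,
    qc_spots,
)


def _cells_fixture():
    """5 cells: one violating each rule in attribution order, one clean.

    Genes: mt (mito), hb (hemoglobin), bulk (everything else).
    """
    #              clean  mito   lowumi highumi hb
    mt_counts =   [10,    200,   10,    100,    10]
    hb_counts =   [2,     2,     1,     5,      100]
    bulk_counts = [988,   798,   139,   10895,  890]
    counts = np.array([mt_counts, hb_counts, bulk_counts])
    m = make_count_matrix(counts, gene_ids=["mt", "hb", "bulk"],
                          obs_ids=["clean", "mito", "lowumi", "highumi", "hbhigh"])
    obs = make_obs(m.obs_ids)
    return m, obs


class TestCellQC:
    def test_one_violation_per_rule(self):
        m, obs = _cells_fixture()
        out, report = qc_cells(m, obs, QCParams(), ["mt"], ["hb"])
        assert out.obs_ids == ["clean"]
        assert report.n_dropped_by_rule == {"mito": 1, "umi_min": 1, "umi_max": 1, "hb": 1}
        assert report.check_conservation()

    def test_mito_boundary_is_strict(self):
        # 10% exactly survives, above is dropped
        counts = np.array([[100, 150], [900, 850]])
        m = make_count_matrix(counts, gene_ids=["mt", "bulk"], obs_ids=["at", "above"])
        out, _ = qc_cells(m, make_obs(m.obs_ids), QCParams(), ["mt"], [])
        assert out.obs_ids == ["at"]

    def test_umi_boundaries_are_strict(self):
        totals = [150, 200, 10_000, 10_001]
        counts = np.array([totals])
        m = make_count_matrix(counts, gene_ids=["bulk"],
                              obs_ids=["drop_low", "keep_low", "keep_high", "drop_high"])
        out, rep = qc_cells(m, make_obs(m.obs_ids), QCParams(), [], [])
        assert out.obs_ids == ["keep_low", "keep_high"]
        assert rep.n_dropped_by_rule == {"mito": 0, "umi_min": 1, "umi_max": 1, "hb": 0}

    def test_overlapping_gene_classes_rejected(self):
        m, obs = _cells_fixture()
        with pytest.raises(ValueError, match="disjoint"):
            qc_cells(m, obs, QCParams(), ["mt"], ["mt"])

    def test_empty_output_is_error(self):
        counts = np.array([[50, 60]])
        m = make_count_matrix(counts)
        with pytest.raises(EmptyOutputError):
            qc_cells(m, make_obs(m.obs_ids), QCParams(), [], [])

    def test_idempotent(self, scrna_sim):
        m, obs, truth = scrna_sim
        p = QCParams()
        once, _ = qc_cells(m, obs, p, ["mt-Sim1"], ["Hba-s1"])
        twice, rep = qc_cells(once, obs.subset(once.obs_ids), p, ["mt-Sim1"], ["Hba-s1"])
        assert once.obs_ids == twice.obs_ids and rep.n_out == rep.n_in

    def test_loosening_thresholds_never_shrinks_output(self, scrna_sim):
        m, obs, _ = scrna_sim
        tight, _ = qc_cells(m, obs, QCParams(mito_max=0.06, umi_min=800), ["mt-Sim1"], [])
        loose, _ = qc_cells(m, obs, QCParams(mito_max=0.20, umi_min=200), ["mt-Sim1"], [])
        assert set(tight.obs_ids) <= set(loose.obs_ids)


class TestGeneQC:
    def test_detection_boundary(self):
        counts = np.array(
            [
                [1, 1, 0, 0],  # 2 cells -> dropped
                [1, 1, 1, 0],  # exactly 3 -> kept
                [0, 0, 0, 0],  # all-zero -> dropped
                [5, 5, 5, 5],
            ]
        )
        m = make_count_matrix(counts)
        out, rep = qc_genes(m, QCParams())
        assert out.gene_ids == ["g1", "g3"]
        assert rep.n_dropped_by_rule == {"min_cells": 2}

    def test_constructed_survivor_count(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((10, 20), dtype=int)
        for g in range(6):  # 6 genes in >= 3 cells
            counts[g, rng.choice(20, 4, replace=False)] = 1
        for g in range(6, 10):  # 4 genes below threshold
            counts[g, rng.choice(20, 2, replace=False)] = 1
        out, _ = qc_genes(make_count_matrix(counts), QCParams())
        assert out.n_genes == 6


class TestDoubletQC:
    def test_exact_count_removed_highest_scores(self):
        ids = [f"c{i:03d}" for i in range(100)]
        scores = np.linspace(0, 0.99, 100)
        obs = make_obs(ids, doublet_score=scores)
        kept, rep = qc_doublets(obs, QCParams())
        assert rep.n_dropped_by_rule["doublet"] == 6
        assert set(rep.dropped["doublet"]) == set(ids[-6:])

    def test_ties_broken_by_barcode_order(self):
        ids = [f"c{i:03d}" for i in range(100)]
        obs = make_obs(ids, doublet_score=[0.5] * 100)
        kept, rep = qc_doublets(obs, QCParams())
        assert rep.dropped["doublet"] == ids[:6]

    def test_missing_scores_is_error(self):
        obs = make_obs(["a", "b"])
        with pytest.raises(ValueError, match="doublet_score"):
            qc_doublets(obs, QCParams())

    def test_planted_doublets_recovered_exactly(self, scrna_sim):
        m, obs, truth = scrna_sim
        kept, rep = qc_doublets(obs, QCParams())
        assert set(rep.dropped["doublet"]) == set(truth.doublet_ids())


class TestSpotQC:
    def _fixture(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(20, size=(4, 20))
        counts[:, :3] = 0
        counts[0, :3] = [10, 20, 30]  # 3 low-UMI spots
        ids = [f"s{i:02d}" for i in range(20)]
        m = make_count_matrix(counts, gene_ids=["bulk", "mt", "rp", "other"],
                              obs_ids=ids, obs_kind="spot")
        labels = ["tissue"] * 20
        labels[5] = labels[6] = "off_tissue"
        obs = make_obs(ids, obs_kind="spot", x=list(range(20)), y=[0] * 20, group_label=labels)
        return m, obs

    def test_low_umi_and_label_exclusion(self):
        m, obs = self._fixture()
        p = QCParams(spot_umi_min=50, spot_gene_min=2, exclude_spot_labels=("off_tissue",))
        out, rep = qc_spots(m, obs, p, ["mt"], ["rp"])
        assert out.n_obs == 15
        assert rep.n_dropped_by_rule["excluded_label"] == 2
        assert rep.n_dropped_by_rule["spot_umi"] == 3
        assert rep.check_conservation()

    def test_mito_and_ribo_genes_removed(self):
        m, obs = self._fixture()
        out, _ = qc_spots(m, obs, QCParams(spot_umi_min=50, spot_gene_min=2), ["mt"], ["rp"])
        assert "mt" not in out.gene_ids and "rp" not in out.gene_ids
        assert "bulk" in out.gene_ids


class TestLogNormalize:
    def test_spot_median_scaling(self):
        # totals {100, 200, 300}: median 200; count 10 in the 100-total spot -> ln(21)
        counts = np.array([[10, 40, 100], [90, 160, 200]])
        expr = lognormalize(make_count_matrix(counts, obs_kind="spot"), "spots")
        assert expr.scale_factor == 200
        assert np.isclose(expr.values[0, 0], np.log(21))

    def test_zero_count_maps_to_zero(self):
        counts = np.array([[0, 5], [10, 5]])
        expr = lognormalize(make_count_matrix(counts), "cells")
        assert expr.values[0, 0] == 0.0

    def test_cell_scale_factor(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1
        counts[1, 0] = 9999
        expr = lognormalize(make_count_matrix(counts), "cells")
        assert np.isclose(expr.values[0, 0], np.log(2))

    def test_zero_total_observation_is_error(self):
        counts = np.array([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="zero-total"):
            lognormalize(make_count_matrix(counts), "cells")

    @given(st.integers(1, 500), st.integers(0, 400))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_in_count(self, c1, c2):
        lo, hi = sorted({c1, c2 + 501})  # distinct counts, same observation total via filler gene
        total = 2000
        counts = np.array([[lo, hi], [total - lo, total - hi]])
        expr = lognormalize(make_count_matrix(counts), "cells")
        assert expr.values[0, 0] < expr.values[0, 1]
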