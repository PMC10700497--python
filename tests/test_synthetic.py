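import filecmp

import numpy as np
import pytest
from scipy import stats

from follimap.io_formats import write_count_matrix
from follimap.markers import build_gene_sets
from follimap.mia import mia_map
from follimap.preprocess import lognormalize
from follimap.synthetic import (
    LRChannel,
    SimConfig,
    default_config,
    generate_lr_channels,
    generate_scrna,
    generate_st,
    read_truth,
    write_truth,
)


class TestConfigValidation:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(cell_types={"A": 0.5, "B": 0.2})

    def test_too_many_markers_for_gene_panel(self):
        with pytest.raises(ValueError, match="too small"):
            generate_scrna(default_config(n_genes=50))

    def test_channel_with_unknown_type_rejected(self):
        ch = LRChannel("p", "L", "NoSuchType", "R", "TFC-1", (1.0,) * 4)
        with pytest.raises(ValueError, match="unknown cell type"):
            default_config(lr_channels=(ch,))

    def test_effect_schedule_length_must_match_time_points(self):
        ch = LRChannel("p", "L", "TFC-1", "R", "TFC-2", (1.0, 2.0))
        with pytest.raises(ValueError, match="effects"):
            default_config(lr_channels=(ch,))


class TestScrnaGeneration:
    def test_dimensions_follow_config(self, sim_cfg, scrna_sim):
        m, obs, truth = scrna_sim
        assert m.n_obs == sim_cfg.n_cells_per_timepoint * len(sim_cfg.time_points)
        assert m.n_genes == sim_cfg.n_genes
        assert obs.matches(m)

    def test_doublet_count_is_planted_exactly(self):
        cfg = default_config(seed=3, n_cells_per_timepoint=250, n_genes=600, doublet_rate=0.06)
        _, obs, truth = generate_scrna(cfg)
        assert truth.obs.is_doublet.sum() == 60  # round(0.06 * 250) per time point
        assert (obs.table.loc[truth.obs.is_doublet.values, "doublet_score"] == 1.0).all()
        assert (obs.table.loc[~truth.obs.is_doublet.values, "doublet_score"] < 0.5).all()

    def test_same_seed_gives_byte_identical_files(self, tmp_path, sim_cfg):
        for run in ("a", "b"):
            m, _, _ = generate_scrna(sim_cfg)
            write_count_matrix(m, str(tmp_path / run))
        assert filecmp.cmp(tmp_path / "a.mtx", tmp_path / "b.mtx", shallow=False)

    def test_planted_markers_elevated_in_their_type(self, scrna_sim, scrna_expr):
        """Recovery precondition: marker expression beats the rest (one-sided Wilcoxon)."""
        m, obs, truth = scrna_sim
        labels = obs.column("group_label").reindex(scrna_expr.obs_ids).to_numpy()
        for cell_type in ("TFC-1", "Macrophage"):
            in_group = labels == cell_type
            for gene in truth.markers_of(cell_type)[:5]:
                vals = scrna_expr.gene_values(gene)
                p = stats.mannwhitneyu(vals[in_group], vals[~in_group], alternative="greater").pvalue
                assert p < 1e-6

    def test_receptor_decays_across_time_in_receiver(self, scrna_sim, scrna_expr):
        """The flagship channel's receptor mean log-expression decreases with age."""
        m, obs, truth = scrna_sim
        tab = obs.table
        means = []
        for tp in ("d5", "d10", "d20", "d30"):
            sel = (tab.group_label == "TFC-1") & (tab.time_point == tp)
            means.append(scrna_expr.gene_values("Tnfrsf1a")[sel.to_numpy()].mean())
        assert all(a > b for a, b in zip(means, means[1:]))


class TestStGeneration:
    def test_spot_count_and_grid(self, sim_cfg, st_sim):
        m, obs, truth = st_sim
        assert m.n_obs == sim_cfg.n_spots
        assert {"x", "y"} <= set(obs.table.columns)

    def test_region_gene_higher_in_its_region(self, st_sim):
        m, obs, truth = st_sim
        expr = lognormalize(m, "spots")
        central = (obs.column("group_label").reindex(expr.obs_ids) == "central").to_numpy()
        gene = truth.genes_of_region("central")[0]
        vals = expr.gene_values(gene)
        p = stats.ttest_ind(vals[central], vals[~central], alternative="greater").pvalue
        assert p < 0.01

    def test_regions_required(self):
        with pytest.raises(ValueError, match="region"):
            generate_st(default_config(regions=()))

    def test_zero_shared_genes_breaks_correspondence(self):
        """Negative control: without shared genes the MIA link cannot be recovered."""
        cfg = default_config(
            seed=5, n_cells_per_timepoint=200, n_genes=600, n_spots=300,
            region_marker_share=0.0,
        )
        sc, sc_obs, _ = generate_scrna(cfg)
        st, st_obs, _ = generate_st(cfg)
        cell_sets = build_gene_sets(
            lognormalize(sc, "cells"), sc_obs.column("group_label"), p_threshold=1e-20
        )
        region_sets = build_gene_sets(
            lognormalize(st, "spots"), st_obs.column("group_label"), p_threshold=1e-3
        )
        result = mia_map(cell_sets, region_sets)
        scores = result.scores("enrichment")
        assert scores.loc["TFC-1", "central"] < 2.0
        assert scores.loc["TFC-2", "peripheral"] < 2.0


class TestChannelsAndTruth:
    def test_channel_schedule_recorded(self, sim_cfg, scrna_sim):
        _, _, truth = scrna_sim
        ch = truth.channels
        flagship = ch[(ch.pair_id == "P01")].sort_values("time_point", key=lambda s: s.map(
            {t: i for i, t in enumerate(sim_cfg.time_points)}))
        assert flagship["effect"].tolist() == [2.0, 1.5, 1.0, 0.5]

    def test_decoys_have_zero_effect(self, scrna_sim):
        _, _, truth = scrna_sim
        decoys = truth.channels[truth.channels.pair_id.str.startswith("D")]
        assert (decoys["effect"] == 0).all()

    def test_lr_database_contains_all_channels(self, sim_cfg):
        db = generate_lr_channels(sim_cfg)
        assert len(db) == len(sim_cfg.lr_channels)
        assert set(db.table.source) == {"planted", "decoy"}

    def test_truth_round_trips_through_tsv(self, tmp_path, st_sim):
        _, _, truth = st_sim
        write_truth(truth, str(tmp_path / "t"))
        back = read_truth(str(tmp_path / "t"))
        assert back.region_map == truth.region_map
        assert back.gene_roles.equals(truth.gene_roles)
        assert list(back.obs.is_doublet) == list(truth.obs.is_doublet)

    def test_each_marker_belongs_to_one_type(self, scrna_sim):
        _, _, truth = scrna_sim
        markers = truth.gene_roles[truth.gene_roles.role == "marker"]
        assert markers.gene_id.is_unique
        assert (markers.groupby("gene_id").target.nunique() == 1).all()
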