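import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_expression
from follimap.markers import (
    avg_log_fc,
    bh_adjust,
    build_gene_sets,
    exact_rank_sum_p,
    ttest_group_vs_rest,
    wilcoxon_group_vs_rest,
)


def brute_force_bh(p):
    """Step-up definition: adj_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj[order[rank - 1]] = min(1.0, running)
    return adj


def _two_group_expr(x, y):
    values = np.array([np.concatenate([x, y])])
    expr = make_expression(values)
    labels = pd.Series(
        ["g"] * len(x) + ["r"] * len(y), index=expr.obs_ids
    )
    return expr, labels


class TestWilcoxon:
    def test_balanced_interleaved_ranks_give_p_one(self):
        # group ranks {1,4} vs rest {2,3}: rank-sum 5 equals its expectation
        expr, labels = _two_group_expr([1.0, 4.0], [2.0, 3.0])
        res = wilcoxon_group_vs_rest(expr, labels, "g")
        assert res.table["p_value"].iloc[0] == 1.0

    def test_fully_tied_values_give_p_one(self):
        expr, labels = _two_group_expr([2.0, 2.0, 2.0], [2.0, 2.0])
        res = wilcoxon_group_vs_rest(expr, labels, "g")
        assert res.table["p_value"].iloc[0] == 1.0

    def test_planted_marker_reaches_deep_significance(self, scrna_sim, scrna_expr):
        m, obs, truth = scrna_sim
        res = wilcoxon_group_vs_rest(scrna_expr, obs.column("group_label"), "TFC-1")
        marker_p = res.table.loc[truth.markers_of("TFC-1"), "p_value"]
        assert (marker_p < 1e-20).all()

    def test_group_absent_is_error(self):
        expr, labels = _two_group_expr([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="absent"):
            wilcoxon_group_vs_rest(expr, labels, "nope")

    def test_exact_enumeration_is_symmetric_in_groups(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5), rng.normal(size=7)
        assert exact_rank_sum_p(x, y) == pytest.approx(exact_rank_sum_p(y, x), abs=1e-12)


class TestTTest:
    def test_equal_means_gives_t_zero_p_one(self):
        expr, labels = _two_group_expr([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        res = ttest_group_vs_rest(expr, labels, "g")
        assert res.table["statistic"].iloc[0] == pytest.approx(0.0)
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_all_zero_groups_flagged_degenerate(self):
        expr, labels = _two_group_expr([0.0, 0.0], [0.0, 0.0])
        res = ttest_group_vs_rest(expr, labels, "g")
        assert res.table["p_value"].iloc[0] == 1.0
        assert "degenerate" in res.note

    def test_planted_region_gene_significant_in_st(self, st_sim):
        from follimap.preprocess import lognormalize

        m, obs, truth = st_sim
        expr = lognormalize(m, "spots")
        res = ttest_group_vs_rest(expr, obs.column("group_label"), "central")
        region_p = res.table.loc[truth.genes_of_region("central"), "p_value"]
        assert (region_p < 0.001).all()


class TestAvgLogFC:
    def test_difference_of_means(self):
        expr, labels = _two_group_expr([2.0, 2.0], [1.5, 1.5])
        assert avg_log_fc(expr, labels, "g").iloc[0] == pytest.approx(0.5)

    def test_identical_groups_zero_and_antisymmetry(self):
        expr, labels = _two_group_expr([1.0, 3.0], [1.0, 3.0])
        assert avg_log_fc(expr, labels, "g").iloc[0] == pytest.approx(0.0)
        expr2, labels2 = _two_group_expr([1.0, 2.0], [3.0, 5.0])
        fwd = avg_log_fc(expr2, labels2, "g").iloc[0]
        rev = avg_log_fc(expr2, labels2, "r").iloc[0]
        assert fwd == pytest.approx(-rev)


class TestBH:
    def test_uniform_ladder_collapses(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value(self):
        assert bh_adjust([1.0]).tolist() == [1.0]

    def test_adjusted_at_least_raw_and_permutation_stable(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.max(np.abs(bh_adjust(p) - brute_force_bh(p))) < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBuildGeneSets:
    def test_marker_recovery_and_exclusivity(self, scrna_sim, scrna_expr):
        """Each well-powered type's set holds >=90% of its planted markers and
        none of any other type's markers."""
        m, obs, truth = scrna_sim
        sets = build_gene_sets(scrna_expr, obs.column("group_label"),
                               test="ttest", p_threshold=1e-20)
        for cell_type in ("TFC-1", "TFC-2", "Macrophage", "Fibroblast"):
            planted = set(truth.markers_of(cell_type))
            got = set(sets[cell_type].genes)
            assert len(got & planted) / len(planted) >= 0.9
            for other in sets.names():
                if other != cell_type:
                    assert not (set(sets[other].genes) & planted)

    def test_region_set_sensitivity(self, st_sim):
        from follimap.preprocess import lognormalize

        m, obs, truth = st_sim
        sets = build_gene_sets(lognormalize(m, "spots"), obs.column("group_label"),
                               test="ttest", p_threshold=1e-3, modality="ST")
        for region in ("central", "peripheral"):
            planted = set(truth.genes_of_region(region))
            got = set(sets[region].genes)
            assert len(got & planted) / len(planted) >= 0.9

    def test_nonpositive_threshold_is_error(self, scrna_sim, scrna_expr):
        m, obs, _ = scrna_sim
        with pytest.raises(ValueError, match="positive"):
            build_gene_sets(scrna_expr, obs.column("group_label"), p_threshold=-1.0)

    def test_invariant_to_observation_and_gene_order(self, scrna_sim, scrna_expr):
        m, obs, _ = scrna_sim
        labels = obs.column("group_label")
        base = build_gene_sets(scrna_expr, labels, p_threshold=1e-20)
        rng = np.random.default_rng(0)
        perm_obs = rng.permutation(scrna_expr.n_obs)
        perm_genes = rng.permutation(scrna_expr.n_genes)
        from follimap.preprocess import ExpressionMatrix

        shuffled = ExpressionMatrix(
            [scrna_expr.gene_ids[i] for i in perm_genes],
            [scrna_expr.obs_ids[i] for i in perm_obs],
            scrna_expr.values[perm_genes][:, perm_obs],
            scrna_expr.scale_factor,
        )
        other = build_gene_sets(shuffled, labels, p_threshold=1e-20)
        for name in base.names():
            assert set(base[name].genes) == set(other[name].genes)

    def test_only_positive_logfc_genes_enter_sets(self, scrna_sim, scrna_expr):
        m, obs, _ = scrna_sim
        sets = build_gene_sets(scrna_expr, obs.column("group_label"), p_threshold=1e-20)
        res = {name: ttest_group_vs_rest(scrna_expr, obs.column("group_label"), name)
               for name in sets.names()}
        for name in sets.names():
            fc = res[name].table.loc[sets[name].genes, "avg_log_fc"]
            assert (fc > 0).all()


@pytest.mark.parametrize("group", ["TFC-1"])
def test_wilcoxon_cross_check_against_scanpy(scrna_sim, scrna_expr, group):
    """Independent route: scanpy's tie-corrected rank-sum z-scores should agree."""
    sc = pytest.importorskip("scanpy")
    import anndata as ad

    m, obs, truth = scrna_sim
    adata = ad.AnnData(X=scrna_expr.dense().T.astype(np.float32))
    adata.var_names = scrna_expr.gene_ids
    adata.obs_names = scrna_expr.obs_ids
    adata.obs["label"] = obs.column("group_label").reindex(scrna_expr.obs_ids).to_numpy()
    sc.tl.rank_genes_groups(adata, "label", groups=[group], method="wilcoxon",
                            tie_correct=True, rankby_abs=True)
    sc_scores = pd.Series(
        np.asarray(adata.uns["rank_genes_groups"]["scores"][group], dtype=float),
        index=[str(n[0]) for n in adata.uns["rank_genes_groups"]["names"]],
    )
    res = wilcoxon_group_vs_rest(scrna_expr, obs.column("group_label"), group)
    # translate both to |z|; scanpy reports z directly, ours via the two-sided p
    ours_absz = pd.Series(
        stats.norm.isf(np.clip(res.table["p_value"], 1e-280, 1.0) / 2.0),
        index=res.table.index,
    )
    common = [g for g in truth.markers_of(group)[:10]]
    for g in common:
        assert abs(abs(sc_scores[g]) - ours_absz[g]) < 0.1 * abs(sc_scores[g]) + 0.6
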