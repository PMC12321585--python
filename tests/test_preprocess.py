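"""Normalization/scaling conventions, DE statistics and label transfer."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import clonodyn as cd
from clonodyn.preprocess import DETable, highly_variable_genes

from conftest import make_adata


def exact_ranksum_p(a, b):
    """Independent oracle: exact two-sided rank-sum p by enumerating all
    assignments of the pooled sample to the two groups (midranks for ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(c)].sum() - n1 * (n1 + 1) / 2
            for c in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    p_ge = np.mean(us >= u_obs - 1e-9)
    p_le = np.mean(us <= u_obs + 1e-9)
    return min(1.0, 2 * min(p_ge, p_le))


class TestNormalize:
    def test_depth_invariance(self):
        """Two cells with proportional count vectors normalize identically."""
        adata = make_adata([[1, 3, 0], [2, 6, 0]], normalize=False)
        adata = cd.normalize_counts(adata, target_depth=4)
        np.testing.assert_allclose(adata.layers["normalized"][0], adata.layers["normalized"][1])

    def test_hand_computed_two_gene_cell(self):
        """Counts (1,3) at target depth 4: scale factor 1, so log1p(1), log1p(3)."""
        adata = make_adata([[1, 3]], normalize=False)
        adata = cd.normalize_counts(adata, target_depth=4)
        np.testing.assert_allclose(
            adata.layers["normalized"][0], [np.log1p(1), np.log1p(3)]
        )

    def test_all_zero_gene_stays_zero(self):
        adata = make_adata([[1, 0], [3, 0]], normalize=False)
        adata = cd.normalize_counts(adata, target_depth=10)
        assert np.all(adata.layers["normalized"][:, 1] == 0)

    def test_zero_depth_cell_excluded_with_warning(self):
        adata = make_adata([[1, 2], [0, 0]], normalize=False)
        with pytest.warns(UserWarning, match="zero total counts"):
            adata = cd.normalize_counts(adata)
        assert adata.n_obs == 1

    def test_recomputation_from_recorded_params_is_exact(self):
        adata = make_adata(np.random.default_rng(0).poisson(2, (20, 10)), normalize=False)
        adata = cd.normalize_counts(adata)
        target = adata.uns["normalization"]["target_depth"]
        counts = adata.layers["counts"].astype(float)
        redo = np.log1p(counts * (target / counts.sum(axis=1))[:, None])
        np.testing.assert_array_equal(redo, adata.layers["normalized"])


class TestScale:
    def test_constant_gene_maps_to_zero(self):
        adata = make_adata([[2, 5], [2, 1]], normalize=False)
        adata.layers["normalized"] = np.array([[1.0, 0.0], [1.0, 2.0]])
        adata = cd.scale_genes(adata)
        assert np.all(adata.layers["scaled"][:, 0] == 0)

    def test_two_value_gene_population_sd(self):
        """Values (0, 2): population SD 1, so scaled (-1, +1) by convention."""
        adata = make_adata([[0], [2]], normalize=False)
        adata.layers["normalized"] = np.array([[0.0], [2.0]])
        adata = cd.scale_genes(adata)
        np.testing.assert_allclose(adata.layers["scaled"][:, 0], [-1.0, 1.0])

    def test_clipping(self):
        adata = make_adata([[0]] * 10, normalize=False)
        vals = np.zeros((10, 1))
        vals[0, 0] = 50.0  # extreme outlier, > 2 population SDs
        adata.layers["normalized"] = vals
        adata = cd.scale_genes(adata, clip=2.0)
        assert adata.layers["scaled"].max() == 2.0


class TestMitoticThreshold:
    def test_max_of_mitotic_clusters(self):
        cells = pd.DataFrame(
            {"cluster": ["M", "M", "P"], "pseudotime": [0.1, 0.4, 0.9]},
            index=["a", "b", "c"],
        )
        cutoff, post = cd.mitotic_threshold(cells, ["M"])
        assert cutoff == 0.4
        assert list(post) == [False, False, True]

    def test_all_cells_mitotic(self):
        cells = pd.DataFrame(
            {"cluster": ["M", "M"], "pseudotime": [0.2, 0.5]}, index=["a", "b"]
        )
        cutoff, post = cd.mitotic_threshold(cells, ["M"])
        assert post.sum() == 0

    def test_recovers_simulated_cutoff(self, model, uniform_cells):
        """Estimated cutoff sits just below the true boundary at large n."""
        cells, _ = uniform_cells
        cutoff, _ = cd.mitotic_threshold(cells, ["AP", "BP"])
        assert cutoff <= model.mitotic_cutoff
        assert cutoff == pytest.approx(model.mitotic_cutoff, abs=0.01)

    def test_empty_cluster_set_rejected(self, uniform_cells):
        cells, _ = uniform_cells
        with pytest.raises(ValueError):
            cd.mitotic_threshold(cells, [])


class TestComposition:
    def test_rows_sum_to_one(self, uniform_cells):
        cells, _ = uniform_cells
        comp = cd.state_composition(cells, "cohort", "broad_state")
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-12)

    def test_trivial_half_half(self):
        cells = pd.DataFrame(
            {"g": ["x"] * 4, "s": ["A", "A", "B", "B"]}, index=list("abcd")
        )
        comp = cd.state_composition(cells, "g", "s")
        assert comp.loc["x", "A"] == 0.5 and comp.loc["x", "B"] == 0.5


class TestPseudobulkCorrelation:
    def test_identical_and_anticorrelated_groups(self):
        adata = make_adata(np.zeros((4, 3), int), normalize=False)
        adata.layers["normalized"] = np.array(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [3.0, 2.0, 1.0]]
        )
        cells = pd.DataFrame({"grp": ["a", "a", "b", "b"]}, index=adata.obs_names)
        corr = cd.pseudobulk_correlation(adata, cells, "grp", list(adata.var_names))
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.loc["a", "a"] == pytest.approx(1.0)

    def test_small_gene_set_rejected(self, small_adata, uniform_cells):
        adata, _ = small_adata
        cells, _ = uniform_cells
        with pytest.raises(ValueError, match="3 genes"):
            cd.pseudobulk_correlation(adata, cells, "cluster", list(adata.var_names[:2]))

    def test_shared_programs_correlate_higher(self, model):
        """Stages sharing expression programs correlate above disjoint stages."""
        cohorts = [
            cd.CohortSpec(s, s, 0.0, 1.0, distribution="uniform")
            for s in ("s1", "s2", "s3")
        ]
        cells, _ = cd.simulate_cells(model, 1500, cohorts, seed=21)
        rng = np.random.default_rng(5)
        panel = []
        for j in range(60):  # s1/s2 share a program; s3 is its own world
            panel.append(
                cd.GeneArchetype(
                    "stage", 2.0, 2.0, stage_factors=(("s1", 4.0), ("s2", 4.0 if j % 2 else 1.0), ("s3", 1.0))
                )
            )
        for j in range(60):
            panel.append(
                cd.GeneArchetype("stage", 2.0, 2.0, stage_factors=(("s1", 1.0), ("s2", 1.0), ("s3", 4.0 if j % 2 else 1.0)))
            )
        adata, _ = cd.simulate_expression(cells, panel, seed=22)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adata = cd.normalize_counts(adata)
        corr = cd.pseudobulk_correlation(adata, adata.obs, "stage", list(adata.var_names))
        assert corr.loc["s1", "s2"] > corr.loc["s1", "s3"]


class TestRankSumDE:
    def test_matches_exact_enumeration_oracle(self):
        """Asymptotic p agrees with exhaustive enumeration for groups of 6-8.

        Continuous expression values (no ties): the documented regime for the
        normal approximation; heavy ties at smaller n degrade it.
        """
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(30):
            n1, n2 = rng.integers(6, 9, 2)
            adata = make_adata(np.ones((n1 + n2, 8), int), normalize=False)
            adata.layers["normalized"] = rng.gamma(2.0, 1.0, size=(n1 + n2, 8))
            a = list(adata.obs_names[:n1])
            b = list(adata.obs_names[n1:])
            de = cd.rank_sum_de(adata, a, b)
            norm = adata.layers["normalized"]
            for j, g in enumerate(adata.var_names):
                pe = exact_ranksum_p(norm[:n1, j], norm[n1:, j])
                worst = max(worst, abs(pe - de.table.loc[g, "pvalue"]))
        assert worst <= 0.02

    def test_null_calibration(self):
        """Exchangeable halves give ~5% raw rejections across genes."""
        rng = np.random.default_rng(8)
        adata = make_adata(rng.negative_binomial(2, 0.4, (120, 600)))
        a = list(adata.obs_names[:60])
        b = list(adata.obs_names[60:])
        de = cd.rank_sum_de(adata, a, b)
        rate = (de.table["pvalue"] < 0.05).mean()
        assert 0.02 <= rate <= 0.08

    def test_extreme_separation(self):
        counts = np.zeros((20, 2), int)
        counts[:10, 0] = 10  # gene 0 only in group a
        counts[:, 1] = 5
        adata = make_adata(counts)
        de = cd.rank_sum_de(adata, list(adata.obs_names[:10]), list(adata.obs_names[10:]))
        assert de.table.iloc[0]["log2fc"] > 1
        assert de.table.iloc[0]["pvalue"] < 1e-3

    def test_adjustment_properties(self):
        rng = np.random.default_rng(9)
        adata = make_adata(rng.poisson(3, (30, 200)) + 1)
        a, b = list(adata.obs_names[:15]), list(adata.obs_names[15:])
        bonf = cd.rank_sum_de(adata, a, b, adjust="bonferroni").table
        bh = cd.rank_sum_de(adata, a, b, adjust="BH").table
        m = len(bonf)
        np.testing.assert_allclose(bonf["padj"], np.minimum(bonf["pvalue"] * m, 1.0))
        assert (bh["padj"] >= bh["pvalue"] - 1e-12).all()
        s = bh.sort_values("pvalue")["padj"].to_numpy()
        assert np.all(np.diff(s) >= -1e-12)  # BH monotone in p order

    def test_group_validation(self, small_adata):
        adata, _ = small_adata
        ids = list(adata.obs_names[:6])
        with pytest.raises(ValueError, match="disjoint"):
            cd.rank_sum_de(adata, ids, ids)
        with pytest.raises(ValueError, match="method"):
            cd.rank_sum_de(adata, ids[:3], ids[3:], adjust="holm")


class TestMarkerIntersection:
    @staticmethod
    def _table(markers, genes):
        frame = pd.DataFrame(
            {"log2fc": [1.0 if g in markers else 0.0 for g in genes],
             "padj": [0.001 if g in markers else 0.9 for g in genes]},
            index=genes,
        )
        return frame

    def test_disjoint_and_identical_sets(self):
        genes = [f"g{i}" for i in range(10)]
        t1 = self._table({"g1", "g2"}, genes)
        t2 = self._table({"g8", "g9"}, genes)
        res = cd.marker_intersection({"a": t1, "b": t2})
        assert res["intersections"][("a", "b")]["size"] == 0
        res2 = cd.marker_intersection({"a": t1, "b": t1})
        assert res2["intersections"][("a", "b")]["genes"] == {"g1", "g2"}

    def test_triple_intersections_emitted(self):
        genes = [f"g{i}" for i in range(6)]
        t = self._table({"g0"}, genes)
        res = cd.marker_intersection({"x": t, "y": t, "z": t})
        assert res["intersections"][("x", "y", "z")]["size"] == 1


class TestLabelTransfer:
    def test_centroid_query_gets_its_label(self, small_adata):
        adata, _ = small_adata
        labels = adata.obs["broad_state"]
        hvg = highly_variable_genes(adata, 200)
        # build one query cell = exact AP centroid
        ap_centroid = np.asarray(adata.layers["normalized"])[
            (labels == "AP").to_numpy()
        ].mean(axis=0, keepdims=True)
        query = make_adata(np.zeros((1, adata.n_vars), int), normalize=False)
        query.var_names = adata.var_names
        query.layers["normalized"] = ap_centroid
        pred = cd.label_transfer(adata, labels, query)
        assert pred.iloc[0]["predicted"] == "AP"
        assert pred.iloc[0]["score"] > 0.95

    def test_noise_query_not_assigned(self, small_adata):
        adata, _ = small_adata
        rng = np.random.default_rng(1)
        query = make_adata(np.zeros((20, adata.n_vars), int), normalize=False)
        query.var_names = adata.var_names
        query.layers["normalized"] = rng.normal(size=(20, adata.n_vars))
        pred = cd.label_transfer(adata, adata.obs["broad_state"], query)
        assert (pred["predicted"] == "not assigned").mean() >= 0.9

    def test_truth_accuracy_on_separated_states(self, small_adata):
        """Branch tips are separated by marker programs: >= 90% recovered."""
        adata, _ = small_adata
        post = adata[adata.obs["branch_tip"].notna()].copy()
        labels = post.obs["branch_tip"]
        pred = cd.label_transfer(post, labels, post, min_score=0.0)
        assert (pred["predicted"] == labels).mean() >= 0.9
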