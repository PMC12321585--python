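"""Cohort shift test, weighted maturation score, and perturbation statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest

import clonodyn as cd

from conftest import make_adata


def manual_assignment(conditions, replicate="rep1"):
    """Build an assignment table directly (cell ids cond0, cond1, ...)."""
    return pd.DataFrame(
        {
            "condition": conditions,
            "guides": "manual",
            "replicate": replicate,
        },
        index=pd.Index([f"cell{i}" for i in range(len(conditions))], name="cell_id"),
    )


class TestCohortShift:
    def test_exact_tiny_instance(self):
        """Single observation per cohort: direction right, rank-sum p is 1."""
        cells = pd.DataFrame(
            {"cohort": ["a", "b"], "pseudotime": [0.1, 0.9]}, index=["x", "y"]
        )
        res = cd.cohort_pseudotime_shift(cells, "a", "b")
        assert res["direction"] == "b>a"
        assert res["pvalue"] == pytest.approx(1.0)

    def test_planted_shift_detected(self, model):
        cohorts = [
            cd.CohortSpec("early", "e", 0.4, 0.2),
            cd.CohortSpec("late", "l", 0.6, 0.2),
        ]
        for seed in range(5):
            cells, _ = cd.simulate_cells(model, 4000, cohorts, seed=seed)
            res = cd.cohort_pseudotime_shift(cells, "early", "late", subsample_n=2000, seed=seed)
            assert res["pvalue"] < 1e-4
            assert res["direction"] == "b>a"

    def test_null_rejection_rate_near_alpha(self, model):
        cohorts = [cd.CohortSpec("a", "s", 0.5, 0.2), cd.CohortSpec("b", "s", 0.5, 0.2)]
        hits = 0
        for seed in range(50):
            cells, _ = cd.simulate_cells(model, 600, cohorts, seed=1000 + seed)
            res = cd.cohort_pseudotime_shift(cells, "a", "b")
            hits += res["pvalue"] < 0.05
        assert hits <= 8  # ~Binomial(50, 0.05), generous upper bound

    def test_subsample_validation(self):
        cells = pd.DataFrame(
            {"cohort": ["a"] * 5 + ["b"] * 5, "pseudotime": np.arange(10.0)},
            index=[f"c{i}" for i in range(10)],
        )
        with pytest.raises(ValueError, match="smaller"):
            cd.cohort_pseudotime_shift(cells, "a", "b", subsample_n=6)


class TestWeightedScore:
    def test_one_hot_and_arithmetic(self):
        props = pd.DataFrame([[1.0, 0.0], [0.5, 0.5]], columns=["A", "B"],
                             index=["r1", "r2"])
        scores = cd.weighted_maturation_score(props, {"A": 0.7, "B": 0.2})
        assert scores["r1"] == pytest.approx(0.7)
        props2 = pd.DataFrame([[0.5, 0.5]], columns=["A", "B"], index=["r"])
        assert cd.weighted_maturation_score(props2, {"A": 1.0, "B": 3.0})["r"] == pytest.approx(2.0)

    def test_linear_and_order_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), size=3)
        props = pd.DataFrame(p, columns=list("ABCD"), index=["r1", "r2", "r3"])
        summ = {"A": 0.1, "B": 0.4, "C": 0.6, "D": 0.9}
        s1 = cd.weighted_maturation_score(props, summ)
        s2 = cd.weighted_maturation_score(props[list("DCBA")], summ)
        np.testing.assert_allclose(s1, s2)
        # linearity: score of an average of rows = average of scores
        mix = props.mean(axis=0).to_frame().T
        mix.index = ["mix"]
        assert cd.weighted_maturation_score(mix, summ)["mix"] == pytest.approx(s1.mean())

    def test_validation(self):
        props = pd.DataFrame([[0.6, 0.6]], columns=["A", "B"], index=["r"])
        with pytest.raises(ValueError, match="sum to 1"):
            cd.weighted_maturation_score(props, {"A": 1, "B": 2})
        good = pd.DataFrame([[0.5, 0.5]], columns=["A", "B"], index=["r"])
        with pytest.raises(ValueError, match="summary"):
            cd.weighted_maturation_score(good, {"A": 1})

    def test_host_stage_ordering_recovered(self, uniform_cells):
        """Late-host compositions score above early-host ones nearly always."""
        cells, _ = uniform_cells
        summ = cd.maturation.cluster_summary_pseudotime(cells)
        wins = 0
        for pair in range(30):
            late = cd.synthetic.simulate_replicate_proportions(
                summ.to_dict(), 0.6, 1, seed=2 * pair)
            early = cd.synthetic.simulate_replicate_proportions(
                summ.to_dict(), -0.6, 1, seed=2 * pair + 1)
            s_late = cd.weighted_maturation_score(late, summ).iloc[0]
            s_early = cd.weighted_maturation_score(early, summ).iloc[0]
            wins += s_late > s_early
        assert wins >= 29

    def test_median_vs_mean_summaries(self, uniform_cells):
        cells, _ = uniform_cells
        med = cd.maturation.cluster_summary_pseudotime(cells, summary="median")
        mean = cd.maturation.cluster_summary_pseudotime(cells, summary="mean")
        assert not np.allclose(med, mean)  # both available, different values
        with pytest.raises(ValueError):
            cd.maturation.cluster_summary_pseudotime(cells, summary="mode")


class TestAssignConditions:
    def test_rules(self):
        guides = pd.DataFrame(
            {
                "cell_id": ["c1", "c2", "c2", "c4"],
                "guide_id": ["sgNfib", "sgNfib", "sgLacZ", "sgLacZ"],
                "replicate": ["r1"] * 4,
            }
        )
        res = cd.assign_conditions(guides, ["sgNfib", "sgNfix"], ["sgLacZ"])
        assert res.loc["c1", "condition"] == "perturbed"
        assert res.loc["c2", "condition"] == "excluded"  # carries both classes
        assert res.loc["c4", "condition"] == "control"

    def test_no_recognized_guides_excluded(self):
        guides = pd.DataFrame({"cell_id": ["c1"], "guide_id": ["sgOther"]})
        res = cd.assign_conditions(guides, ["sgNfib"], ["sgLacZ"])
        assert res.loc["c1", "condition"] == "excluded"

    def test_overlapping_classes_rejected(self):
        guides = pd.DataFrame({"cell_id": ["c1"], "guide_id": ["sgA"]})
        with pytest.raises(ValueError, match="disjoint"):
            cd.assign_conditions(guides, ["sgA"], ["sgA"])


class TestProportionChange:
    @staticmethod
    def _cells(clusters):
        return pd.DataFrame(
            {"cluster": clusters},
            index=pd.Index([f"cell{i}" for i in range(len(clusters))], name="cell_id"),
        )

    def test_identical_composition_gives_zero(self):
        cells = self._cells(["X"] * 10 + ["Y"] * 10 + ["X"] * 10 + ["Y"] * 10)
        assignment = manual_assignment(["perturbed"] * 20 + ["control"] * 20)
        res = cd.proportion_change(assignment, cells)
        np.testing.assert_allclose(res.aggregated["mean"], 0.0, atol=1e-12)

    def test_halved_fraction_near_log10_half(self):
        # control: 100 X of 200; perturbed: 50 X of 150 -> ratio (1/3)/(1/2)
        clusters = ["X"] * 50 + ["Y"] * 100 + ["X"] * 100 + ["Y"] * 100
        assignment = manual_assignment(["perturbed"] * 150 + ["control"] * 200)
        res = cd.proportion_change(assignment, self._cells(clusters), pseudocount=1e-9)
        assert res.aggregated.loc["X", "mean"] == pytest.approx(np.log10((1 / 3) / 0.5), abs=1e-6)

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(1)
        clusters = list(rng.choice(["X", "Y", "Z"], 300))
        conds = ["perturbed"] * 150 + ["control"] * 150
        cells = self._cells(clusters)
        a1 = manual_assignment(conds)
        swapped = ["control" if c == "perturbed" else "perturbed" for c in conds]
        a2 = manual_assignment(swapped)
        r1 = cd.proportion_change(a1, cells)
        r2 = cd.proportion_change(a2, cells)
        np.testing.assert_allclose(
            r1.per_replicate["log10_ratio"].to_numpy(),
            -r2.per_replicate["log10_ratio"].to_numpy(),
        )

    def test_missing_condition_replicate_skipped(self):
        cells = self._cells(["X"] * 6)
        assignment = manual_assignment(["perturbed"] * 3 + ["control"] * 3)
        assignment.loc[:, "replicate"] = ["r1", "r1", "r2", "r1", "r1", "r1"]
        with pytest.warns(UserWarning, match="missing a condition"):
            res = cd.proportion_change(assignment, cells)
        assert set(res.per_replicate["replicate"]) == {"r1"}


class TestPerStateComparison:
    def test_planted_ap_only_shift_localized(self, uniform_cells):
        cells, _ = uniform_cells
        assignment, out, _ = cd.simulate_perturbation(
            cells, {}, ap_pseudotime_shift=-0.06, n_replicates=1, seed=9
        )
        table = cd.maturation.per_state_pseudotime_comparison(out, assignment)
        assert table.loc["AP", "pvalue"] < 0.001
        others = table.drop(index="AP")
        assert (others["pvalue"] > 0.001).all()

    def test_undersized_state_flagged(self):
        cells = pd.DataFrame(
            {"broad_state": ["AP"] * 8 + ["BP"] * 2,
             "pseudotime": np.linspace(0, 1, 10)},
            index=pd.Index([f"cell{i}" for i in range(10)], name="cell_id"),
        )
        assignment = manual_assignment(["perturbed", "control"] * 5)
        with pytest.warns(UserWarning, match="undersized"):
            table = cd.maturation.per_state_pseudotime_comparison(cells, assignment)
        assert bool(table.loc["BP", "skipped"])
        assert np.isnan(table.loc["BP", "pvalue"])


class TestDECountPerCluster:
    def test_planted_program_counted_in_target_cluster_only(self):
        rng = np.random.default_rng(5)
        n_per = 60
        clusters = ["AP"] * (2 * n_per) + ["BP"] * (2 * n_per)
        counts = rng.negative_binomial(4, 0.4, (4 * n_per, 120))
        # perturbed AP cells: first 20 genes doubled
        counts[:n_per, :20] *= 3
        adata = make_adata(counts)
        cells = pd.DataFrame({"cluster": clusters}, index=adata.obs_names)
        cells.index.name = "cell_id"
        conds = (["perturbed"] * n_per + ["control"] * n_per) * 2
        assignment = manual_assignment(conds)
        assignment.index = adata.obs_names
        table = cd.maturation.de_count_per_cluster(adata, cells, assignment)
        assert table.loc["AP", "n_de_genes"] >= 15
        assert table.loc["BP", "n_de_genes"] <= 2

    def test_null_counts_near_zero(self):
        rng = np.random.default_rng(6)
        counts = rng.negative_binomial(4, 0.4, (120, 150))
        adata = make_adata(counts)
        cells = pd.DataFrame({"cluster": ["C1"] * 120}, index=adata.obs_names)
        assignment = manual_assignment(["perturbed", "control"] * 60)
        assignment.index = adata.obs_names
        table = cd.maturation.de_count_per_cluster(adata, cells, assignment)
        assert table.loc["C1", "n_de_genes"] <= 1
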