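"""Extinction trajectories, loss curves, AUC, nulls and effect sizes."""

import numpy as np
import pytest

import funcsens as fs
from funcsens.extinction import cluster_null_aucs

from conftest import random_trait_table


def seq_trajectory(order):
    return fs.Trajectory(steps=tuple((s,) for s in order), scenario="custom")


def brute_force_greedy(tree, species, mode):
    """Independent per-step arg-min/arg-max oracle using the pool-tree FD."""
    remaining = sorted(species)
    order = []
    while len(remaining) > 1:
        losses = [
            (tree.functional_richness(remaining) - tree.functional_richness([r for r in remaining if r != s]), s)
            for s in remaining
        ]
        extreme = min(l for l, _ in losses) if mode == "best" else max(l for l, _ in losses)
        tol = 1e-12
        pick = next(s for l, s in losses if (l <= extreme + tol if mode == "best" else l >= extreme - tol))
        order.append(pick)
        remaining.remove(pick)
    return order


class TestLossCurve:
    def test_toy_worst_direction(self, toy_tree, toy_assemblage):
        curve = fs.loss_curve(toy_tree, toy_assemblage, seq_trajectory(["C", "A"]))
        np.testing.assert_allclose(curve.x, [0, 0.5, 1])
        np.testing.assert_allclose(curve.y, [1, 0.4 / 1.4, 0], atol=1e-12)

    def test_toy_best_direction(self, toy_tree, toy_assemblage):
        curve = fs.loss_curve(toy_tree, toy_assemblage, seq_trajectory(["A", "B"]))
        np.testing.assert_allclose(curve.y, [1, 1.2 / 1.4, 0], atol=1e-12)

    def test_two_species_curve(self, schema):
        rng = np.random.default_rng(0)
        table = random_trait_table(2, schema, rng)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        asm = fs.Assemblage(site_id="p", system="lake",
                            abundances={s: 1.0 for s in table.species})
        curve = fs.loss_curve(tree, asm, seq_trajectory([table.species[0]]))
        np.testing.assert_allclose(curve.x, [0, 1])
        np.testing.assert_allclose(curve.y, [1, 0])

    def test_per_species_axis_convention(self, toy_tree, toy_assemblage):
        curve = fs.loss_curve(toy_tree, toy_assemblage, seq_trajectory(["C", "A"]),
                              axis="per-species")
        np.testing.assert_allclose(curve.x, [0, 1 / 3, 2 / 3, 1])
        np.testing.assert_allclose(curve.y, [1, 0.4 / 1.4, 0, 0], atol=1e-12)

    def test_degenerate_assemblage_rejected(self, schema):
        import pandas as pd

        row = {
            "size": "0-8",
            "vertical_position": "benthic",
            "trophic_group": "omnivorous",
            "spawning_habitat": "lithophilic",
            "swimming_mode": "carangiform",
        }
        other = dict(row, size=">80.1")
        table = fs.TraitTable(pd.DataFrame([row, row, other], index=["a", "b", "c"]), schema)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        asm = fs.Assemblage(site_id="d", system="lake", abundances={"a": 1.0, "b": 1.0})
        with pytest.raises(fs.DegenerateAssemblageError):
            fs.loss_curve(tree, asm, seq_trajectory(["a"]))

    def test_curve_invariants_on_random_orders(self, schema):
        rng = np.random.default_rng(8)
        table = random_trait_table(12, schema, rng)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        asm = fs.Assemblage(site_id="x", system="river",
                            abundances={s: 1.0 for s in table.species})
        for _ in range(10):
            order = list(rng.permutation(table.species))[:-1]
            curve = fs.loss_curve(tree, asm, seq_trajectory(order))
            assert curve.x[0] == 0 and curve.y[0] == 1
            assert curve.x[-1] == 1 and curve.y[-1] == 0
            assert np.all(np.diff(curve.y) <= 1e-12)  # nested subsets: y decreases
            auc = fs.trapezoid_auc(curve)
            assert 0 <= auc <= 1


class TestAUC:
    def test_straight_line_is_half(self):
        curve = fs.LossCurve(x=np.array([0.0, 1.0]), y=np.array([1.0, 0.0]))
        assert fs.trapezoid_auc(curve) == pytest.approx(0.5)

    def test_toy_values(self, toy_tree, toy_assemblage):
        worst = fs.loss_curve(toy_tree, toy_assemblage, seq_trajectory(["C", "A"]))
        best = fs.loss_curve(toy_tree, toy_assemblage, seq_trajectory(["A", "B"]))
        assert fs.trapezoid_auc(worst) == pytest.approx(0.25 + 0.5 * (0.4 / 1.4), abs=1e-9)
        assert fs.trapezoid_auc(best) == pytest.approx(0.25 + 0.5 * (1.2 / 1.4), abs=1e-9)


class TestRandomNull:
    def test_toy_mean_converges_to_enumeration(self, toy_tree, toy_assemblage):
        oracle = fs.exhaustive_auc_oracle(toy_tree, toy_assemblage)
        assert oracle.mean == pytest.approx(3.5 / 6, abs=1e-12)
        aucs = fs.random_null_aucs(toy_tree, toy_assemblage, n=999, seed=0)
        se = oracle.sd_population / np.sqrt(len(aucs))
        assert abs(aucs.mean() - oracle.mean) < 3 * se

    def test_two_species_constant(self, schema):
        rng = np.random.default_rng(1)
        table = random_trait_table(2, schema, rng)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        asm = fs.Assemblage(site_id="p", system="lake",
                            abundances={s: 1.0 for s in table.species})
        aucs = fs.random_null_aucs(tree, asm, n=50, seed=3)
        np.testing.assert_allclose(aucs, 0.5, atol=1e-12)
        assert fs.redundancy_index(tree, asm, n=50, seed=3) == pytest.approx(0.5)

    def test_seed_determinism(self, toy_tree, toy_assemblage):
        a = fs.random_null_aucs(toy_tree, toy_assemblage, n=99, seed=7)
        b = fs.random_null_aucs(toy_tree, toy_assemblage, n=99, seed=7)
        np.testing.assert_array_equal(a, b)
        trajs_a = fs.random_trajectories(toy_assemblage, n=5, seed=7)
        trajs_b = fs.random_trajectories(toy_assemblage, n=5, seed=7)
        assert [t.steps for t in trajs_a] == [t.steps for t in trajs_b]

    def test_rejects_too_few_replicates(self, toy_tree, toy_assemblage):
        with pytest.raises(ValueError):
            fs.random_null_aucs(toy_tree, toy_assemblage, n=1, seed=0)

    def test_vectorised_null_matches_per_trajectory_curves(self, toy_tree, toy_assemblage):
        """Batch evaluator only ever produces AUCs that explicit curves produce."""
        possible = {round(a, 9) for a in fs.exhaustive_auc_oracle(toy_tree, toy_assemblage).aucs}
        batch = fs.random_null_aucs(toy_tree, toy_assemblage, n=500, seed=5)
        assert {round(a, 9) for a in batch} <= possible
        trajs = fs.random_trajectories(toy_assemblage, n=20, seed=5)
        explicit = {
            round(fs.trapezoid_auc(fs.loss_curve(toy_tree, toy_assemblage, t)), 9)
            for t in trajs
        }
        assert explicit <= possible


class TestGreedy:
    def test_toy_best_and_worst(self, toy_tree, toy_assemblage):
        best = fs.greedy_trajectory(toy_tree, toy_assemblage.species, "best")
        worst = fs.greedy_trajectory(toy_tree, toy_assemblage.species, "worst")
        assert best.steps[0] == ("A",)  # tie between A and B broken to A
        assert worst.steps[0] == ("C",)
        assert fs.trapezoid_auc(fs.loss_curve(toy_tree, toy_assemblage, best)) == pytest.approx(0.6786, abs=1e-4)
        assert fs.trapezoid_auc(fs.loss_curve(toy_tree, toy_assemblage, worst)) == pytest.approx(0.3929, abs=1e-4)

    @pytest.mark.parametrize("mode", ["best", "worst"])
    @pytest.mark.parametrize("seed", [2, 9, 17])
    def test_matches_brute_force_oracle(self, schema, mode, seed):
        rng = np.random.default_rng(seed)
        table = random_trait_table(8, schema, rng)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        species = table.species
        traj = fs.greedy_trajectory(tree, species, mode)
        assert [s for (s,) in traj.steps] == brute_force_greedy(tree, species, mode)

    def test_singular_species_removed_first_in_worst(self, schema):
        import pandas as pd

        base = {
            "size": "0-8",
            "vertical_position": "benthic",
            "trophic_group": "omnivorous",
            "spawning_habitat": "lithophilic",
            "swimming_mode": "carangiform",
        }
        rows = [dict(base), dict(base), dict(base, size="8.1-15")]
        singular = dict(
            base,
            size=">80.1",
            vertical_position="non-benthic",
            trophic_group="parasitic",
            spawning_habitat="pelagophilic",
            swimming_mode="rajiform",
        )
        table = fs.TraitTable(
            pd.DataFrame(rows + [singular], index=["a", "b", "c", "zsing"]), schema
        )
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        traj = fs.greedy_trajectory(tree, table.species, "worst")
        assert traj.steps[0] == ("zsing",)

    def test_bounds_vs_exhaustive_extremes(self, schema):
        rng = np.random.default_rng(4)
        table = random_trait_table(6, schema, rng)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        asm = fs.Assemblage(site_id="x", system="lake",
                            abundances={s: 1.0 for s in table.species})
        oracle = fs.exhaustive_auc_oracle(tree, asm)
        worst_auc = fs.trapezoid_auc(
            fs.loss_curve(tree, asm, fs.greedy_trajectory(tree, asm.species, "worst"))
        )
        best_auc = fs.trapezoid_auc(
            fs.loss_curve(tree, asm, fs.greedy_trajectory(tree, asm.species, "best"))
        )
        assert worst_auc >= oracle.min - 1e-12  # greedy bounded by global extremes
        assert best_auc <= oracle.max + 1e-12
        # empirical ordering: worst <= redundancy (mean) <= best
        assert worst_auc <= oracle.mean <= best_auc


class TestScoreRanked:
    def test_abundance_order_rarest_first(self, toy_assemblage):
        traj = fs.score_ranked_trajectory(toy_assemblage, toy_assemblage.abundances, "ascending")
        assert [s for (s,) in traj.steps] == ["A", "C"]  # B survives

    def test_vulnerability_descending(self, toy_assemblage):
        traj = fs.score_ranked_trajectory(
            toy_assemblage, {"A": 80, "B": 20, "C": 55}, "descending"
        )
        assert [s for (s,) in traj.steps] == ["A", "C"]

    def test_equal_scores_lexicographic(self, toy_assemblage):
        traj = fs.score_ranked_trajectory(toy_assemblage, {"A": 1, "B": 1, "C": 1}, "ascending")
        assert [s for (s,) in traj.steps] == ["A", "B"]

    def test_missing_score_lists_species(self, toy_assemblage):
        with pytest.raises(KeyError, match="C"):
            fs.score_ranked_trajectory(toy_assemblage, {"A": 1, "B": 2}, "ascending")


class TestIUCN:
    def test_cluster_order(self, toy_assemblage):
        traj = fs.iucn_cluster_trajectory(toy_assemblage, {"A": "CR", "B": "LC", "C": "LC"})
        assert traj.steps == (("A",), ("B", "C"))

    def test_all_least_concern_single_cluster(self, toy_tree, toy_assemblage):
        traj = fs.iucn_cluster_trajectory(toy_assemblage, {"A": "LC", "B": "LC", "C": "LC"})
        assert traj.steps == (("A", "B", "C"),)
        curve = fs.loss_curve(toy_tree, toy_assemblage, traj)
        np.testing.assert_allclose(curve.x, [0, 1])
        np.testing.assert_allclose(curve.y, [1, 0])

    def test_not_evaluated_folds_into_least_concern(self, toy_assemblage):
        traj = fs.iucn_cluster_trajectory(toy_assemblage, {"A": "NE", "B": "DD", "C": "EN"})
        assert traj.steps == (("C",), ("A", "B"))

    def test_unknown_category_rejected(self, toy_assemblage):
        with pytest.raises(ValueError):
            fs.iucn_cluster_trajectory(toy_assemblage, {"A": "XX", "B": "LC", "C": "LC"})


class TestClusterNull:
    def test_single_cluster_constant(self, toy_tree, toy_assemblage):
        aucs = cluster_null_aucs(toy_tree, toy_assemblage, [3], n=20, seed=0)
        np.testing.assert_allclose(aucs, aucs[0])

    def test_one_plus_rest_matches_enumeration(self, toy_tree, toy_assemblage):
        """Sizes [1, 2] on the toy: three equally likely first picks."""
        # enumerate: first pick A or B -> y after = FD(BC)=FD(AC)=1.2/1.4; pick C -> 0.4/1.4
        xs = np.array([0, 0.5, 1.0])
        auc_ab = np.trapezoid([1, 1.2 / 1.4, 0], xs)
        auc_c = np.trapezoid([1, 0.4 / 1.4, 0], xs)
        aucs = cluster_null_aucs(toy_tree, toy_assemblage, [1, 2], n=999, seed=2)
        vals = set(np.round(aucs, 9))
        assert vals == {round(auc_ab, 9), round(auc_c, 9)}
        frac_c = np.mean(np.isclose(aucs, auc_c))
        assert abs(frac_c - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 999)

    def test_seed_reproducibility(self, toy_assemblage):
        a = fs.random_cluster_trajectories(toy_assemblage, [1, 2], n=5, seed=4)
        b = fs.random_cluster_trajectories(toy_assemblage, [1, 2], n=5, seed=4)
        assert [t.steps for t in a] == [t.steps for t in b]

    def test_size_mismatch_rejected(self, toy_assemblage):
        with pytest.raises(ValueError):
            fs.random_cluster_trajectories(toy_assemblage, [1, 1], n=5, seed=0)


class TestSES:
    def test_zero_when_observed_equals_mean(self):
        assert fs.standardized_effect_size(0.5, [0.4, 0.5, 0.6]) == pytest.approx(0.0)

    def test_minus_one_at_one_sd(self):
        null = np.array([0.4, 0.5, 0.6])
        sd = np.std(null, ddof=1)
        assert fs.standardized_effect_size(0.5 - sd, null) == pytest.approx(-1.0)

    def test_toy_worst_case_vs_exhaustive_null(self, toy_tree, toy_assemblage):
        oracle = fs.exhaustive_auc_oracle(toy_tree, toy_assemblage)
        worst = fs.trapezoid_auc(
            fs.loss_curve(toy_tree, toy_assemblage,
                          fs.greedy_trajectory(toy_tree, toy_assemblage.species, "worst"))
        )
        ses = fs.standardized_effect_size(worst, oracle.aucs, ddof=0)
        assert ses == pytest.approx(-np.sqrt(2), abs=1e-6)

    def test_zero_sd_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fs.standardized_effect_size(0.4, [0.5, 0.5, 0.5])


class TestExhaustiveOracle:
    def test_two_species(self, schema):
        rng = np.random.default_rng(2)
        table = random_trait_table(2, schema, rng)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        oracle = fs.exhaustive_auc_oracle(tree, table.species)
        assert oracle.mean == oracle.min == oracle.max == pytest.approx(0.5)
        assert oracle.sd_population == pytest.approx(0.0)

    def test_refuses_large_assemblages(self, schema):
        rng = np.random.default_rng(2)
        table = random_trait_table(8, schema, rng)
        tree = fs.build_upgma_dendrogram(fs.gower_dissimilarity(table))
        with pytest.raises(ValueError):
            fs.exhaustive_auc_oracle(tree, table.species)


class TestTrajectoryValidation:
    def test_duplicate_removal_rejected(self):
        with pytest.raises(ValueError):
            fs.Trajectory(steps=(("A",), ("A",)))

    def test_derived_seeds_differ_between_sites(self):
        a = fs.derive_seed(1, "site_a").generate_state(4)
        b = fs.derive_seed(1, "site_b").generate_state(4)
        assert not np.array_equal(a, b)
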