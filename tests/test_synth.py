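import numpy as np
import pytest

from caenophylo.genefamily import infer_duplication_nodes
from caenophylo.genomestats import gene_structure_stats
from caenophylo.orthology import duplication_ratio
from caenophylo.synth import (
    SimulationConfig,
    sim_annotation_and_assembly,
    sim_brownian_traits,
    sim_discrete_character,
    sim_gene_family,
    sim_orthogroup_table,
    sim_species_tree,
)
from caenophylo.trees import write_newick


class TestSpeciesTree:
    def test_two_species_is_a_cherry(self):
        tree, _ = sim_species_tree(2, 1.0, seed=0)
        assert len(tree.leaves()) == 2
        assert len(tree.root.children) == 2

    def test_deterministic_under_seed(self):
        a, _ = sim_species_tree(32, 1.0, seed=42)
        b, _ = sim_species_tree(32, 1.0, seed=42)
        assert write_newick(a) == write_newick(b)

    def test_seed_changes_output(self):
        a, _ = sim_species_tree(16, 1.0, seed=1)
        b, _ = sim_species_tree(16, 1.0, seed=2)
        assert write_newick(a) != write_newick(b)

    def test_rejects_fewer_than_two(self):
        with pytest.raises(ValueError):
            sim_species_tree(1, 1.0)

    def test_positive_branch_lengths(self):
        tree, _ = sim_species_tree(20, 3.0, seed=5)
        assert all(
            (n.length or 0) > 0 for n in tree.preorder() if n is not tree.root
        )

    def test_doubling_birth_rate_halves_depth(self):
        # Yule height is proportional to 1/birth_rate in expectation
        def mean_depth(rate, seeds):
            vals = []
            for s in seeds:
                tree, _ = sim_species_tree(8, rate, seed=s)
                d = tree.depths()
                vals.append(np.mean([d[l] for l in tree.leaves()]))
            return float(np.mean(vals))

        seeds = range(500)
        m1 = mean_depth(1.0, seeds)
        m2 = mean_depth(2.0, seeds)
        assert m1 / m2 == pytest.approx(2.0, rel=0.15)


class TestDiscreteCharacter:
    def test_zero_rate_all_tips_share_root_state(self):
        tree, _ = sim_species_tree(10, 1.0, seed=0)
        tips, internals, n_trans = sim_discrete_character(tree, 0.0, 2, seed=1)
        assert n_trans == 0
        assert len(set(tips.values())) == 1

    def test_high_rate_approaches_stationary_uniform(self):
        tree, _ = sim_species_tree(4, 1.0, seed=0)
        props = []
        for s in range(1000):
            tips, _, _ = sim_discrete_character(tree, 50.0, 2, seed=s)
            props.append(np.mean(list(tips.values())))
        assert float(np.mean(props)) == pytest.approx(0.5, abs=0.03)

    def test_deterministic_under_seed(self):
        tree, _ = sim_species_tree(12, 1.0, seed=0)
        a = sim_discrete_character(tree, 0.7, 3, seed=9)
        b = sim_discrete_character(tree, 0.7, 3, seed=9)
        assert a[0] == b[0] and a[1] == b[1]

    def test_k_below_two_rejected(self):
        tree, _ = sim_species_tree(4, 1.0, seed=0)
        with pytest.raises(ValueError):
            sim_discrete_character(tree, 1.0, 1)


class TestBrownianTraits:
    def test_zero_variance_is_exact_linear_response(self):
        tree, _ = sim_species_tree(8, 1.0, seed=0)
        table, beta = sim_brownian_traits(tree, [10.0, 2.0], 0.0, seed=1)
        fitted = 10.0 + 2.0 * table["x1"].to_numpy()
        assert np.allclose(table["genome_size"].to_numpy(), fitted)

    def test_star_tree_residuals_uncorrelated(self):
        from caenophylo.trees import parse_newick

        star = parse_newick("(A:1,B:1,C:1,D:1);")
        resids = []
        for s in range(1000):
            table, _ = sim_brownian_traits(star, [0.0], 1.0, seed=s)
            resids.append(table["genome_size"].to_numpy())
        cov = np.cov(np.array(resids).T)
        off = cov[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.12
        assert np.allclose(np.diag(cov), 1.0, atol=0.15)

    def test_deterministic_under_seed(self):
        tree, _ = sim_species_tree(6, 1.0, seed=0)
        a, _ = sim_brownian_traits(tree, [1.0, 0.5], 2.0, seed=3)
        b, _ = sim_brownian_traits(tree, [1.0, 0.5], 2.0, seed=3)
        assert a.equals(b)


class TestGeneFamily:
    def test_no_events_congruent_with_species_tree(self):
        tree, _ = sim_species_tree(8, 1.0, seed=0)
        fam = sim_gene_family(tree, 0.0, 0.0, seed=1)
        assert not fam.empty
        assert fam.duplication_clades == set()
        species_clades = {
            frozenset(tree.leaf_set(n)) for n in tree.internal_nodes()
        }
        gene_clades = {
            frozenset(fam.species_map[l] for l in fam.tree.leaf_set(n))
            for n in fam.tree.internal_nodes()
        }
        assert gene_clades == species_clades

    def test_forced_root_duplication_doubles_every_species(self):
        tree, _ = sim_species_tree(6, 1.0, seed=0)
        fam = sim_gene_family(tree, 0.0, 0.0, seed=1, root_duplication=True)
        counts = {}
        for leaf, sp in fam.species_map.items():
            counts[sp] = counts.get(sp, 0) + 1
        assert set(counts.values()) == {2}
        assert len(fam.duplication_clades) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_planted_duplications_recovered_without_losses(self, seed):
        tree, _ = sim_species_tree(8, 1.0, seed=0)
        fam = sim_gene_family(tree, 0.5, 0.0, seed=seed)
        rec = infer_duplication_nodes(fam.tree, fam.species_map)
        assert rec.duplication_clades == fam.duplication_clades

    def test_total_loss_signals_empty_family(self):
        tree, _ = sim_species_tree(4, 1.0, seed=0)
        fam = sim_gene_family(tree, 0.0, 500.0, seed=2)
        assert fam.empty


class TestOrthogroupTable:
    def test_no_planting_gives_unit_ratios(self):
        table, truth = sim_orthogroup_table(["a", "b"], 20, seed=0)
        assert set(truth.values()) == {1.0}

    def test_planted_ratio_hand_count(self):
        table, truth = sim_orthogroup_table(
            ["a", "b"], 10, planted_dup_species=["a"], planted_dup_fraction=0.3,
            seed=0,
        )
        assert truth["a"] == pytest.approx(1.3)
        assert truth["b"] == pytest.approx(1.0)

    def test_recomputed_ratio_matches_truth(self):
        species = [f"s{i}" for i in range(6)]
        table, truth = sim_orthogroup_table(
            species, 50, planted_dup_species=["s0", "s3"],
            planted_dup_fraction=0.4, seed=7,
        )
        for sp in species:
            assert duplication_ratio(table, table.orthogroups, sp) == pytest.approx(
                truth[sp]
            )


class TestAnnotation:
    def test_recomputed_structure_equals_truth(self):
        config = SimulationConfig(n_scaffolds=3, genes_per_scaffold=30)
        sim = sim_annotation_and_assembly(config, seed=11)
        stats = gene_structure_stats(sim.annotation)
        merged = stats.per_gene.merge(
            sim.gene_truth, on="gene_id", suffixes=("", "_true")
        )
        assert len(merged) == len(sim.gene_truth)
        assert (merged["intron_span"] == merged["intron_span_true"]).all()
        assert (merged["intron_count"] == merged["intron_count_true"]).all()
        assert (merged["exon_span"] == merged["exon_span_true"]).all()

    def test_deterministic_under_seed(self):
        config = SimulationConfig(n_scaffolds=2, genes_per_scaffold=10)
        a = sim_annotation_and_assembly(config, seed=3)
        b = sim_annotation_and_assembly(config, seed=3)
        assert a.sequences == b.sequences
        assert a.gene_truth.equals(b.gene_truth)
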