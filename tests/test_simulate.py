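"""Synthetic-data generators: determinism, realized statistics, truth tables."""

import numpy as np
import pytest

from vespagen import (
    AssemblySimSpec,
    CpGSimSpec,
    OrthoSimSpec,
    check_ultrametric,
    count_nucleotides,
    cpg_oe,
    cpg_table,
    mrca_age,
    pan_core_curve,
    scale_to_root_age,
    select_components,
    simulate_assembly,
    simulate_cpg_genes,
    simulate_orthogroup_table,
    simulate_ultrametric_tree,
    species_summary,
)


class TestSimulateAssembly:
    def test_no_contaminants_means_all_host_truth(self):
        spec = AssemblySimSpec(n_contaminant_contigs=0, n_host_contigs=5, seed=0)
        _, truth, _, _ = simulate_assembly(spec)
        assert (truth["class"] == "host").all()

    def test_same_seed_identical_output(self):
        a1, t1, tax1, r1 = simulate_assembly(AssemblySimSpec(seed=11))
        a2, t2, tax2, r2 = simulate_assembly(AssemblySimSpec(seed=11))
        assert a1.records == a2.records
        assert t1.equals(t2)
        assert tax1.hits == tax2.hits
        assert r1 == r2

    def test_different_seed_differs(self):
        a1, *_ = simulate_assembly(AssemblySimSpec(seed=1))
        a2, *_ = simulate_assembly(AssemblySimSpec(seed=2))
        assert a1.records != a2.records

    def test_realized_gc_within_binomial_bound(self):
        """Per-contig GC within 3 binomial SDs of the spec GC for contigs
        >= 10 kb (unmasked unambiguous bases only)."""
        spec = AssemblySimSpec(
            n_host_contigs=20, n_contaminant_contigs=5, gap_rate=0.0, seed=3
        )
        _, truth, _, _ = simulate_assembly(spec)
        big = truth[truth["length"] >= 10_000]
        assert len(big) > 5
        for _, row in big.iterrows():
            p = row["target_gc"]
            se = np.sqrt(p * (1 - p) / row["length"])
            assert abs(row["realized_gc"] - p) <= 3.5 * se

    def test_mask_fraction_near_target(self):
        spec = AssemblySimSpec(gap_rate=0.0, seed=5)
        _, truth, _, _ = simulate_assembly(spec)
        assert truth["mask_fraction"].mean() == pytest.approx(0.18, abs=0.02)

    def test_taxonomy_and_rescue_structure(self):
        spec = AssemblySimSpec(seed=7)
        _, truth, tax, rescue = simulate_assembly(spec)
        host = truth[truth["class"] == "host"]
        cont = truth[truth["class"] == "contaminant"]
        # every host either has a keyword-bearing hit or rescue genes
        for cid, row in host.iterrows():
            assert row["has_taxonomy_hit"] or rescue.get(cid, 0) >= 1
        # contaminants never have rescue genes
        assert all(rescue.get(cid, 0) == 0 for cid in cont.index)
        # host hits carry a keep keyword; contaminant hits never do
        keywords = ("polistes", "vespula", "wasp")
        for cid in host.index:
            for d in tax.descriptions_for(cid):
                assert any(k in d.lower() for k in keywords)
        for cid in cont.index:
            for d in tax.descriptions_for(cid):
                assert not any(k in d.lower() for k in keywords)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            AssemblySimSpec(repeat_fraction=1.5)


class TestSimulateCpgGenes:
    def test_no_thinning_gives_unit_oe(self):
        spec = CpGSimSpec(
            components=((1.0, 1.0, 0.0),),
            n_genes=200,
            gene_length_law=("constant", 10_000),
            seed=0,
        )
        genes, _ = simulate_cpg_genes(spec)
        vals = cpg_table(genes).defined_values()
        assert vals.mean() == pytest.approx(1.0, abs=0.05)

    def test_full_depletion_leaves_almost_no_cpg(self):
        """With depletion 0 the only CGs left are re-created at substitution
        boundaries: < 5% of the i.i.d. expectation (L/16)."""
        spec = CpGSimSpec(
            components=((1.0, 1e-9, 0.0),),
            n_genes=50,
            gene_length_law=("constant", 10_000),
            seed=1,
        )
        genes, _ = simulate_cpg_genes(spec)
        for _, seq in genes:
            assert count_nucleotides(seq).n_CpG < 0.05 * len(seq) / 16

    def test_same_seed_identical(self):
        g1, t1 = simulate_cpg_genes(CpGSimSpec(seed=4, n_genes=20))
        g2, t2 = simulate_cpg_genes(CpGSimSpec(seed=4, n_genes=20))
        assert g1.records == g2.records
        assert t1.equals(t2)

    def test_component_proportions_recovered_end_to_end(self):
        """Classifying genes by fitted posterior on a well-separated spec
        recovers the planted component proportions within 3 SEs."""
        spec = CpGSimSpec(
            components=((0.5, 0.3, 0.04), (0.5, 0.95, 0.04)),
            n_genes=400,
            gene_length_law=("constant", 6_000),
            seed=6,
        )
        genes, truth = simulate_cpg_genes(spec)
        vals = cpg_table(genes).defined_values()
        sel = select_components(vals, k_max=3, seed=0)
        assert sel.selected.k == 2
        low_weight = sel.selected.weights[0]
        se = np.sqrt(0.5 * 0.5 / len(vals))
        assert abs(low_weight - 0.5) <= 3 * se
        planted_low = (truth["component"] == 0).mean()
        assert abs(low_weight - planted_low) <= 3 * se

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CpGSimSpec(components=((0.5, 0.4, 0.1), (0.4, 0.9, 0.1)))


class TestSimulateOrthogroupTable:
    def test_core_only_curve_is_flat(self):
        spec = OrthoSimSpec(
            n_species=4, n_core=30, n_accessory=0,
            n_specific_per_species=0, seed=0,
        )
        table, truth = simulate_orthogroup_table(spec)
        assert (truth["stratum"] == "core").all()
        curve = pan_core_curve(table, seed=0)
        for k in range(1, 5):
            assert curve.mean_core(k) == curve.mean_pan(k) == 30

    def test_strata_structure_matches_truth(self):
        spec = OrthoSimSpec(n_species=5, n_core=40, n_accessory=30,
                            n_specific_per_species=6, seed=2)
        table, truth = simulate_orthogroup_table(spec)
        pres = table.presence()
        core_ids = truth.index[truth["stratum"] == "core"]
        assert pres.loc[core_ids].all(axis=1).all()
        spec_ids = truth.index[truth["stratum"].str.startswith("specific")]
        assert (pres.loc[spec_ids].sum(axis=1) == 1).all()
        s = species_summary(table)
        assert (s["species_specific_orthogroups"] == 6).all()

    def test_closed_form_core_expectation(self):
        """Expected core at subset size k is n_core + n_accessory * p^k;
        the sampled mean must sit within 3 SEs of it."""
        spec = OrthoSimSpec(
            n_species=10, n_core=500, n_accessory=2000,
            accessory_presence_prob=0.5, n_specific_per_species=0, seed=8,
        )
        table, _ = simulate_orthogroup_table(spec)
        curve = pan_core_curve(table, cap=200, seed=3)
        for k in (2, 4, 6):
            expected = 500 + 2000 * 0.5**k
            cores = np.array([c for _, c, _ in curve.samples[k]])
            # binomial variation of the table itself dominates
            se = np.sqrt(2000 * 0.5**k * (1 - 0.5**k))
            assert abs(cores.mean() - expected) <= 3 * se

    def test_unassigned_rate_realised(self):
        spec = OrthoSimSpec(n_species=3, n_core=200, n_accessory=0,
                            n_specific_per_species=0,
                            unassigned_gene_rate=0.2, seed=1)
        table, _ = simulate_orthogroup_table(spec)
        for sp in table.species:
            total = table.counts[sp].sum() + table.unassigned[sp]
            assert table.unassigned[sp] / total == pytest.approx(0.2, abs=0.01)


class TestSimulateUltrametricTree:
    def test_always_ultrametric(self):
        for seed in range(10):
            tree = simulate_ultrametric_tree(6, root_height=3.0, seed=seed)
            ok, dev = check_ultrametric(tree, rel_tol=1e-9)
            assert ok, dev

    def test_binary_topology_node_counts(self):
        tree = simulate_ultrametric_tree(9, root_height=1.0, seed=0)
        assert len(tree.leaf_nodes()) == 9
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 8
        assert all(len(n.child_nodes()) == 2 for n in internal)

    def test_scaling_doubles_every_mrca_age(self):
        tree = simulate_ultrametric_tree(6, root_height=2.0, seed=5)
        scaled, _ = scale_to_root_age(tree, 4.0)
        taxa = [t.label for t in tree.taxon_namespace]
        for a, b in zip(taxa, taxa[1:]):
            assert mrca_age(scaled, [a, b]) == pytest.approx(
                2 * mrca_age(tree, [a, b]), rel=1e-9
            )

    def test_deterministic_given_seed(self):
        t1 = simulate_ultrametric_tree(7, 1.0, seed=3)
        t2 = simulate_ultrametric_tree(7, 1.0, seed=3)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
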