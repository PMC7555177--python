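"""Generator contracts: determinism, ground truth, and recoverability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohortpath import synthetic
from cohortpath.errors import ConfigurationError


def _base_spec(**kw):
    defaults = dict(n_datasets=2, n_genes=200, n_affected=4, n_control=4,
                    noise_sd=0.5, seed=1)
    defaults.update(kw)
    return synthetic.CohortSpec(**defaults)


class TestGenerateCohort:
    def test_null_spec_has_no_perturbed_genes(self):
        datasets, truth = synthetic.generate_cohort(_base_spec())
        assert truth.all_perturbed_genes == set()
        assert all(not d for d in truth.perturbed.values())

    def test_same_seed_is_bit_identical(self):
        a, _ = synthetic.generate_cohort(_base_spec(seed=9))
        b, _ = synthetic.generate_cohort(_base_spec(seed=9))
        for da, db in zip(a, b):
            assert da.values.equals(db.values)
            assert da.groups == db.groups

    def test_different_seed_differs(self):
        a, _ = synthetic.generate_cohort(_base_spec(seed=1))
        b, _ = synthetic.generate_cohort(_base_spec(seed=2))
        assert not a[0].values.equals(b[0].values)

    def test_reference_t_test_recovers_perturbed_genes(self):
        """An independent gene-wise t-test finds >= 80% of planted genes.

        The reference routine is scipy's two-sample t-test, not the
        package's own DE engine.
        """
        universe = synthetic.gene_universe(1000)
        members = universe[:50]
        spec = synthetic.CohortSpec(
            n_datasets=1, n_genes=1000, n_affected=10, n_control=10,
            perturbed_sets={"PW1": 1.0}, set_members={"PW1": members},
            noise_sd=0.5, seed=7,
        )
        (ds,), truth = synthetic.generate_cohort(spec)
        aff = ds.values[ds.samples_in_group("affected")].to_numpy()
        ctl = ds.values[ds.samples_in_group("control")].to_numpy()
        _, p = stats.ttest_ind(aff.T, ctl.T)
        idx = [ds.gene_ids.index(g) for g in members]
        assert np.mean(p[idx] < 0.05) >= 0.80
        assert truth.perturbed[ds.name] == {g: 1.0 for g in members}

    def test_affected_means_shift_by_effect(self):
        universe = synthetic.gene_universe(100)
        spec = _base_spec(
            n_genes=100, n_affected=50, n_control=50, noise_sd=0.1,
            n_datasets=1, perturbed_sets={"S": 2.0},
            set_members={"S": universe[:10]},
        )
        (ds,), _ = synthetic.generate_cohort(spec)
        diff = (
            ds.values[ds.samples_in_group("affected")].mean(axis=1)
            - ds.values[ds.samples_in_group("control")].mean(axis=1)
        )
        assert diff.iloc[:10].mean() == pytest.approx(2.0, abs=0.1)
        assert abs(diff.iloc[10:].mean()) < 0.1

    def test_consistent_fraction_controls_active_datasets(self):
        universe = synthetic.gene_universe(50)
        spec = _base_spec(
            n_genes=50, n_datasets=6, consistent_fraction=1 / 3,
            perturbed_sets={"S": 1.0}, set_members={"S": universe[:5]},
        )
        _, truth = synthetic.generate_cohort(spec)
        assert len(truth.active_datasets["S"]) == 2  # ceil(6/3)

    def test_dialects(self):
        for dialect, check in [
            ("log2", lambda v: v.max() < 30),
            ("linear", lambda v: v.min() > 0),
            ("linear_with_negatives", lambda v: v.min() < 0),
        ]:
            (ds,), _ = synthetic.generate_cohort(
                _base_spec(dialect=dialect, n_datasets=1)
            )
            assert check(ds.values.to_numpy()), dialect
            assert ds.is_log2 == (dialect == "log2")

    def test_null_pvalues_uniform(self):
        """Gene-wise reference t-test p-values on a null cohort pass KS."""
        spec = _base_spec(n_genes=5000, n_affected=5, n_control=5, n_datasets=1)
        (ds,), _ = synthetic.generate_cohort(spec)
        aff = ds.values[ds.samples_in_group("affected")].to_numpy()
        ctl = ds.values[ds.samples_in_group("control")].to_numpy()
        _, p = stats.ttest_ind(aff.T, ctl.T)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("field,value", [
        ("n_affected", 1), ("n_control", 0), ("noise_sd", 0.0),
        ("consistent_fraction", 0.0), ("consistent_fraction", 1.5),
        ("dialect", "counts"),
    ])
    def test_invalid_spec_names_field(self, field, value):
        with pytest.raises(ConfigurationError):
            synthetic.generate_cohort(_base_spec(**{field: value}))

    def test_perturbed_sets_without_members_rejected(self):
        with pytest.raises(ConfigurationError, match="set_members"):
            synthetic.generate_cohort(_base_spec(perturbed_sets={"S": 1.0}))

    def test_duplicate_probes_and_sign_flip(self):
        universe = synthetic.gene_universe(100)
        spec = _base_spec(
            n_genes=100, n_datasets=1, duplicate_probes=True, flip_fraction=1.0,
            perturbed_sets={"S": 1.5}, set_members={"S": universe[:10]},
            n_affected=20, n_control=20, noise_sd=0.2,
        )
        (ds,), truth = synthetic.generate_cohort(spec)
        assert len(ds.gene_ids) == 200
        assert truth.probe_map["G0005.p2"] == "G0005"
        # flipped second probe carries the opposite shift
        aff, ctl = ds.samples_in_group("affected"), ds.samples_in_group("control")
        d1 = ds.values.loc["G0000.p1", aff].mean() - ds.values.loc["G0000.p1", ctl].mean()
        d2 = ds.values.loc["G0000.p2", aff].mean() - ds.values.loc["G0000.p2", ctl].mean()
        assert d1 > 1.0 and d2 < -1.0


class TestGeneratePathways:
    def test_zero_overlap_gives_disjoint_sets(self):
        coll = synthetic.generate_pathways(
            5, (5, 8), synthetic.gene_universe(100), overlap_fraction=0.0, seed=0
        )
        ids = sorted(coll.sets)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert not set(coll.members(a)) & set(coll.members(b))

    def test_neighbor_jaccard_meets_requirement(self):
        coll = synthetic.generate_pathways(
            2, (5, 5), synthetic.gene_universe(50), overlap_fraction=0.4, seed=1
        )
        a, b = (set(coll.members(s)) for s in sorted(coll.sets))
        assert len(a & b) / len(a | b) >= 0.4

    def test_sizes_within_range(self):
        coll = synthetic.generate_pathways(
            10, (6, 12), synthetic.gene_universe(500), overlap_fraction=0.2, seed=2
        )
        assert all(6 <= len(coll.members(s)) <= 12 for s in coll.sets)

    def test_empty_universe_errors(self):
        with pytest.raises(ConfigurationError):
            synthetic.generate_pathways(2, (2, 3), [], 0.0, seed=0)

    def test_invalid_overlap_fraction_errors(self):
        with pytest.raises(ConfigurationError):
            synthetic.generate_pathways(
                3, (2, 2), synthetic.gene_universe(50), overlap_fraction=1.5, seed=0
            )

    def test_disjoint_sets_exhaust_small_universe(self):
        with pytest.raises(ConfigurationError, match="exhausted"):
            synthetic.generate_pathways(
                10, (5, 5), synthetic.gene_universe(20), overlap_fraction=0.0, seed=0
            )


class TestGeneratePathwayNetwork:
    def test_edge_iff_min_shared(self):
        from cohortpath.enrichment import GeneSetCollection
        coll = GeneSetCollection(sets={
            "A": ("A", ["g1", "g2", "g3", "g4"]),
            "B": ("B", ["g3", "g4", "g5", "g2"]),
            "C": ("C", ["g9", "g10", "g11"]),
        })
        net = synthetic.generate_pathway_network(coll, min_shared=3, seed=0)
        assert net.has_edge("A", "B")  # share g2,g3,g4
        native = [e for e in net.edges(data=True) if not e[2]["backbone"]]
        assert len(native) == 1

    def test_disjoint_sets_connected_by_backbone(self):
        from cohortpath.enrichment import GeneSetCollection
        coll = GeneSetCollection(sets={
            "A": ("A", ["g1"]), "B": ("B", ["g2"]),
        })
        net = synthetic.generate_pathway_network(coll, min_shared=1, seed=0)
        assert net.graph["backbone_added"]
        assert net.has_edge("A", "B") and net["A"]["B"]["backbone"]

    def test_min_shared_zero_is_complete(self):
        coll = synthetic.generate_pathways(
            5, (3, 5), synthetic.gene_universe(100), overlap_fraction=0.0, seed=0
        )
        net = synthetic.generate_pathway_network(coll, min_shared=0, seed=0)
        assert net.number_of_edges() == 5 * 4 // 2


class TestGeneratePPITable:
    def test_complete_module_edge_count(self):
        table = synthetic.generate_ppi_table(
            ["a", "b", "c"], {"a": 0, "b": 0, "c": 0}, intra_density=1.0, seed=0
        )
        assert len(table) == 3

    def test_empty_gene_list(self):
        table = synthetic.generate_ppi_table([], {}, seed=0)
        assert table.empty

    def test_inter_scores_below_threshold(self):
        genes = [f"p{i}" for i in range(12)]
        modules = {g: i // 6 for i, g in enumerate(genes)}
        table = synthetic.generate_ppi_table(
            genes, modules, intra_score_range=(0.75, 0.99),
            inter_score_range=(0.0, 0.5), seed=4, inter_density=0.5,
        )
        inter = table[[modules[u] != modules[v]
                       for u, v in zip(table.protein1, table.protein2)]]
        assert (inter.combined_score < 0.700).all()

    def test_determinism(self):
        genes = [f"p{i}" for i in range(8)]
        mods = {g: 0 for g in genes}
        a = synthetic.generate_ppi_table(genes, mods, seed=5)
        b = synthetic.generate_ppi_table(genes, mods, seed=5)
        pd.testing.assert_frame_equal(a, b)
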