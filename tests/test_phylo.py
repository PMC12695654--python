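"""Unit tests for genotype matrices, perfect phylogeny and branch dating."""

import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest

from clonetrace.phylo import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    build_genotype_matrix,
    clade_filter_for_tracing,
    colony_purity,
    date_mutation,
    dating_ci,
    make_ultrametric,
    perfect_phylogeny,
    poisson_ci,
    timeline_span,
)
from clonetrace.simulate import (
    simulate_colony_reads,
    simulate_donor,
    simulate_phylogeny,
    tree_mutation_carriers,
)


def reads_df(rows):
    return pd.DataFrame(rows, columns=["colony", "mutation", "mut_reads", "total_reads"])


class TestGenotypeMatrix:
    @pytest.mark.parametrize(
        "mut,total,state",
        [
            (3, 15, POSITIVE),  # VAF 0.2 >= 0.15 and >= 2 mutant reads
            (0, 10, NEGATIVE),  # no mutant reads at depth >= 5
            (1, 4, UNKNOWN),  # fails both rules
            (2, 20, UNKNOWN),  # VAF 0.1 < 0.15
            (0, 4, UNKNOWN),  # too shallow to call negative
            (2, 13, POSITIVE),  # VAF 0.154
        ],
    )
    def test_entry_rules(self, mut, total, state):
        m = build_genotype_matrix(reads_df([("c1", "m1", mut, total)]))
        assert m.loc["c1", "m1"] == state

    def test_mutant_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            build_genotype_matrix(reads_df([("c1", "m1", 5, 3)]))

    def test_missing_column(self):
        with pytest.raises(ValueError, match="colony"):
            build_genotype_matrix(pd.DataFrame({"mutation": [], "mut_reads": [], "total_reads": []}))


class TestColonyPurity:
    def test_heterozygous_colony_passes(self):
        rows = [("c1", f"m{i}", 10, 20) for i in range(10)]
        m = build_genotype_matrix(reads_df(rows))
        qc = colony_purity(m, reads_df(rows))
        assert qc[0].passed and qc[0].median_vaf == 0.5

    def test_doublet_like_vaf_fails(self):
        rows = [("c1", f"m{i}", 5, 20) for i in range(10)]  # VAF 0.25
        m = build_genotype_matrix(reads_df(rows))
        qc = colony_purity(m, reads_df(rows))
        assert not qc[0].passed

    def test_low_depth_fails(self):
        rows = [("c1", f"m{i}", 2, 5) for i in range(10)]
        m = build_genotype_matrix(reads_df(rows))
        qc = colony_purity(m, reads_df(rows), depth_floor=8)
        assert not qc[0].passed

    def test_doublet_mixture_fails_more_than_singlets(self):
        """Pooling two cells halves non-shared VAFs and trips the QC window."""
        rng = np.random.default_rng(11)
        singlet_fail = doublet_fail = 0
        n = 40
        for i in range(n):
            depth = 30
            singlet = [("s", f"m{j}", int(rng.binomial(depth, 0.5)), depth) for j in range(30)]
            doublet = [("d", f"m{j}", int(rng.binomial(depth, 0.25)), depth) for j in range(30)]
            for rows, is_doublet in ((singlet, False), (doublet, True)):
                df = reads_df(rows)
                df.loc[df["mut_reads"] < 2, "mut_reads"] = 2  # keep entries callable
                m = build_genotype_matrix(df)
                qc = colony_purity(m, df)
                if not qc[0].passed:
                    if is_doublet:
                        doublet_fail += 1
                    else:
                        singlet_fail += 1
        assert doublet_fail > singlet_fail


class TestPerfectPhylogeny:
    def test_textbook_example(self):
        rows = []
        carriers = {"mAB": {"A", "B"}, "mA": {"A"}, "mB": {"B"}, "mC": {"C"}}
        for colony in "ABC":
            for m, cs in carriers.items():
                rows.append((colony, m, 10 if colony in cs else 0, 20))
        tree = perfect_phylogeny(build_genotype_matrix(reads_df(rows)))
        assert tree_mutation_carriers(tree) == {
            m: frozenset(c) for m, c in carriers.items()
        }
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert labels == {"A", "B", "C"}
        # the {A,B} clade exists with one mutation on its stem
        for node in tree.preorder_node_iter():
            tips = frozenset(l.taxon.label for l in node.leaf_iter())
            if tips == {"A", "B"}:
                assert node.edge.length == 1
                break
        else:
            pytest.fail("clade {A,B} missing")

    def test_nested_carriers_give_caterpillar(self):
        sets = {"m1": {"A", "B", "C", "D"}, "m2": {"A", "B", "C"}, "m3": {"A", "B"}, "m4": {"A"}}
        rows = [
            (colony, m, 10 if colony in cs else 0, 20)
            for colony in "ABCD"
            for m, cs in sets.items()
        ]
        tree = perfect_phylogeny(build_genotype_matrix(reads_df(rows)))
        # root-to-A path visits nested clades of sizes 4,3,2,1
        node = next(l for l in tree.leaf_node_iter() if l.taxon.label == "A")
        depths = []
        while node is not None:
            depths.append(node.edge.length or 0)
            node = node.parent_node
        assert sum(depths) == 4

    def test_four_gamete_conflict_detected(self):
        sets = {"m1": {"A", "B"}, "m2": {"B", "C"}}
        rows = [
            (colony, m, 10 if colony in cs else 0, 20)
            for colony in "ABC"
            for m, cs in sets.items()
        ]
        with pytest.raises(ValueError, match="four-gamete"):
            perfect_phylogeny(build_genotype_matrix(reads_df(rows)))

    def test_recovery_from_error_free_reads(self):
        """Zero sequencing error and depth >= 20 reproduce the simulated
        carrier structure (and hence topology and branch counts) exactly,
        up to branches carrying no mutations."""
        donor = simulate_donor(
            50, 1, [0, 0, 0, 1, 0, 0], seed=11, mutation_rate=0.6,
            hsc_mcf_range=(0.3, 0.5),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree, _ = simulate_phylogeny(donor, 10, seed=12)
        reads = simulate_colony_reads(tree, mean_depth=30, error_rate=0.0, seed=13)
        recovered = perfect_phylogeny(build_genotype_matrix(reads))
        assert tree_mutation_carriers(recovered) == tree_mutation_carriers(tree)


class TestUltrametric:
    def _two_tip_tree(self, c_stem, c_a, c_b):
        t = dendropy.Tree.get(data=f"((A:{c_a},B:{c_b}):{c_stem});", schema="newick")
        t.is_rooted = True
        return t

    def test_midpoint_node_age(self):
        tree = self._two_tip_tree(50, 50, 50)
        make_ultrametric(tree, 80.0, gestation_weeks=0.0)
        inner = tree.seed_node.child_nodes()[0]
        assert inner.age == pytest.approx(40.0)

    def test_gestation_span(self):
        assert timeline_span(80, 40) == pytest.approx(80.7666, abs=1e-3)

    def test_tips_forced_to_span(self, small_donor):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree, truth = simulate_phylogeny(small_donor, 20, seed=3)
        make_ultrametric(tree, small_donor.age_at_sampling)
        for leaf in tree.leaf_node_iter():
            assert leaf.age == pytest.approx(truth["span"], abs=1e-9)

    def test_node_ages_monotone(self, small_donor):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree, _ = simulate_phylogeny(small_donor, 20, seed=4)
        make_ultrametric(tree, small_donor.age_at_sampling)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.age >= node.parent_node.age - 1e-9

    def test_zero_root_to_tip_count_rejected(self):
        tree = self._two_tip_tree(0, 0, 5)
        with pytest.raises(ValueError, match="zero root-to-tip"):
            make_ultrametric(tree, 80.0)


class TestDating:
    def _dated_tree(self):
        tree = dendropy.Tree.get(
            data="((A:75,B:75):25,(C:60,D:60):40);", schema="newick"
        )
        tree.is_rooted = True
        make_ultrametric(tree, 100.0, gestation_weeks=0.0)
        return tree

    def test_conventions(self):
        tree = self._dated_tree()
        node = next(
            n
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
            and {l.taxon.label for l in n.leaf_iter()} == {"A", "B"}
        )
        assert date_mutation(tree, node, "distal") == pytest.approx(25.0)
        assert date_mutation(tree, node, "proximal") == pytest.approx(0.0)
        assert date_mutation(tree, node, "midpoint") == pytest.approx(12.5)

    def test_poisson_ci_zero_count(self):
        lo, hi = poisson_ci(0)
        assert lo == 0.0
        assert hi == pytest.approx(3.689, abs=1e-3)

    def test_ci_contains_point_and_tightens_with_counts(self):
        small = dendropy.Tree.get(data="((A:30,B:30):10);", schema="newick")
        big = dendropy.Tree.get(data="((A:3000,B:3000):1000);", schema="newick")
        widths = []
        for t in (small, big):
            t.is_rooted = True
            node = t.seed_node.child_nodes()[0]
            d = dating_ci(t, node, 40.0, gestation_weeks=0.0)
            assert d.ci_low <= d.age <= d.ci_high
            widths.append(d.ci_high - d.ci_low)
        assert widths[1] < widths[0]

    def test_true_acquisition_age_covered(self, small_donor):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree, truth = simulate_phylogeny(small_donor, 25, seed=5)
        make_ultrametric(tree, small_donor.age_at_sampling)
        for clone_id, node in truth["clone_nodes"].items():
            d = dating_ci(tree, node, small_donor.age_at_sampling)
            assert d.ci_low <= truth["clone_ages"][clone_id] <= d.ci_high


class TestCladeFilter:
    def test_threshold(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = clade_filter_for_tracing({"a": 0.05, "b": 0.01, "c": 0.02})
        assert set(kept) == {"a", "c"}

    def test_empty(self):
        assert clade_filter_for_tracing({}) == {}
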