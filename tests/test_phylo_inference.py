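import numpy as np
import pytest

from foramlineage import GTRIGParams
from foramlineage.io_formats import Alignment, SequenceRecord, parse_newick
from foramlineage.phylo_inference import (
    BootstrapSummary,
    DistanceMatrix,
    OutgroupScheme,
    bootstrap_support,
    clade_support,
    estimate_model_params,
    infer_ml_tree,
    nj_tree,
    nni_search,
    optimize_branch_lengths,
    pairwise_distances,
    root_with_outgroup,
)
from foramlineage.phylo_model import tree_log_likelihood
from foramlineage.synthetic_data import SimTreeConfig, simulate_alignment
from foramlineage.tree import PhyloTree
from conftest import random_gtrig_params
from _oracles import random_tree


class TestDistances:
    def test_identical_sequences_have_zero_distance(self):
        aln = Alignment(
            [SequenceRecord("A", "ACGTACGT"), SequenceRecord("B", "ACGTACGT")]
        )
        d = pairwise_distances(aln)
        assert d.values[0, 1] == 0.0

    def test_jc_correction_closed_form(self):
        # 1 mismatch in 10 comparable sites: p = 0.1
        aln = Alignment(
            [SequenceRecord("A", "ACGTACGTAC"), SequenceRecord("B", "ACGTACGTAG")]
        )
        d = pairwise_distances(aln)
        expected = -0.75 * np.log(1 - 0.4 / 3.0)
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert d.values[0, 1] == pytest.approx(0.1073, abs=1e-4)

    def test_matrix_symmetric_zero_diagonal(self, rng):
        names = ["A", "B", "C", "D", "E"]
        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in names]
        aln = Alignment([SequenceRecord(n, s) for n, s in zip(names, seqs)])
        d = pairwise_distances(aln)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_saturated_pair_capped(self):
        aln = Alignment(
            [SequenceRecord("A", "AAAAAAAAAA"), SequenceRecord("B", "CCCCCCCCCC")]
        )
        assert pairwise_distances(aln).values[0, 1] == 5.0

    def test_no_comparable_sites_is_error(self):
        aln = Alignment(
            [SequenceRecord("A", "NNNN"), SequenceRecord("B", "ACGT")]
        )
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distances(aln)

    def test_gapped_sites_excluded_from_comparison(self):
        aln = Alignment(
            [SequenceRecord("A", "ACGT-CGTAC"), SequenceRecord("B", "ACGTAC-TAG")]
        )
        # 8 comparable sites, 1 mismatch
        expected = -0.75 * np.log(1 - (4.0 / 3.0) * (1.0 / 8.0))
        assert pairwise_distances(aln).values[0, 1] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxon_linear_solve(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = nj_tree(d)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_additive_matrix_recovered_exactly(self, rng):
        true = random_tree(["A", "B", "C", "D", "E", "F"], rng)
        names = sorted(true.leaf_names())
        # path-length (additive) distances from the true tree
        def leaf_path(tree, a, b):
            def ancestors(node):
                out = []
                while node is not None:
                    out.append(node)
                    node = node.parent
                return out
            na, nb = tree.find_leaf(a), tree.find_leaf(b)
            anc_a = ancestors(na)
            seen = {id(n) for n in anc_a}
            node, d_b = nb, 0.0
            while id(node) not in seen:
                d_b += node.length or 0.0
                node = node.parent
            d_a = 0.0
            for n in anc_a:
                if n is node:
                    break
                d_a += n.length or 0.0
            return d_a + d_b

        mat = np.zeros((6, 6))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    mat[i, j] = mat[j, i] = leaf_path(true, a, b)
        recovered = nj_tree(DistanceMatrix(names, mat))
        assert recovered.rf_distance(true) == 0
        # branch lengths reproduced too (additivity)
        for leaf in recovered.leaves:
            assert leaf.length == pytest.approx(
                true.find_leaf(leaf.name).length, abs=1e-10
            )

    def test_all_equal_distances_is_resolved_tie(self):
        d = DistanceMatrix(["A", "B", "C", "D"], np.ones((4, 4)) - np.eye(4))
        tree = nj_tree(d)
        assert sorted(tree.leaf_names()) == ["A", "B", "C", "D"]

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestBranchLengths:
    def test_two_taxon_consistency(self, jc_params):
        tree = parse_newick("(A:0.05,B:0.05);")
        sim_tree = parse_newick("(A:0.05,B:0.05);")
        aln = simulate_alignment(
            SimTreeConfig(tree=sim_tree, params=jc_params, n_sites=100_000, seed=9)
        )
        optimize_branch_lengths(tree, aln, jc_params)
        total = sum(leaf.length for leaf in tree.leaves)
        assert total == pytest.approx(0.1, abs=0.01)

    def test_idempotent_when_already_optimal(self, rng, jc_params):
        tree = random_tree(["A", "B", "C", "D"], rng)
        aln = simulate_alignment(
            SimTreeConfig(tree=tree.copy(), params=jc_params, n_sites=500, seed=2)
        )
        optimize_branch_lengths(tree, aln, jc_params)
        ll1 = tree_log_likelihood(tree, aln, jc_params)
        lengths = [n.length for n in tree.postorder() if n is not tree.root]
        optimize_branch_lengths(tree, aln, jc_params)
        ll2 = tree_log_likelihood(tree, aln, jc_params)
        lengths2 = [n.length for n in tree.postorder() if n is not tree.root]
        assert ll2 >= ll1 - 1e-9
        assert np.allclose(lengths, lengths2, atol=1e-4)

    def test_monotone_likelihood_trace(self, rng):
        from foramlineage._likelihood import TreeLikelihood

        names = ["A", "B", "C", "D", "E", "F"]
        true = random_tree(names, rng)
        params = random_gtrig_params(rng)
        aln = simulate_alignment(
            SimTreeConfig(tree=true, params=params, n_sites=300, seed=4)
        )
        start = random_tree(names, rng)  # wrong lengths, maybe wrong topology
        eng = TreeLikelihood(start, aln, params)
        ll_before = eng.loglik()
        trace = [ll_before]
        for _ in range(5):
            trace.append(eng.optimize_branch_lengths(max_rounds=1))
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


class TestModelEstimation:
    @pytest.mark.filterwarnings("ignore:model-parameter estimation")
    def test_jc_exchangeabilities_recovered(self):
        tree = parse_newick(
            "((A:0.15,B:0.12):0.08,(C:0.1,D:0.2):0.06,E:0.15);"
        )
        truth = GTRIGParams(gamma_shape=100.0, n_categories=1)
        aln = simulate_alignment(
            SimTreeConfig(tree=tree.copy(), params=truth, n_sites=50_000, seed=21)
        )
        est = estimate_model_params(
            tree, aln, GTRIGParams(n_categories=1), max_iter=8
        )
        rel = est.exchangeabilities / est.exchangeabilities[5]
        assert np.all(rel > 0.8) and np.all(rel < 1.2)

    @pytest.mark.filterwarnings("ignore:model-parameter estimation")
    def test_likelihood_never_decreases(self, rng):
        names = ["A", "B", "C", "D"]
        tree = random_tree(names, rng)
        params = random_gtrig_params(rng)
        aln = simulate_alignment(
            SimTreeConfig(tree=tree.copy(), params=params, n_sites=400, seed=6)
        )
        init = GTRIGParams()
        fit_tree = tree.copy()
        before = tree_log_likelihood(fit_tree, aln, init)
        est = estimate_model_params(fit_tree, aln, init, max_iter=3)
        after = tree_log_likelihood(fit_tree, aln, est)
        assert after >= before


class TestNNISearch:
    def test_recovers_true_topology_across_seeds(self):
        tree_text = (
            "(((A:0.1,B:0.1):0.06,(C:0.1,D:0.1):0.06):0.06,E:0.12,F:0.18);"
        )
        params = GTRIGParams(
            base_freqs=[0.3, 0.2, 0.25, 0.25],
            exchangeabilities=[1.5, 3.0, 0.8, 1.1, 4.0, 1.0],
            gamma_shape=0.8,
            p_inv=0.1,
        )
        hits = 0
        for seed in range(5):
            true = parse_newick(tree_text)
            aln = simulate_alignment(
                SimTreeConfig(tree=true, params=params, n_sites=5000, seed=seed)
            )
            inferred = infer_ml_tree(aln, params)
            hits += inferred.rf_distance(true) == 0
        assert hits == 5

    def test_true_topology_is_local_optimum(self, rng, jc_params):
        true = random_tree(["A", "B", "C", "D", "E", "F"], rng)
        aln = simulate_alignment(
            SimTreeConfig(tree=true.copy(), params=jc_params, n_sites=4000, seed=8)
        )
        result = nni_search(true.copy(), aln, jc_params)
        assert result.rf_distance(true) == 0

    def test_search_never_lowers_likelihood(self, rng, jc_params):
        names = ["A", "B", "C", "D", "E", "F"]
        true = random_tree(names, rng)
        aln = simulate_alignment(
            SimTreeConfig(tree=true, params=jc_params, n_sites=800, seed=13)
        )
        start = random_tree(names, rng)
        baseline_tree = start.copy()
        optimize_branch_lengths(baseline_tree, aln, jc_params)
        ll_start = tree_log_likelihood(baseline_tree, aln, jc_params)
        result = nni_search(start, aln, jc_params)
        ll_end = tree_log_likelihood(result, aln, jc_params)
        assert ll_end >= ll_start - 1e-6


@pytest.fixture(scope="module")
def four_taxon_data():
    tree = parse_newick("((A:0.1,B:0.1):0.15,(C:0.1,D:0.1));")
    tree.unroot()
    params = GTRIGParams(n_categories=1)
    aln = simulate_alignment(
        SimTreeConfig(tree=tree, params=params, n_sites=1500, seed=17)
    )
    return aln, params


class TestBootstrap:

    def test_same_seed_reproduces_supports(self, four_taxon_data):
        aln, params = four_taxon_data
        s1 = bootstrap_support(aln, params, 5, seed=3)
        s2 = bootstrap_support(aln, params, 5, seed=3)
        assert s1.support == s2.support

    def test_single_replicate_supports_are_binary(self, four_taxon_data):
        aln, params = four_taxon_data
        summary = bootstrap_support(aln, params, 1, seed=5)
        assert set(summary.support.values()) <= {0.0, 1.0}

    def test_support_equals_replicate_recount(self, four_taxon_data):
        aln, params = four_taxon_data
        summary = bootstrap_support(aln, params, 10, seed=11)
        for split, frac in summary.support.items():
            assert frac == summary.replicate_counts.get(split, 0) / 10

    def test_long_internal_edge_gets_high_support(self, four_taxon_data):
        aln, params = four_taxon_data
        summary = bootstrap_support(aln, params, 20, seed=29)
        assert clade_support(summary, ["A", "B"]) >= 0.9

    def test_replicate_count_validation(self, four_taxon_data):
        aln, params = four_taxon_data
        with pytest.raises(ValueError):
            bootstrap_support(aln, params, 0, seed=1)


@pytest.fixture(scope="module")
def summary():
    return BootstrapSummary(
        n_replicates=10,
        seed=0,
        support={frozenset({"C", "D"}): 0.7, frozenset({"D", "E"}): 0.0},
        best_tree=parse_newick("((C:0.1,D:0.1):0.2,(A:0.1,B:0.1),E:0.2);"),
    )


class TestCladeSupport:

    def test_full_leaf_set_is_trivially_supported(self, summary):
        assert clade_support(summary, ["A", "B", "C", "D", "E"]) == 1.0

    def test_edge_clade_returns_fraction(self, summary):
        assert clade_support(summary, ["C", "D"]) == 0.7
        # complement of an edge names the same bipartition
        assert clade_support(summary, ["A", "B", "E"]) == 0.7

    def test_non_edge_grouping_is_absent(self, summary):
        assert clade_support(summary, ["A", "C"]) == "absent"

    def test_unknown_taxon_raises(self, summary):
        with pytest.raises(KeyError):
            clade_support(summary, ["A", "Z"])


class TestOutgroupRooting:
    def test_single_taxon_outgroup_roots_on_pendant_edge(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1));")
        tree.unroot()
        scheme = OutgroupScheme("og", ["D"], ["A", "B", "C"])
        rooted = root_with_outgroup(tree, scheme)
        assert len(rooted.root.children) == 2
        sides = [set(c.leaf_names()) for c in rooted.root.children]
        assert {"D"} in sides

    def test_monophyletic_outgroup_roots_on_internal_edge(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        # make C+D a clade
        tree = parse_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2,E:0.1);")
        scheme = OutgroupScheme("og", ["C", "D"], ["A", "B", "E"])
        rooted = root_with_outgroup(tree, scheme)
        sides = [set(c.leaf_names()) for c in rooted.root.children]
        assert {"C", "D"} in sides

    def test_rooting_preserves_ingroup_bipartitions(self, rng):
        tree = random_tree([f"t{i}" for i in range(8)], rng)
        og = ["t0"]
        scheme = OutgroupScheme("og", og, [f"t{i}" for i in range(1, 8)])
        rooted = root_with_outgroup(tree, scheme)
        assert rooted.bipartitions() == tree.bipartitions()

    def test_missing_outgroup_taxa_is_error(self):
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        with pytest.raises(ValueError, match="absent"):
            root_with_outgroup(
                tree, OutgroupScheme("og", ["Z"], ["A", "B", "C"])
            )

    def test_non_monophyletic_outgroup_warns(self):
        tree = parse_newick("((A:0.1,C:0.1):0.2,(B:0.1,D:0.1):0.2,E:0.1);")
        scheme = OutgroupScheme("og", ["A", "B"], ["C", "D", "E"])
        with pytest.warns(UserWarning, match="monophyletic"):
            rooted = root_with_outgroup(tree, scheme)
        assert sorted(rooted.leaf_names()) == ["A", "B", "C", "D", "E"]

    def test_scheme_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            OutgroupScheme("og", ["A"], ["A", "B"])


class TestRelabelingInvariance:
    def test_taxon_relabeling_permutes_outputs(self, rng, jc_params):
        names = ["A", "B", "C", "D", "E"]
        true = random_tree(names, rng)
        aln = simulate_alignment(
            SimTreeConfig(tree=true, params=jc_params, n_sites=2000, seed=19)
        )
        mapping = {"A": "V", "B": "W", "C": "X", "D": "Y", "E": "Z"}
        relabeled = Alignment(
            [
                SequenceRecord(mapping[r.taxon_id], r.sequence)
                for r in aln.records
            ]
        )
        t1 = infer_ml_tree(aln, jc_params)
        t2 = infer_ml_tree(relabeled, jc_params)
        remapped = {
            frozenset(mapping[x] for x in split)
            for split in t1.bipartitions()
        }
        # canonicalize the remapped splits against t2's leaf universe
        universe = frozenset(mapping.values())
        ref = min(universe)
        canon = {
            s if ref not in s else universe - s for s in remapped
        }
        assert canon == t2.bipartitions()
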