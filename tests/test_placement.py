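import json

import numpy as np
import pytest

from lshplace import (MatchHistogram, Phylogeny, TaxonomyTree,
                      clade_histograms, closest_reference,
                      indistinguishable_leaf_set, lrt_distinguishable,
                      multiplacement_weights, place_read, place_taxonomic,
                      write_jplace)
from lshplace.distance import DistanceEstimate, estimate_distance
from lshplace.distance import p_match, p_miss
from lshplace.placement import CladeScore, PlacementResult

K, H, DELTA = 29, 14, 4
L = 150
TRIALS = L - K + 1


def expected_hist(D, rho=0.25):
    """Noise-free histogram: expectation of the match model at distance D."""
    v = np.array([TRIALS * p_match(D, d, K, H, rho) for d in range(DELTA + 1)])
    return MatchHistogram(v=v, u=TRIALS - v.sum(), rho=rho, L=L, k=K)


def _score(node, hist):
    est = estimate_distance(hist, H)
    return CladeScore(node=node, hist=hist, d_hat=est.d_hat, loglik=est.loglik,
                      n_leaves=node.n_leaves)


@pytest.fixture
def eight_leaf_tree():
    # balanced ultrametric shape
    nwk = ("(((R0:0.05,R1:0.05):0.05,(R2:0.05,R3:0.05):0.05):0.1,"
           "((R4:0.05,R5:0.05):0.05,(R6:0.05,R7:0.05):0.05):0.1);")
    return Phylogeny.from_newick(nwk)


def leaf_hists_for_query(distances, rho=0.25):
    return {r: expected_hist(D, rho) for r, D in distances.items()}


class TestCladeHistograms:
    def test_cherry_of_equal_children_is_unchanged(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        h = expected_hist(0.05)
        scores = clade_histograms(tree, {"A": h, "B": h}, L,
                                  {"A": 0.25, "B": 0.25}, K, H, DELTA)
        root = scores[tree.root.index]
        assert np.allclose(root.hist.v, h.v)
        assert root.hist.u == pytest.approx(h.u)

    def test_polytomy_mean(self):
        tree = Phylogeny.from_newick("(A:1,B:1,C:1);")
        hs = {r: expected_hist(D) for r, D in
              [("A", 0.02), ("B", 0.05), ("C", 0.2)]}
        scores = clade_histograms(tree, hs, L, {r: 0.25 for r in hs},
                                  K, H, DELTA)
        root = scores[tree.root.index]
        want = np.mean([hs[r].v for r in "ABC"], axis=0)
        assert np.allclose(root.hist.v, want)
        assert root.hist.trials == TRIALS  # affine combination preserves trials

    def test_rho_is_max_of_children(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        hs = {"A": expected_hist(0.05, rho=0.2), "B": expected_hist(0.05, rho=0.4)}
        scores = clade_histograms(tree, hs, L, {"A": 0.2, "B": 0.4}, K, H, DELTA)
        assert scores[tree.root.index].hist.rho == 0.4

    def test_unmatched_leaf_gets_all_miss_histogram(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        scores = clade_histograms(tree, {"A": expected_hist(0.05)}, L,
                                  {"A": 0.25, "B": 0.3}, K, H, DELTA)
        b = tree.node_by_label("B")
        assert scores[b.index].hist.n_matches == 0
        assert scores[b.index].hist.rho == 0.3
        assert scores[b.index].d_hat is None

    def test_empty_input_empty_scores(self, eight_leaf_tree):
        assert clade_histograms(eight_leaf_tree, {}, L, {}, K, H, DELTA) == {}


class TestLrt:
    def test_equal_distance_indistinguishable(self, eight_leaf_tree):
        n = eight_leaf_tree.leaves[0]
        s = _score(n, expected_hist(0.05))
        assert not lrt_distinguishable(s, s, alpha=0.10, h=H)

    def test_statistic_matches_hand_computation(self, eight_leaf_tree):
        from lshplace.distance import log_likelihood
        from scipy.stats import chi2
        a = _score(eight_leaf_tree.leaves[0], expected_hist(0.03))
        b = _score(eight_leaf_tree.leaves[1], expected_hist(0.15))
        stat = 2 * (a.loglik - log_likelihood(b.d_hat, a.hist, H))
        assert stat >= 0
        want = stat > chi2.ppf(0.90, 1)
        assert lrt_distinguishable(a, b, alpha=0.10, h=H) == want

    def test_alpha_one_limit_distinguishes_everything(self, eight_leaf_tree):
        a = _score(eight_leaf_tree.leaves[0], expected_hist(0.050))
        b = _score(eight_leaf_tree.leaves[1], expected_hist(0.051))
        assert lrt_distinguishable(a, b, alpha=0.9999, h=H)
        assert not lrt_distinguishable(a, a, alpha=0.9999, h=H)


class TestPlaceRead:
    def test_noise_free_query_placed_as_sister_to_true_cherry(self, eight_leaf_tree):
        """A query equidistant-minimal to the (R0,R1) cherry, with
        model-expectation histograms, is placed on the cherry's edge."""
        distances = {"R0": 0.03, "R1": 0.03, "R2": 0.12, "R3": 0.12}
        distances.update({r: 0.25 for r in ["R4", "R5", "R6", "R7"]})
        hists = leaf_hists_for_query(distances)
        scores = clade_histograms(eight_leaf_tree, hists, L,
                                  {r: 0.25 for r in distances}, K, H, DELTA)
        res = place_read(scores, eight_leaf_tree, alpha=0.10, tau=2, h=H)
        assert res.status == "placed"
        got = ({n.label for n in res.node.children} if not res.node.is_leaf
               else {res.node.label})
        assert got == {"R0", "R1"}
        assert res.pendant == 0.0
        assert res.distal == pytest.approx((res.node.length or 0) / 2)

    def test_all_tied_goes_to_root_unplaced(self, eight_leaf_tree):
        distances = {f"R{i}": 0.05 for i in range(8)}
        hists = leaf_hists_for_query(distances)
        scores = clade_histograms(eight_leaf_tree, hists, L,
                                  {r: 0.25 for r in distances}, K, H, DELTA)
        res = place_read(scores, eight_leaf_tree, alpha=0.10, tau=2, h=H)
        assert res.status == "unplaced"
        assert res.node.parent is None

    def test_tau_filter_on_fractional_counts(self, eight_leaf_tree):
        node = eight_leaf_tree.leaves[0]
        v = np.array([0.4, 0.3, 0.2, 0.05, 0.0])
        hist = MatchHistogram(v=v, u=TRIALS - v.sum(), rho=0.25, L=L, k=K)
        scores = {node.index: _score(node, hist)}
        res = place_read(scores, eight_leaf_tree, alpha=0.10, tau=2, h=H)
        assert res.status == "unplaced"  # sum_{i<=tau} v = 0.9 <= 1

    def test_empty_scores_unmapped(self, eight_leaf_tree):
        assert place_read({}, eight_leaf_tree).status == "unmapped"

    def test_candidate_set_shrinks_with_alpha(self, eight_leaf_tree):
        distances = {"R0": 0.04, "R1": 0.05, "R2": 0.06, "R3": 0.08}
        distances.update({r: 0.25 for r in ["R4", "R5", "R6", "R7"]})
        hists = leaf_hists_for_query(distances)
        scores = clade_histograms(eight_leaf_tree, hists, L,
                                  {r: 0.25 for r in distances}, K, H, DELTA)
        sizes = []
        for alpha in [0.01, 0.10, 0.5, 0.99]:
            res = place_read(scores, eight_leaf_tree, alpha=alpha, tau=2, h=H)
            sizes.append(len(res.tied))
        assert sizes == sorted(sizes, reverse=True)


class TestWeights:
    def test_singleton_candidate_weight_one(self, eight_leaf_tree):
        s = _score(eight_leaf_tree.leaves[0], expected_hist(0.05))
        w = multiplacement_weights(s, [s], H)
        assert w[0][1] == pytest.approx(1.0)

    def test_exact_tie_splits_evenly_and_sums_to_one(self, eight_leaf_tree):
        a = _score(eight_leaf_tree.leaves[0], expected_hist(0.05))
        b = _score(eight_leaf_tree.leaves[1], expected_hist(0.05))
        w = multiplacement_weights(a, [a, b], H)
        assert w[0][1] == pytest.approx(0.5)
        assert sum(x for _n, x in w) == pytest.approx(1.0, abs=1e-12)


class TestClosestAndLeafSets:
    def test_closest_reference_rules(self):
        est = {
            "x": DistanceEstimate(0.10, -5.0, 30),
            "y": DistanceEstimate(0.02, -4.0, 30),
        }
        assert closest_reference(est) == "y"
        tie = {
            "b": DistanceEstimate(0.02, -4.0, 30),
            "a": DistanceEstimate(0.02, -4.0, 40),
        }
        assert closest_reference(tie) == "a"  # more matches wins

    def test_leaf_set_contains_ties(self, eight_leaf_tree):
        leaves = eight_leaf_tree.leaves
        scores = {
            "R0": _score(leaves[0], expected_hist(0.05)),
            "R1": _score(leaves[1], expected_hist(0.05)),
            "R2": _score(leaves[2], expected_hist(0.30)),
        }
        got = indistinguishable_leaf_set(scores, alpha=0.10, h=H)
        assert {"R0", "R1"} <= got
        assert "R2" not in got

    def test_single_leaf_returns_itself(self, eight_leaf_tree):
        scores = {"R0": _score(eight_leaf_tree.leaves[0], expected_hist(0.1))}
        assert indistinguishable_leaf_set(scores, alpha=0.10, h=H) == {"R0"}


class TestTaxonomic:
    def test_single_genome_species_equals_genome_histogram(self):
        tax = TaxonomyTree(
            tree=Phylogeny.from_newick("(sp1:1,sp2:1);"),
            species_map={"g1": "sp1", "g2": "sp2"})
        h = expected_hist(0.04)
        res = place_taxonomic({"g1": h}, tax, L,
                              {"g1": 0.25, "g2": 0.25}, K, H, DELTA)
        assert res.status in {"placed", "unplaced"}

    def test_read_matching_single_species_placed_there(self):
        nwk = "((sp1:1,sp2:1):1,(sp3:1,sp4:1):1);"
        tax = TaxonomyTree(
            tree=Phylogeny.from_newick(nwk),
            species_map={f"g{i}": f"sp{i}" for i in range(1, 5)})
        hists = {"g1": expected_hist(0.01)}
        res = place_taxonomic(hists, tax, L, {f"g{i}": 0.25 for i in range(1, 5)},
                              K, H, DELTA)
        assert res.status == "placed"
        assert res.node.label == "sp1"

    def test_genus_level_placement_when_species_tie(self):
        nwk = "((sp1:1,sp2:1)genus1:1,(sp3:1,sp4:1)genus2:1);"
        tax = TaxonomyTree(
            tree=Phylogeny.from_newick(nwk),
            species_map={f"g{i}": f"sp{i}" for i in range(1, 5)})
        hists = {"g1": expected_hist(0.05), "g2": expected_hist(0.05)}
        res = place_taxonomic(hists, tax, L, {f"g{i}": 0.25 for i in range(1, 5)},
                              K, H, DELTA)
        assert res.status == "placed"
        assert {c.label for c in res.node.children} == {"sp1", "sp2"}

    def test_unknown_species_mapping_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            TaxonomyTree(tree=Phylogeny.from_newick("(sp1:1,sp2:1);"),
                         species_map={"g1": "nope"})


class TestJplace:
    def test_round_trip_and_conventions(self, eight_leaf_tree, tmp_path):
        distances = {"R0": 0.03, "R1": 0.03, "R2": 0.12, "R3": 0.12}
        distances.update({r: 0.25 for r in ["R4", "R5", "R6", "R7"]})
        hists = leaf_hists_for_query(distances)
        scores = clade_histograms(eight_leaf_tree, hists, L,
                                  {r: 0.25 for r in distances}, K, H, DELTA)
        res = place_read(scores, eight_leaf_tree, alpha=0.10, tau=2, h=H)
        out = tmp_path / "out.jplace"
        write_jplace({"read1": res, "skipped": PlacementResult(status="unplaced")},
                     eight_leaf_tree, str(out))
        doc = json.loads(out.read_text())
        assert doc["version"] == 3
        assert doc["fields"][0] == "edge_num"
        # edge numbers in the tree string must cover every non-root node
        import re
        edges = sorted(int(m) for m in re.findall(r"\{(\d+)\}", doc["tree"]))
        n_edges = len(eight_leaf_tree.nodes) - 1
        assert edges == list(range(n_edges))
        assert len(doc["placements"]) == 1  # unplaced reads are not emitted
        rows = doc["placements"][0]["p"]
        assert sum(r[2] for r in rows) == pytest.approx(1.0, abs=1e-12)
        lengths = {n.edge_num: (n.length or 0.0) for n in eight_leaf_tree.nodes
                   if n.parent is not None}
        for edge, _ll, _w, distal, pendant in rows:
            assert pendant == 0.0
            assert distal == pytest.approx(lengths[edge] / 2)
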