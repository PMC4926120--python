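"""Neighbour joining, bootstrap supports, Newick round trips."""

import re

import numpy as np
import pytest

from barcodiag.distances import DistanceMatrix
from barcodiag.errors import TreeError
from barcodiag.phylo import (
    bipartitions,
    bootstrap_support,
    from_newick,
    neighbor_joining,
    to_newick,
    tree_length,
)
from barcodiag.seqio import Alignment, SeqRecord


def random_additive_matrix(n_taxa, rng):
    """Random unrooted binary tree -> path-length distance matrix + bipartitions.

    Built by the reverse of agglomeration: grow a tree by splitting leaves,
    then sum branch lengths along paths (independent of the NJ code).
    """
    # star over 3 leaves, then attach leaves to random edges
    import networkx as nx

    g = nx.Graph()
    g.add_node("internal0")
    for i in range(3):
        g.add_edge(f"L{i}", "internal0", weight=float(rng.uniform(0.05, 1.0)))
    next_internal = 1
    for i in range(3, n_taxa):
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"internal{next_internal}"
        next_internal += 1
        f = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * f)
        g.add_edge(mid, v, weight=w * (1 - f))
        g.add_edge(mid, f"L{i}", weight=float(rng.uniform(0.05, 1.0)))
    leaves = [f"L{i}" for i in range(n_taxa)]
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    values = np.array([[0.0 if a == b else dist[a][b] for b in leaves] for a in leaves])
    values = (values + values.T) / 2.0  # exact symmetry despite float summation order

    # true bipartitions: leaf sets separated by each internal edge
    anchor = min(leaves)
    true_bps = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(l for l in leaves if l in comp)
        g.add_edge(u, v, weight=dist[u][v] if u in dist else 0.1)
        if anchor in side:
            side = frozenset(set(leaves) - side)
        if 2 <= len(side) <= n_taxa - 2:
            true_bps.add(side)
    return DistanceMatrix(labels=leaves, values=values), true_bps


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        d_ab, d_ac, d_bc = 0.3, 0.5, 0.6
        m = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, 0.6, 0]]),
        )
        tree = neighbor_joining(m)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_five_taxon_hand_tree_recovered(self):
        # caterpillar tree ((A,B),(C,(D,E))) with known branch lengths;
        # distances are hand-summed path lengths
        bl = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.15, "E": 0.25,
              "AB-i": 0.4, "DE-i": 0.35}
        leaves = ["A", "B", "C", "D", "E"]

        def path(x, y):
            # central node joins {AB-internal, C, DE-internal}
            side = {"A": "ab", "B": "ab", "C": "c", "D": "de", "E": "de"}
            up = {
                "A": bl["A"] + bl["AB-i"], "B": bl["B"] + bl["AB-i"],
                "C": bl["C"],
                "D": bl["D"] + bl["DE-i"], "E": bl["E"] + bl["DE-i"],
            }
            if side[x] == side[y]:
                return bl[x] + bl[y]
            return up[x] + up[y]

        values = np.array([[0.0 if a == b else path(a, b) for b in leaves] for a in leaves])
        tree = neighbor_joining(DistanceMatrix(labels=leaves, values=values))
        assert bipartitions(tree) == {
            frozenset({"A", "B"}) if "A" not in min(leaves) else frozenset({"C", "D", "E"}),
            frozenset({"D", "E"}),
        }
        assert tree_length(tree) == pytest.approx(sum(bl.values()))

    @pytest.mark.parametrize("n_taxa", [6, 8, 10])
    def test_additive_matrix_exact_recovery(self, n_taxa):
        for seed in range(3):
            rng = np.random.default_rng(1000 * n_taxa + seed)
            m, true_bps = random_additive_matrix(n_taxa, rng)
            tree = neighbor_joining(m)
            assert bipartitions(tree) == true_bps

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(42)
        m, _ = random_additive_matrix(7, rng)
        noise = rng.uniform(0, 0.01, size=m.values.shape)
        noisy = m.values + (noise + noise.T) * (1 - np.eye(len(m.labels)))
        ours = neighbor_joining(DistanceMatrix(labels=m.labels, values=noisy))
        theirs = skbio_nj(skbio.DistanceMatrix(noisy, ids=m.labels))
        their_bps = set()
        leaves = set(m.labels)
        anchor = min(leaves)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                their_bps.add(side)
        assert bipartitions(ours) == their_bps

    def test_total_length_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        m, _ = random_additive_matrix(8, rng)
        base = tree_length(neighbor_joining(m))
        perm = rng.permutation(len(m.labels))
        shuffled = DistanceMatrix(
            labels=[m.labels[i] for i in perm],
            values=m.values[np.ix_(perm, perm)],
        )
        assert tree_length(neighbor_joining(shuffled)) == pytest.approx(base)

    def test_too_few_taxa_and_missing_entries(self):
        with pytest.raises(TreeError):
            neighbor_joining(DistanceMatrix(labels=["A", "B"], values=np.zeros((2, 2))))
        values = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0.0]])
        with pytest.raises(TreeError):
            neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], values=values))


@pytest.fixture(scope="module")
def two_group_alignment():
    from barcodiag.fixtures import SimSpec, simulate_library

    return simulate_library(
        SimSpec(n_species=2, n_per_species=3, intra=0.0, inter=0.20, seed=5)
    )


class TestBootstrap:
    def test_distinct_groups_full_support(self, two_group_alignment):
        lib = two_group_alignment
        tree = bootstrap_support(lib.alignment, reps=50, seed=1)
        group = frozenset(
            rid for rid, sp in lib.species_of.items() if sp == "sp02"
        )
        leaves = frozenset(lib.species_of)
        anchor = min(leaves)
        want = frozenset(leaves - group) if anchor in group else group
        supports = {
            frozenset(lf.taxon.label for lf in node.leaf_iter()): node.label
            for node in tree.preorder_node_iter()
            if node is not tree.seed_node and not node.is_leaf()
        }
        matching = [
            int(lab) for side, lab in supports.items()
            if lab is not None and (side == want or frozenset(leaves - side) == want)
        ]
        assert matching and all(s == 100 for s in matching)

    def test_single_replicate_supports_binary(self, two_group_alignment):
        tree = bootstrap_support(two_group_alignment.alignment, reps=1, seed=9)
        labels = [
            int(node.label)
            for node in tree.preorder_node_iter()
            if node.label is not None and not node.is_leaf()
        ]
        assert labels and all(s in (0, 100) for s in labels)

    def test_same_seed_identical_output(self, two_group_alignment):
        aln = two_group_alignment.alignment
        t1 = to_newick(bootstrap_support(aln, reps=10, seed=4))
        t2 = to_newick(bootstrap_support(aln, reps=10, seed=4))
        assert t1 == t2


class TestNewick:
    def test_three_leaf_form(self):
        m = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0.0]]),
        )
        text = to_newick(neighbor_joining(m))
        assert text.startswith("(")
        assert text.rstrip().endswith(";")
        for leaf in "ABC":
            assert f"{leaf}:" in text

    def test_round_trip_bipartitions(self):
        rng = np.random.default_rng(8)
        m, _ = random_additive_matrix(5, rng)
        tree = neighbor_joining(m)
        back = from_newick(to_newick(tree))
        assert bipartitions(back) == bipartitions(tree)

    def test_supports_in_internal_label_position(self, sim_library):
        sub = Alignment(sim_library.alignment.records[::4])
        tree = bootstrap_support(sub, reps=5, seed=2)
        text = to_newick(tree)
        assert re.search(r"\)\d+:", text)
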