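"""Distances, neighbor joining, RF congruence, clades, amplicon typing."""

import itertools
import math
import random

import dendropy
import numpy as np
import pandas as pd
import pytest

from mtmarker import simkit
from mtmarker.cladephylo import (
    CladeModel,
    DistanceMatrix,
    assign_clades,
    classify_amplicons,
    nj_tree,
    p_distance_matrix,
    resolution_score,
    rf_distance,
)
from mtmarker.seqcore import CircularGenome, Interval, subseq


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary tree; returns (adjacency, leaf labels, newick).

    Built by splitting a random edge for each new leaf; branch lengths are
    bounded away from zero so no internal edge collapses.
    """
    adj = {}  # node -> {nbr: length}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    leaves = [f"L{i}" for i in range(n_leaves)]
    nxt = [0]

    def inner():
        nxt[0] += 1
        return f"I{nxt[0]}"

    c = inner()
    for l in leaves[:3]:
        connect(c, l, rng.uniform(0.1, 1.0))
    for l in leaves[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.randrange(len(edges))]
        w = adj[u][v]
        m = inner()
        disconnect(u, v)
        f = rng.uniform(0.2, 0.8)
        connect(u, m, w * f)
        connect(m, v, w * (1 - f))
        connect(m, l, rng.uniform(0.1, 1.0))

    def newick(node, parent):
        if node.startswith("L"):
            return node
        parts = [
            f"{newick(ch, node)}:{adj[node][ch]:.10g}"
            for ch in adj[node]
            if ch != parent
        ]
        return "(" + ",".join(parts) + ")"

    def dist(a, b):
        # BFS over the tree
        stack = [(a, None, 0.0)]
        while stack:
            node, par, acc = stack.pop()
            if node == b:
                return acc
            for nb, w in adj[node].items():
                if nb != par:
                    stack.append((nb, node, acc + w))
        raise AssertionError

    d = np.array([[0.0 if a == b else dist(a, b) for b in leaves] for a in leaves])
    return DistanceMatrix(labels=leaves, d=d), newick(c, None) + ";"


def patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


class TestPDistance:
    def test_identical_all_zero(self):
        dm = p_distance_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert (dm.d == 0).all()

    def test_single_difference(self):
        dm = p_distance_matrix({"a": "AAAAAAAAAA", "b": "AAAAAAAAAT"})
        assert dm.get("a", "b") == pytest.approx(0.1)

    def test_jc69_closed_form(self):
        dm = p_distance_matrix({"a": "A" * 10, "b": "A" * 9 + "T"}, jc69=True)
        expect = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert dm.get("a", "b") == pytest.approx(expect, abs=5e-5)
        assert round(dm.get("a", "b"), 4) == 0.1073

    def test_jc69_saturation_guarded(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "AAAA", "b": "TTTT"}, jc69=True)

    def test_pairwise_deletion(self):
        dm = p_distance_matrix({"a": "ACGT", "b": "NCGA"})
        assert dm.get("a", "b") == pytest.approx(1 / 3)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        nwk = nj_tree(DistanceMatrix(labels=["A", "B", "C"], d=d))
        p = patristic(nwk)
        assert p[frozenset(("A", "B"))] == pytest.approx(5)
        assert p[frozenset(("A", "C"))] == pytest.approx(9)
        assert p[frozenset(("B", "C"))] == pytest.approx(10)

    def test_additive_six_leaf_recovery(self):
        """NJ recovers topology and branch lengths from additive distances."""
        rng = random.Random(11)
        for _ in range(25):
            dm, true_nwk = random_additive_tree(6, rng)
            est = nj_tree(dm)
            assert rf_distance(est, true_nwk) == 0
            pd_est = patristic(est)
            for i, j in itertools.combinations(range(6), 2):
                key = frozenset((dm.labels[i], dm.labels[j]))
                assert pd_est[key] == pytest.approx(dm.d[i, j], abs=1e-9)

    def test_q_tie_lexicographic(self):
        # d_AB = d_AC = 1, all other distances 2: Q ties at (A,B), (A,C),
        # (B,D), (C,D); the lexicographically smallest pair (A,B) is joined
        # first, fixing the AB|CD split.
        d = np.full((4, 4), 2.0) - 2 * np.eye(4)
        lab = ["A", "B", "C", "D"]
        d[0, 1] = d[1, 0] = 1.0
        d[0, 2] = d[2, 0] = 1.0
        nwk = nj_tree(DistanceMatrix(labels=lab, d=d))
        assert rf_distance(nwk, "((A,B),(C,D));") == 0

    def test_all_zero_matrix_star(self):
        d = np.zeros((5, 5))
        nwk = nj_tree(DistanceMatrix(labels=list("ABCDE"), d=d))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 1  # star: single internal node

    def test_least_squares_oracle(self):
        """On additive 5-leaf matrices NJ matches exhaustive LS tree search."""
        rng = random.Random(13)
        for _ in range(5):
            dm, true_nwk = random_additive_tree(5, rng)
            est = nj_tree(dm)
            best_nwk, best_res = None, None
            for nwk in _all_unrooted_topologies(dm.labels):
                res = _ls_residual(nwk, dm)
                if best_res is None or res < best_res - 1e-12:
                    best_nwk, best_res = nwk, res
            assert rf_distance(est, best_nwk) == 0


def _all_unrooted_topologies(labels):
    """Enumerate unrooted binary topologies by sequential edge insertion."""
    assert len(labels) >= 3
    base = [(labels[0], "X1"), (labels[1], "X1"), (labels[2], "X1")]
    trees = [(base, 1)]
    for leaf in labels[3:]:
        new_trees = []
        for edges, k in trees:
            for idx, (u, v) in enumerate(edges):
                m = f"X{k + 1}"
                ne = [e for i, e in enumerate(edges) if i != idx]
                ne += [(u, m), (m, v), (leaf, m)]
                new_trees.append((ne, k + 1))
        trees = new_trees
    for edges, _ in trees:
        yield _edges_to_newick(edges, labels)


def _edges_to_newick(edges, labels):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = next(n for n in adj if n.startswith("X"))

    def rec(node, parent):
        kids = [n for n in adj[node] if n != parent]
        if not kids:
            return node
        return "(" + ",".join(rec(c, node) for c in kids) + ")"

    return rec(root, None) + ";"


def _ls_residual(newick, dm):
    """Least-squares branch-length fit residual of a topology to distances."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    labels = dm.labels
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    leaf_sets = []
    for e in edges:
        leaf_sets.append({l.taxon.label for l in e.head_node.leaf_iter()})
    for r, (i, j) in enumerate(pairs):
        for c, ls in enumerate(leaf_sets):
            if (labels[i] in ls) != (labels[j] in ls):
                A[r, c] = 1
    y = np.array([dm.d[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


class TestRobinsonFoulds:
    def test_self_zero(self):
        nwk = "((A,B),(C,D),E);"
        assert rf_distance(nwk, nwk) == 0

    def test_quartet_topologies(self):
        assert rf_distance("((A,B),C,D);", "((A,C),B,D);") == 2

    def test_star_vs_resolved(self):
        star = "(A,B,C,D,E,F);"
        resolved = "((A,B),((C,D),E),F);"
        tree = dendropy.Tree.get(data=resolved, schema="newick")
        n_internal_edges = sum(
            1
            for e in tree.preorder_edge_iter()
            if e.head_node.parent_node and not e.head_node.is_leaf()
        )
        assert rf_distance(star, resolved) == n_internal_edges

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError):
            rf_distance("((A,B),C,D);", "((A,B),C,E);")

    def test_metric_properties_on_random_triples(self):
        rng = random.Random(17)
        for _ in range(5):
            trees = [random_additive_tree(6, rng)[1] for _ in range(3)]
            d01 = rf_distance(trees[0], trees[1])
            d12 = rf_distance(trees[1], trees[2])
            d02 = rf_distance(trees[0], trees[2])
            assert d01 == rf_distance(trees[1], trees[0])
            assert d02 <= d01 + d12


class TestResolution:
    def test_marker_with_all_variants_scores_one(self, small_reference):
        """With every variant inside the marker, marker and genome trees agree."""
        spec = simkit.PanelSpec(
            genome_length=5000,
            planted_window=Interval(1000, 1399),
            background_rate=0.0,
            planted_rate=5e-3,
            seed=21,
        )
        strains, truth = simkit.simulate_strains(small_reference, spec)
        marker_aln = {g.id: subseq(g, truth.true_window) for g in strains}
        genome_aln = {g.id: g.seq for g in strains}
        res = resolution_score(marker_aln, genome_aln)
        assert res.score == 1.0 and res.rf == 0

    def test_uninformative_marker_scores_half(self, small_reference, small_panel):
        _, strains, truth = small_panel
        # pick a 400-nt window verified to carry no planted variant
        positions = set(truth.true_snvs["position"])
        start = next(
            s
            for s in range(1, small_reference.length - 399)
            if not any(p in positions for p in range(s, s + 400))
        )
        marker_aln = {g.id: subseq(g, Interval(start, start + 399)) for g in strains}
        genome_aln = {g.id: g.seq for g in strains}
        res = resolution_score(marker_aln, genome_aln)
        n = len(strains)
        assert res.score == pytest.approx(1 - (n - 3) / (2 * (n - 3)))
        assert res.warning is not None

    def test_three_taxa_scores_one(self):
        aln = {"a": "ACGT", "b": "ACGA", "c": "ACTT"}
        res = resolution_score(aln, aln)
        assert res.score == 1.0


class TestClades:
    def test_identical_one_clade(self):
        cm = assign_clades({"a": "ACGT" * 100, "b": "ACGT" * 100})
        assert cm.n_clades == 1

    def test_three_groups_two_diffs_apart(self):
        base = ["A"] * 400
        seqs = {}
        for k, positions in enumerate([(), (10, 20), (100, 110, 120)]):
            s = base.copy()
            for p in positions:
                s[p] = "T"
            seqs[f"g{k}a"] = "".join(s)
            seqs[f"g{k}b"] = "".join(s)
        cm = assign_clades(seqs, linkage_cutoff=0.005)
        assert cm.n_clades == 3
        assert cm.clade_of["g0a"] == cm.clade_of["g0b"]

    def test_large_cutoff_single_clade(self):
        cm = assign_clades(
            {"a": "AAAA" * 100, "b": "TTTT" * 100, "c": "GGGG" * 100},
            linkage_cutoff=2.0,
        )
        assert cm.n_clades == 1

    def test_monotone_in_cutoff(self, small_reference, small_panel):
        _, strains, truth = small_panel
        aln = {g.id: subseq(g, truth.true_window) for g in strains}
        ks = [
            assign_clades(aln, linkage_cutoff=c).n_clades
            for c in (1e-9, 0.003, 0.01, 0.05, 1.0)
        ]
        assert ks == sorted(ks, reverse=True)

    def test_numbering_by_smallest_member(self):
        seqs = {"z": "A" * 400, "a": "T" * 400, "m": "A" * 400}
        cm = assign_clades(seqs)
        assert cm.clade_of["a"] == 1  # clade containing the smallest label
        assert cm.clade_of["m"] == cm.clade_of["z"] == 2


class TestAmpliconTyping:
    haps = {
        "clade1": "A" * 400,
        "clade2": "A" * 390 + "T" * 10,
        "clade3": "C" * 10 + "A" * 390,
    }

    def _meta(self, ids):
        return pd.DataFrame(
            {
                "amplicon": ids,
                "site": ["s1"] * len(ids),
                "region": ["Bohai Sea"] * len(ids),
            }
        )

    def test_exact_match_assigned(self):
        amps = [CircularGenome("a1", self.haps["clade2"])]
        t = classify_amplicons(amps, self._meta(["a1"]), self.haps)
        row = t.per_amplicon.iloc[0]
        assert (row["clade"], row["distance"]) == ("clade2", 0.0)
        assert t.region_clade_matrix.loc["Bohai Sea", "clade2"] == 1

    def test_equidistant_ambiguous(self):
        # 5 T's: distance 5/400 to clade1 and clade2 alike
        amp = CircularGenome("a1", "A" * 390 + "T" * 5 + "A" * 5)
        t = classify_amplicons([amp], self._meta(["a1"]), self.haps)
        assert t.per_amplicon.iloc[0]["clade"] == "ambiguous"

    def test_distant_amplicon_unassigned(self):
        amp = CircularGenome("a1", "G" * 400)
        t = classify_amplicons([amp], self._meta(["a1"]), self.haps)
        assert t.per_amplicon.iloc[0]["clade"] == "unassigned"

    def test_length_discordant_aligned(self):
        amp = CircularGenome("a1", self.haps["clade3"][5:395])
        t = classify_amplicons([amp], self._meta(["a1"]), self.haps)
        assert t.per_amplicon.iloc[0]["clade"] == "clade3"

    def test_survey_recovery_ground_truth(self, small_reference, small_panel):
        """Planted survey: region x clade matrix matches the generator's truth."""
        spec, strains, truth = small_panel
        win = truth.true_window
        by_clade = {}
        for g in strains:
            by_clade.setdefault(spec.clade_assignment[g.id], subseq(g, win))
        regions = {f"r{i}": [] for i in range(1, 8)}
        regions["r2"] = ["clade1", "clade3"]
        regions["r6"] = ["clade2"]
        amps, meta = simkit.simulate_amplicon_survey(by_clade, regions, 3, 4, 0.0, 5)
        t = classify_amplicons(amps, meta, by_clade)
        assert (t.per_amplicon["clade"] == meta["true_clade"]).all()
        truth_mat = (
            meta.groupby(["region", "true_clade"]).size().unstack(fill_value=0)
        )
        got = t.region_clade_matrix.loc[truth_mat.index, truth_mat.columns]
        assert (got.values == truth_mat.values).all()
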