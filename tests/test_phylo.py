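"""Fitch parsimony, CI/RI, neighbor joining, search and bootstrap."""

import itertools

import numpy as np
import pytest

from plastomekit import phylo as ph
from conftest import random_dna


def build_tree(splits, labels):
    """Small helper: tree from a nested-insertion recipe used in tests."""
    t = ph.Tree.star(labels[:3])
    for lab, edge_idx in splits:
        ph._insert_leaf(t, t.edges()[edge_idx], lab)
    return t


def brute_force_fitch(tree, alignment):
    """Minimal mutation count over all internal labelings (oracle)."""
    leaves = tree.leaves()
    internal = [n for n in tree.adj if n not in leaves]
    edges = tree.edges()
    total = 0
    L = len(next(iter(alignment.values())))
    for site in range(L):
        states = {n: alignment[tree.label[n]][site] for n in leaves}
        best = None
        for combo in itertools.product("ACGT", repeat=len(internal)):
            lab = {**states, **dict(zip(internal, combo))}
            cost = sum(
                1 for u, v in edges
                if lab[u] != lab[v] and lab[u] in "ACGT" and lab[v] in "ACGT"
            )
            best = cost if best is None else min(best, cost)
        total += best
    return total


def test_invariant_site_has_zero_steps():
    t = build_tree([("t4", 0)], ["t1", "t2", "t3"])
    assert ph.fitch_length(t, {f"t{i}": "A" for i in range(1, 5)}) == 0


def test_four_taxon_split_steps_depend_on_topology():
    aln = {"t1": "A", "t2": "A", "t3": "C", "t4": "C"}
    grouped = ph.Tree.star(["t1", "t2", "t3"])
    e = [x for x in grouped.edges()
         if grouped.label.get(x[0]) == "t3" or grouped.label.get(x[1]) == "t3"][0]
    ph._insert_leaf(grouped, e, "t4")  # ((t1,t2),(t3,t4))
    split = ph.Tree.star(["t1", "t3", "t2"])
    e = [x for x in split.edges()
         if split.label.get(x[0]) == "t2" or split.label.get(x[1]) == "t2"][0]
    ph._insert_leaf(split, e, "t4")  # ((t1,t3),(t2,t4))
    assert ph.fitch_length(grouped, aln) == 1
    assert ph.fitch_length(split, aln) == 2


@pytest.mark.parametrize("trial", range(3))
def test_fitch_equals_brute_force_labeling(trial):
    rng = np.random.default_rng(60 + trial)
    labels = [f"t{i}" for i in range(6)]
    aln = {lab: random_dna(rng, 12) for lab in labels}
    for k, tree in enumerate(ph.enumerate_topologies(labels)):
        if k % 21 != 0:  # sample 5 of the 105 topologies
            continue
        assert ph.fitch_length(tree, aln) == brute_force_fitch(tree, aln)


def test_gaps_are_missing_data():
    t = build_tree([("t4", 0)], ["t1", "t2", "t3"])
    aln = {"t1": "A", "t2": "-", "t3": "C", "t4": "N"}
    assert ph.fitch_length(t, aln) == 1


def test_missing_leaf_raises():
    t = build_tree([("t4", 0)], ["t1", "t2", "t3"])
    with pytest.raises(ValueError):
        ph.fitch_length(t, {"t1": "A", "t2": "A", "t3": "A"})


def test_topology_count_is_double_factorial():
    assert sum(1 for _ in ph.enumerate_topologies([f"x{i}" for i in range(5)])) == 15
    assert sum(1 for _ in ph.enumerate_topologies([f"x{i}" for i in range(6)])) == 105


def test_ci_one_iff_no_homoplasy():
    labels = ["t1", "t2", "t3", "t4", "t5", "t6"]
    true = build_tree([("t4", 0), ("t5", 0), ("t6", 2)], labels[:3])
    aln = {lab: "" for lab in labels}
    for side in true.bipartitions():
        for lab in labels:
            aln[lab] += "A" if lab in side else "C"
    res = ph.ci_ri(true, aln)
    assert res.ci == 1.0 and res.ri == 1.0
    # the same characters on a wrong topology show homoplasy
    wrong = build_tree([("t6", 0), ("t5", 0), ("t4", 2)], labels[:3])
    res_w = ph.ci_ri(wrong, aln)
    assert res_w.length > res.length and res_w.ci < 1.0


def test_site_ci_half_on_wrong_topology():
    """A binary site needing two steps has site CI = m/s = 1/2."""
    aln = {"t1": "A", "t2": "C", "t3": "A", "t4": "C"}
    tree = build_tree([("t4", 1)], ["t1", "t2", "t3"])
    res = ph.ci_ri(tree, aln)
    if res.length == 2:  # the pairing split across the tree
        assert res.ci == 0.5


def test_constant_alignment_ci_undefined():
    t = build_tree([("t4", 0)], ["t1", "t2", "t3"])
    res = ph.ci_ri(t, {f"t{i}": "AAAA" for i in range(1, 5)})
    assert res.length == 0 and res.ci is None and res.ri is None


def test_informative_only_and_gap_exclusion_switches():
    aln = {"t1": "AAC-", "t2": "AACA", "t3": "CAAA", "t4": "CGAA"}
    full = ph.ci_ri(build_tree([("t4", 0)], ["t1", "t2", "t3"]), aln)
    info = ph.ci_ri(build_tree([("t4", 0)], ["t1", "t2", "t3"]), aln,
                    include_uninformative=False)
    nogap = ph.ci_ri(build_tree([("t4", 0)], ["t1", "t2", "t3"]), aln,
                     exclude_gapped=True)
    assert info.min_steps <= full.min_steps
    assert nogap.min_steps <= full.min_steps


def test_nj_exact_on_additive_matrix():
    t = ph.Tree.star(["a", "b", "c"])
    ph._insert_leaf(t, t.edges()[0], "d")
    ph._insert_leaf(t, t.edges()[2], "e")
    rng = np.random.default_rng(2)
    for u, v in t.edges():
        bl = float(rng.uniform(0.5, 3.0))
        t.adj[u][v] = t.adj[v][u] = bl
    labels, D = ph.tree_distance_matrix(t)
    rec = ph.nj_tree(labels, D)
    assert rec.same_topology(t)
    _, D2 = ph.tree_distance_matrix(rec)
    assert np.allclose(D, D2)


def test_nj_agrees_with_independent_implementation():
    """Cross-check topology against scikit-bio's neighbor joining."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    t = ph.Tree.star(["a", "b", "c"])
    ph._insert_leaf(t, t.edges()[1], "d")
    ph._insert_leaf(t, t.edges()[4], "e")
    ph._insert_leaf(t, t.edges()[0], "f")
    rng = np.random.default_rng(9)
    for u, v in t.edges():
        bl = float(rng.uniform(0.5, 2.0))
        t.adj[u][v] = t.adj[v][u] = bl
    labels, D = ph.tree_distance_matrix(t)
    mine = ph.nj_tree(labels, D)
    theirs = ph.Tree.from_newick(str(skbio_nj(DistanceMatrix(D, labels))))
    assert mine.same_topology(theirs)


def test_nj_label_permutation_gives_isomorphic_tree():
    t = ph.Tree.star(["a", "b", "c"])
    ph._insert_leaf(t, t.edges()[0], "d")
    rng = np.random.default_rng(4)
    for u, v in t.edges():
        bl = float(rng.uniform(0.5, 2.0))
        t.adj[u][v] = t.adj[v][u] = bl
    labels, D = ph.tree_distance_matrix(t)
    perm = [2, 0, 3, 1]
    labels_p = [labels[i] for i in perm]
    D_p = D[np.ix_(perm, perm)]
    assert ph.nj_tree(labels_p, D_p).same_topology(ph.nj_tree(labels, D))


def test_nj_input_validation():
    with pytest.raises(ValueError):
        ph.nj_tree(["a", "b"], np.zeros((2, 2)))
    bad = np.array([[0.0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
    with pytest.raises(ValueError):
        ph.nj_tree(["a", "b", "c"], bad)


def test_newick_round_trip_up_to_rotation():
    t = ph.Tree.star(["a", "b", "c"])
    ph._insert_leaf(t, t.edges()[0], "d")
    ph._insert_leaf(t, t.edges()[3], "e")
    back = ph.Tree.from_newick(t.newick())
    assert back.same_topology(t)


def test_search_recovers_true_tree_and_matches_exhaustive():
    labels = [f"t{i}" for i in range(1, 7)]
    true = build_tree([("t4", 0), ("t5", 0), ("t6", 2)], labels[:3])
    aln = {lab: "" for lab in labels}
    rng = np.random.default_rng(11)
    for side in true.bipartitions():
        for _ in range(15):
            for lab in labels:
                aln[lab] += "A" if lab in side else "C"
    best, res = ph.search_mp(aln, n_starts=5, seed=2)
    exhaustive = min(ph.enumerate_topologies(labels),
                     key=lambda tr: ph.fitch_length(tr, aln))
    assert ph.fitch_length(best, aln) == ph.fitch_length(exhaustive, aln)
    assert best.same_topology(true)
    assert res.ci == 1.0


def test_eight_taxon_clean_signal_recovered_with_ci_one():
    labels = [f"t{i}" for i in range(1, 9)]
    true = build_tree([("t4", 0), ("t5", 2), ("t6", 4), ("t7", 1), ("t8", 6)],
                      labels[:3])
    aln = {lab: "" for lab in labels}
    for side in true.bipartitions():
        for _ in range(12):
            for lab in labels:
                aln[lab] += "G" if lab in side else "T"
    best, res = ph.search_mp(aln, n_starts=8, seed=5)
    assert best.same_topology(true) and res.ci == 1.0


def test_search_score_never_worsens_with_more_starts():
    rng = np.random.default_rng(31)
    aln = {f"t{i}": random_dna(rng, 40) for i in range(1, 8)}
    l1 = ph.fitch_length(ph.search_mp(aln, n_starts=1, seed=7)[0], aln)
    l20 = ph.fitch_length(ph.search_mp(aln, n_starts=20, seed=7)[0], aln)
    assert l20 <= l1


def test_search_deterministic_under_seed(rng):
    aln = {f"t{i}": random_dna(rng, 30) for i in range(1, 7)}
    t1, r1 = ph.search_mp(aln, n_starts=4, seed=9)
    t2, r2 = ph.search_mp(aln, n_starts=4, seed=9)
    assert t1.newick(lengths=False) == t2.newick(lengths=False)
    assert r1 == r2


def test_bootstrap_single_replicate_is_zero_or_hundred(rng):
    aln = {f"t{i}": random_dna(rng, 30) for i in range(1, 7)}
    builder = lambda a: ph.search_mp(a, n_starts=2, seed=3)[0]
    sup = ph.bootstrap_support(aln, builder, n_reps=1, seed=4)
    assert set(sup.values()) <= {0.0, 100.0}


def test_bootstrap_strong_signal_is_full_support():
    labels = [f"t{i}" for i in range(1, 7)]
    true = build_tree([("t4", 0), ("t5", 0), ("t6", 2)], labels[:3])
    aln = {lab: "" for lab in labels}
    for side in true.bipartitions():
        for _ in range(40):
            for lab in labels:
                aln[lab] += "A" if lab in side else "C"
    builder = lambda a: ph.search_mp(a, n_starts=2, seed=1)[0]
    sup = ph.bootstrap_support(aln, builder, n_reps=20, seed=6)
    assert sup and all(v == 100.0 for v in sup.values())
    sup2 = ph.bootstrap_support(aln, builder, n_reps=20, seed=6)
    assert sup == sup2
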