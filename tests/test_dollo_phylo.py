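import numpy as np
import pandas as pd
import pytest

from mirseed._oracles import brute_force_dollo_length
from mirseed.dollo_phylo import (
    PhyloTree,
    TreeError,
    _attachments,
    _binary_states,
    _dollo_total,
    bootstrap_support,
    canonical,
    dollo_length,
    random_rooted_tree,
    robinson_foulds,
    search_mp,
)
from mirseed.synthetic_data import simulate_family_evolution


def all_rooted_trees(labels):
    trees = [labels[0]]
    for x in labels[1:]:
        trees = [t2 for t in trees for t2 in _attachments(t, x)]
    return trees


def exhaustive_mp(matrix, outgroup):
    species = [s for s in matrix.index if s != outgroup]
    states = _binary_states(matrix)
    scored = [
        (_dollo_total((outgroup, t), states), canonical((outgroup, t)))
        for t in all_rooted_trees(species)
    ]
    best = min(s for s, _ in scored)
    return best, sorted({t for s, t in scored if s == best}, key=str)


def test_character_in_all_leaves_costs_one_gain():
    tree = PhyloTree((("A", "B"), ("C", "D")))
    mat = pd.DataFrame({"f": [1, 1, 1, 1]}, index=list("ABCD"))
    score = dollo_length(tree, mat)
    assert score.total_length == 1 and score.losses.tolist() == [0]


def test_singleton_character_costs_one():
    tree = PhyloTree((("A", "B"), ("C", "D")))
    mat = pd.DataFrame({"f": [0, 1, 0, 0]}, index=list("ABCD"))
    assert dollo_length(tree, mat).total_length == 1


def test_absent_character_costs_nothing():
    tree = PhyloTree((("A", "B"), ("C", "D")))
    mat = pd.DataFrame({"f": [0, 0, 0, 0], "g": [1, 0, 1, 0]}, index=list("ABCD"))
    score = dollo_length(tree, mat)
    assert score.gains.tolist() == [0, 1]


def test_dollo_length_matches_brute_force_on_all_four_taxon_shapes(rng):
    shapes = {canonical(t) for t in all_rooted_trees(list("ABCD"))}
    assert len(shapes) == 15
    for tree in shapes:
        for _ in range(20):
            states = {l: int(rng.integers(0, 2)) for l in "ABCD"}
            mat = pd.DataFrame({"f": [states[l] for l in "ABCD"]}, index=list("ABCD"))
            assert (
                dollo_length(PhyloTree(tree), mat).total_length
                == brute_force_dollo_length(tree, states)
            )


def test_length_invariant_to_character_order_and_relabeling(rng):
    tree = random_rooted_tree(list("ABCDEF"), rng)
    mat = pd.DataFrame(
        rng.integers(0, 2, size=(6, 30)), index=list("ABCDEF")
    )
    shuffled = mat[rng.permutation(mat.columns)]
    assert (
        dollo_length(PhyloTree(tree), mat).total_length
        == dollo_length(PhyloTree(tree), shuffled).total_length
    )
    relabel = dict(zip("ABCDEF", "UVWXYZ"))

    def rl(t):
        return relabel[t] if isinstance(t, str) else (rl(t[0]), rl(t[1]))

    mat2 = mat.rename(index=relabel)
    assert (
        dollo_length(PhyloTree(rl(tree)), mat2).total_length
        == dollo_length(PhyloTree(tree), mat).total_length
    )


def test_constant_characters_shift_length_predictably(rng):
    tree = random_rooted_tree(list("ABCDE"), rng)
    mat = pd.DataFrame(rng.integers(0, 2, size=(5, 10)), index=list("ABCDE"))
    base = dollo_length(PhyloTree(tree), mat).total_length
    with_absent = mat.copy()
    with_absent["zero"] = 0
    assert dollo_length(PhyloTree(tree), with_absent).total_length == base
    with_present = mat.copy()
    with_present["one"] = 1
    assert dollo_length(PhyloTree(tree), with_present).total_length == base + 1


def test_leaf_matrix_mismatch_rejected():
    tree = PhyloTree((("A", "B"), ("C", "D")))
    mat = pd.DataFrame({"f": [1, 0, 1]}, index=list("ABC"))
    with pytest.raises(TreeError):
        dollo_length(tree, mat)


@pytest.mark.parametrize("seed", range(6))
def test_branch_and_bound_equals_exhaustive_on_six_taxa(seed):
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(rng.integers(0, 2, size=(6, 25)), index=list("OABCDE"))
    best_ex, trees_ex = exhaustive_mp(mat, "O")
    trees_bb, best_bb = search_mp(mat, "O")
    assert best_bb == best_ex
    assert sorted((canonical(t.root) for t in trees_bb), key=str) == trees_ex


def test_all_identical_rows_tie_every_topology():
    mat = pd.DataFrame(np.ones((4, 5), dtype=int), index=list("OABC"))
    trees, score = search_mp(mat, "O")
    assert len(trees) == 3  # all rooted 3-ingroup topologies tie
    assert score == 5


def test_outgroup_must_exist_and_four_taxa_required():
    mat = pd.DataFrame(np.eye(4, dtype=int), index=list("ABCD"))
    with pytest.raises(TreeError):
        search_mp(mat, "Z")
    with pytest.raises(TreeError):
        search_mp(mat.iloc[:3], "A")


def test_perfect_characters_recover_generating_tree(rng):
    true = random_rooted_tree([f"s{i}" for i in range(6)], rng)
    mat, _ = simulate_family_evolution(true, 60, loss_prob=0.0, seed=3)
    trees, _ = search_mp(mat, "s0")
    assert len(trees) == 1
    assert robinson_foulds(trees[0], PhyloTree(true)) == 0


def test_bootstrap_supports_are_full_on_clean_data(rng):
    true = random_rooted_tree([f"s{i}" for i in range(6)], rng)
    # enough families that no clade loses all its characters in a resample
    mat, _ = simulate_family_evolution(true, 200, loss_prob=0.0, seed=5)
    tree = bootstrap_support(mat, "s0", n_boot=20, seed=1)
    assert tree.supports and all(v == 100.0 for v in tree.supports.values())


def test_bootstrap_seed_determinism_and_zero_boot(rng):
    true = random_rooted_tree([f"s{i}" for i in range(6)], rng)
    mat, _ = simulate_family_evolution(true, 40, loss_prob=0.1, seed=8)
    t1 = bootstrap_support(mat, "s0", n_boot=15, seed=42)
    t2 = bootstrap_support(mat, "s0", n_boot=15, seed=42)
    assert t1.supports == t2.supports
    t0 = bootstrap_support(mat, "s0", n_boot=0)
    assert t0.supports == {}


def test_robinson_foulds_requires_same_taxa():
    with pytest.raises(TreeError):
        robinson_foulds(PhyloTree(("A", ("B", "C"))), PhyloTree(("A", ("B", "D"))))
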