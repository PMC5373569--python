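"""Dollo-parsimony phylogeny from binary miRNA-family characters.

Each family is a presence/absence character evolving under the Dollo
assumption: gained exactly once on the tree, lost any number of times,
never regained.  The length of a character on a rooted tree is therefore
``1 gain + (minimal losses)``, with the gain placed at the most recent
common ancestor of the presence leaves; characters absent from every leaf
contribute 0.  All characters carry equal weight.

Tree search is exact branch-and-bound by stepwise addition: the Dollo
length of a partial tree (a leaf subset) never exceeds that of any
completion, so partial trees scoring worse than the best complete tree are
pruned.  Rooting is by a user-declared outgroup.  Clade support comes from
bootstrap resampling of characters (the package's stand-in for model-based
posterior support).

Trees are lightweight nested tuples — a leaf is its label string, an
internal node a ``(left, right)`` pair — wrapped in :class:`PhyloTree` for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

Tree = "str | tuple"


class TreeError(ValueError):
    pass


def leaf_set(tree) -> frozenset:
    if isinstance(tree, str):
        return frozenset([tree])
    return leaf_set(tree[0]) | leaf_set(tree[1])


def iter_nodes(tree) -> Iterator:
    """Preorder over all nodes (internal tuples and leaf labels)."""
    yield tree
    if isinstance(tree, tuple):
        for child in tree:
            yield from iter_nodes(child)


def canonical(tree):
    """Order children by smallest descendant label; makes trees comparable."""
    if isinstance(tree, str):
        return tree
    kids = sorted((canonical(c) for c in tree), key=lambda t: min(leaf_set(t)))
    return tuple(kids)


def clades(tree) -> set[frozenset]:
    """Non-trivial clades (internal-node leaf sets, excluding the root)."""
    out: set[frozenset] = set()
    for node in iter_nodes(tree):
        if isinstance(node, tuple) and node is not tree:
            ls = leaf_set(node)
            if len(ls) > 1:
                out.add(ls)
    return out


@dataclass
class PhyloTree:
    """A rooted binary tree with optional bootstrap supports per clade."""

    root: object
    supports: dict[frozenset, float] = field(default_factory=dict)
    outgroup: str | None = None

    def __post_init__(self) -> None:
        labels = self.leaves()
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")
        for node in iter_nodes(self.root):
            if isinstance(node, tuple) and len(node) != 2:
                raise TreeError("internal nodes must be binary")

    def leaves(self) -> list[str]:
        def rec(t):
            if isinstance(t, str):
                return [t]
            return rec(t[0]) + rec(t[1])

        return rec(self.root)

    def newick(self) -> str:
        def rec(t):
            if isinstance(t, str):
                return t
            label = ""
            if self.supports:
                sup = self.supports.get(leaf_set(t))
                if sup is not None:
                    label = f"{sup:g}"
            return f"({rec(t[0])},{rec(t[1])}){label}"

        return rec(self.root) + ";"


def random_rooted_tree(labels: Sequence[str], rng: np.random.Generator):
    """Random rooted binary topology by successive joins."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


# ---------------------------------------------------------------------------
# Dollo length


@dataclass
class DolloScore:
    """Total Dollo length and per-character loss counts (gains are implicit)."""

    total_length: int
    losses: np.ndarray  # per character
    gains: np.ndarray  # per character, 0 or 1


def _binary_states(matrix: pd.DataFrame) -> dict[str, np.ndarray]:
    binary = (matrix.to_numpy() >= 1).astype(np.int64)
    return {sp: binary[k] for k, sp in enumerate(matrix.index)}


def dollo_length(tree, matrix: pd.DataFrame) -> DolloScore:
    """Dollo length of every character (column) of ``matrix`` on ``tree``.

    ``matrix`` rows are species (must exactly match the tree's leaves),
    columns are families; values are binarized at >= 1.
    """
    root = tree.root if isinstance(tree, PhyloTree) else tree
    tree_leaves = leaf_set(root)
    if tree_leaves != set(matrix.index):
        raise TreeError(
            f"tree leaves {sorted(tree_leaves)} != matrix species {sorted(matrix.index)}"
        )
    states = _binary_states(matrix)
    return _dollo_score(root, states)


def _dollo_score(root, states: dict[str, np.ndarray]) -> DolloScore:
    nchar = len(next(iter(states.values())))
    naive = np.zeros(nchar, dtype=np.int64)
    m_full = np.zeros(nchar, dtype=np.int64)  # nodes whose subtree holds all presences
    counts_cache: list[np.ndarray] = []

    def count(node) -> np.ndarray:
        if isinstance(node, str):
            c = states[node]
        else:
            c1 = count(node[0])
            c2 = count(node[1])
            c = c1 + c2
            present = c > 0
            naive[present & (c1 == 0)] += 1
            naive[present & (c2 == 0)] += 1
        counts_cache.append(c)
        return c

    total = count(root)
    for c in counts_cache:
        m_full[(c == total) & (total > 0)] += 1
    gains = (total > 0).astype(np.int64)
    losses = np.where(total > 0, naive - (m_full - 1), 0)
    return DolloScore(
        total_length=int((gains + losses).sum()), losses=losses, gains=gains
    )


def _dollo_total(root, states: dict[str, np.ndarray]) -> int:
    return _dollo_score(root, states).total_length


# ---------------------------------------------------------------------------
# Branch-and-bound maximum-parsimony search


def _attachments(tree, leaf):
    """All trees obtained by attaching ``leaf`` on some edge of ``tree``."""
    yield (leaf, tree)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _attachments(left, leaf):
            yield (sub, right)
        for sub in _attachments(right, leaf):
            yield (left, sub)


def search_mp(
    matrix: pd.DataFrame, outgroup: str, method: str = "branch_and_bound"
) -> tuple[list[PhyloTree], int]:
    """Exact MP search under Dollo; returns ALL minimum-length rooted trees.

    The search enumerates ingroup topologies by stepwise addition and roots
    every tree on the pendant edge of ``outgroup``.  Intended for <= ~12
    taxa (the search is exact).
    """
    if method not in ("branch_and_bound", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    species = list(matrix.index)
    if outgroup not in species:
        raise TreeError(f"outgroup {outgroup!r} not among matrix species")
    if len(species) < 4:
        raise TreeError("need at least 4 species")
    states = _binary_states(matrix)
    ingroup = [s for s in species if s != outgroup]

    best_score = np.iinfo(np.int64).max
    best: list = []

    def rec(subtree, remaining: tuple) -> None:
        nonlocal best_score, best
        score = _dollo_total((outgroup, subtree), _restrict(states, subtree, outgroup))
        if method == "branch_and_bound" and score > best_score:
            return
        if not remaining:
            if score < best_score:
                best_score = score
                best = [canonical((outgroup, subtree))]
            elif score == best_score:
                best.append(canonical((outgroup, subtree)))
            return
        for t2 in _attachments(subtree, remaining[0]):
            rec(t2, remaining[1:])

    rec((ingroup[0], ingroup[1]), tuple(ingroup[2:]))
    uniq = sorted(set(best), key=_tree_sort_key)
    return [PhyloTree(t, outgroup=outgroup) for t in uniq], int(best_score)


def _restrict(states, subtree, outgroup):
    keep = leaf_set(subtree) | {outgroup}
    return {sp: arr for sp, arr in states.items() if sp in keep}


def _tree_sort_key(tree) -> str:
    return PhyloTree(tree).newick()


def bootstrap_support(
    matrix: pd.DataFrame,
    outgroup: str,
    n_boot: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """MP tree with clade supports from character bootstrap.

    A clade is counted in a replicate when it appears in *every* MP tree of
    that replicate.  Supports are percentages on the best tree's clades.
    With ``n_boot=0`` the best tree is returned without supports.
    """
    trees, _ = search_mp(matrix, outgroup)
    base = trees[0]
    if n_boot == 0:
        return base
    rng = np.random.default_rng(seed)
    base_clades = clades(base.root)
    hits = {c: 0 for c in base_clades}
    ncol = matrix.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, ncol, size=ncol)
        rep = matrix.iloc[:, cols]
        rep_trees, _ = search_mp(rep, outgroup)
        rep_clades = set.intersection(*(clades(t.root) for t in rep_trees))
        for c in base_clades:
            if c in rep_clades:
                hits[c] += 1
    supports = {c: 100.0 * h / n_boot for c, h in hits.items()}
    return PhyloTree(base.root, supports=supports, outgroup=outgroup)


def robinson_foulds(tree1, tree2) -> int:
    """Unrooted Robinson-Foulds distance between two trees on the same taxa."""
    import dendropy
    from dendropy.calculate import treecompare

    t1 = tree1 if isinstance(tree1, PhyloTree) else PhyloTree(tree1)
    t2 = tree2 if isinstance(tree2, PhyloTree) else PhyloTree(tree2)
    if set(t1.leaves()) != set(t2.leaves()):
        raise TreeError("trees are on different taxon sets")
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.newick(), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=t2.newick(), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return int(treecompare.symmetric_difference(d1, d2))
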