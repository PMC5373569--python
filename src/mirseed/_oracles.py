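"""Brute-force reference implementations.

These enumerate solution spaces exhaustively at tiny problem sizes and are
deliberately independent of the dynamic programs and search procedures they
cross-check: folding by full enumeration of nested structures, duplex
hybridization by enumeration of monotone pairings, and Dollo length by
enumeration of gain placements and loss sets.  They are exercised by the
test-suite and the acceptance script, never by the pipeline itself.
"""

from __future__ import annotations

from typing import Iterator

from .io_formats import normalize_seq
from .rnafold import EnergyModel, default_model, structure_energy


def enumerate_structures(
    seq: str, model: EnergyModel | None = None
) -> Iterator[list[tuple[int, int]]]:
    """Yield every nested structure (pair list) with the model's min loop."""
    model = model or default_model()
    s = normalize_seq(seq)
    span = model.min_loop + 1

    def rec(i: int, j: int) -> Iterator[list[tuple[int, int]]]:
        if j - i < span:
            yield []
            return
        # position i unpaired
        yield from rec(i + 1, j)
        for k in range(i + span, j + 1):
            if model.pairable(s[i], s[k]):
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        yield [(i, k)] + inner + rest

    yield from rec(0, len(s) - 1)


def brute_force_mfe(
    seq: str, model: EnergyModel | None = None
) -> tuple[float, int, int]:
    """(min energy, max pair count among minima, structures enumerated)."""
    model = model or default_model()
    best_e = 0.0
    best_pairs = 0
    count = 0
    for pairs in enumerate_structures(seq, model):
        count += 1
        e = structure_energy(seq, pairs, model)
        if e < best_e - 1e-9:
            best_e, best_pairs = e, len(pairs)
        elif abs(e - best_e) <= 1e-9:
            best_pairs = max(best_pairs, len(pairs))
    return best_e, best_pairs, count


def brute_force_duplex_energy(
    mirna: str, target: str, model: EnergyModel | None = None
) -> float:
    """Minimum hybridization energy over all monotone intermolecular pairings.

    A pairing matches positions of ``mirna`` (5'->3') to positions of
    ``target`` (5'->3') antiparallel: chosen miRNA indices increase while
    target indices decrease.  Adjacent pairs (consecutive on both strands)
    stack with the folding model's energies; everything else is free.
    Intended for strands of <= ~12 nt.
    """
    model = model or default_model()
    a = normalize_seq(mirna)
    b = normalize_seq(target)
    n, m = len(a), len(b)
    allowed = [[model.pairable(a[i], b[j]) for j in range(m)] for i in range(n)]
    best = [0.0]

    def rec(i: int, j: int, energy: int, last: tuple[int, int] | None) -> None:
        # choose the next pair (i', j') with i' >= i, j' <= j
        if energy / 10.0 < best[0]:
            best[0] = energy / 10.0
        for ii in range(i, n):
            for jj in range(j, -1, -1):
                if not allowed[ii][jj]:
                    continue
                e = energy
                if last is not None and ii == last[0] + 1 and jj == last[1] - 1:
                    e += model.stack(
                        model.pair_name(a[last[0]], b[last[1]]),
                        model.pair_name(a[ii], b[jj]),
                    )
                rec(ii + 1, jj - 1, e, (ii, jj))

    rec(0, m - 1, 0, None)
    return best[0]


def brute_force_dollo_length(tree, states: dict[str, int]) -> int:
    """Minimal Dollo length of one binary character on a rooted tree.

    Enumerates every gain node and every subset of loss edges below it,
    keeping assignments whose implied leaf states match ``states``.  The
    character contributes 0 when absent from every leaf, else
    ``1 + min losses``.  ``tree`` is the nested-tuple representation used by
    :mod:`mirseed.dollo_phylo`.
    """
    from .dollo_phylo import iter_nodes, leaf_set

    leaves = sorted(leaf_set(tree))
    if not any(states[l] for l in leaves):
        return 0

    best = None
    for gain in iter_nodes(tree):
        edges = _edges_below(gain)
        for mask in range(1 << len(edges)):
            lost = {id(edges[k]) for k in range(len(edges)) if mask >> k & 1}
            implied = _implied_states(gain, lost)
            full = {l: implied.get(l, 0) for l in leaves}
            if full == {l: states[l] for l in leaves}:
                nloss = bin(mask).count("1")
                if best is None or 1 + nloss < best:
                    best = 1 + nloss
    assert best is not None, "pattern unreachable under Dollo (cannot happen)"
    return best


def _edges_below(node) -> list:
    """Edges below a node, each identified by its child subtree object."""
    out = []
    if isinstance(node, tuple):
        for child in node:
            out.append(child)
            out.extend(_edges_below(child))
    return out


def _implied_states(gain, lost_edge_ids: set[int]) -> dict[str, int]:
    states: dict[str, int] = {}

    def walk(node, present: bool) -> None:
        if isinstance(node, tuple):
            for child in node:
                walk(child, present and id(child) not in lost_edge_ids)
        else:
            states[node] = 1 if present else 0

    walk(gain, True)
    return states
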