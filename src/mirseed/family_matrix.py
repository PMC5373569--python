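"""miRNA family assignment, family x species matrices and clustering.

Family membership follows a conjunctive homology rule: a miRNA joins the
family of its best-matching seed when an ungapped full-overlap alignment
shows identity above 98% AND fewer than 2 mismatches.  On ~22 nt matures
the two conditions cannot both hold with any mismatch (1/22 is already
<96% identity), so the alignment is computed on precursors, falling back
to mature-only (still conjunctive, and flagged) when a precursor is
missing.

The member-count matrix (species x family) binarizes at count >= 1 to
yield Dollo characters; hierarchical clustering of species uses Euclidean
distance on count rows with average linkage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, dendrogram
from scipy.spatial.distance import pdist

from .known_annotation import MiRNARecord


@dataclass
class FamilySeed:
    family: str
    seq: str  # precursor when available, else mature
    kind: str = "precursor"  # "precursor" | "mature"


@dataclass
class FamilyMatrix:
    """Species x family member counts with a binary presence view."""

    counts: pd.DataFrame  # rows = species, columns = families, ints >= 0

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("member counts must be >= 0")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts >= 1).astype(int)


def _overlap_align(query: str, ref: str) -> tuple[float, int]:
    """Best ungapped full-overlap placement of the shorter sequence within
    the longer; returns (identity over the overlap, mismatches)."""
    short, long_ = (query, ref) if len(query) <= len(ref) else (ref, query)
    n, m = len(short), len(long_)
    best_mm = n + 1
    for off in range(m - n + 1):
        mm = sum(a != b for a, b in zip(short, long_[off : off + n]))
        if mm < best_mm:
            best_mm = mm
            if mm == 0:
                break
    return (n - best_mm) / n, best_mm


def assign_families(
    mirnas: list[MiRNARecord],
    family_seeds: list[FamilySeed],
    min_identity: float = 0.98,
    max_mm: int = 1,
) -> pd.DataFrame:
    """Label each miRNA with its best family seed under the conjunctive rule.

    Returns an audit table (name, family, identity, mismatches, basis);
    ``basis`` records whether the precursor or the mature carried the
    alignment.  miRNAs failing both thresholds stay unassigned.
    """
    rows = []
    for m in mirnas:
        best = None  # (mm, -identity, family, identity, basis)
        for seed in family_seeds:
            if m.precursor_seq and seed.kind == "precursor":
                basis = "precursor"
                ident, mm = _overlap_align(m.precursor_seq, seed.seq)
            else:
                basis = "mature"
                ident, mm = _overlap_align(m.mature_seq, seed.seq)
            key = (mm, -ident, seed.family)
            if best is None or key < best[0]:
                best = (key, seed.family, ident, mm, basis)
        if best is None:
            rows.append({"name": m.name, "family": None})
            continue
        _, family, ident, mm, basis = best
        assigned = ident > min_identity and mm <= max_mm
        m.family = family if assigned else None
        rows.append(
            {
                "name": m.name,
                "family": m.family,
                "identity": round(ident, 4),
                "mismatches": mm,
                "basis": basis,
            }
        )
    return pd.DataFrame(rows).set_index("name")


def build_matrix(
    members: dict[str, dict[str, int]], focal: str | None = None
) -> tuple[FamilyMatrix, pd.DataFrame]:
    """Matrix from per-species family member counts, plus the family-size
    histogram of the focal species (first row by default).

    The histogram maps family size -> number of families of that size,
    with a percent column; its total equals the focal species' family
    count.
    """
    matrix = FamilyMatrix(
        pd.DataFrame(members).T.fillna(0).astype(int).sort_index(axis=1)
    )
    focal = focal or matrix.species[0]
    histogram = family_size_histogram(matrix.counts.loc[focal])
    return matrix, histogram


def family_size_histogram(row: pd.Series) -> pd.DataFrame:
    """Family-size histogram (size, n_families, percent) for one species."""
    sizes = Counter(int(v) for v in row.values if v >= 1)
    total = sum(sizes.values())
    out = pd.DataFrame(
        [
            {
                "size": size,
                "n_families": n,
                "percent": 100.0 * n / total if total else 0.0,
            }
            for size, n in sorted(sizes.items())
        ]
    )
    return out.set_index("size") if len(out) else out


def cluster_species(matrix: FamilyMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of species on Euclidean count rows.

    Returns (scipy linkage matrix, deterministic leaf order).  Column
    permutations leave the distances, and hence the dendrogram, unchanged.
    """
    if len(matrix.species) < 2:
        raise ValueError("need at least 2 species to cluster")
    dists = pdist(matrix.counts.to_numpy(dtype=float), metric="euclidean")
    z = average(dists)
    order = dendrogram(z, no_plot=True)["leaves"]
    return z, [matrix.species[i] for i in order]


def lineage_specific_families(matrix: FamilyMatrix, group: list[str]) -> list[str]:
    """Families present in every ``group`` species and absent elsewhere."""
    if not group:
        raise ValueError("empty species group")
    missing = set(group) - set(matrix.species)
    if missing:
        raise ValueError(f"species not in matrix: {sorted(missing)}")
    binary = matrix.binary
    others = [s for s in matrix.species if s not in group]
    keep = []
    for fam in matrix.families:
        col = binary[fam]
        if all(col[s] == 1 for s in group) and all(col[s] == 0 for s in others):
            keep.append(fam)
    return keep
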