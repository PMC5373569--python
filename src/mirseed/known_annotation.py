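"""Conserved-miRNA calling against multi-species mature/precursor catalogs.

A length-filtered tag is *conserved* when it aligns ungapped and in full
within a catalog mature or precursor with at most ``max_mm`` (default 3)
substitutions.  Matching is sense-only (small-RNA libraries are stranded)
and exact over the mismatch budget: every window of every reference is
scanned, so raising the budget is guaranteed monotone.  Ties among equally
good hits are broken by fewest mismatches, then mature over precursor,
then lexicographically smallest reference id; tags sharing a best mature
merge into one record whose counts sum the tags'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import ReferenceCatalog
from .preprocess import UniqueTag
from ._match import UngappedIndex


@dataclass
class AlignmentHit:
    tag_seq: str
    reference_id: str
    species: str
    mismatches: int
    offset: int  # start of the tag within the reference, 0-based
    reference_kind: str  # "mature" | "precursor"


@dataclass
class MiRNARecord:
    """A called miRNA, conserved (catalog-matched) or novel (hairpin-based)."""

    name: str
    mature_seq: str
    provenance: str  # "conserved" | "novel"
    counts: list[int] = field(default_factory=list)
    precursor_seq: str | None = None
    dotbracket: str | None = None
    family: str | None = None
    source_species: str | None = None
    mismatches: int | None = None
    locus: tuple[str, int, int, str] | None = None

    @property
    def total_count(self) -> int:
        return sum(self.counts)


def match_known(
    tags: list[UniqueTag],
    catalogs: list[ReferenceCatalog],
    max_mm: int = 3,
) -> tuple[list[MiRNARecord], pd.DataFrame]:
    """Call conserved miRNAs; returns (records, per-tag hit table)."""
    if not catalogs or not any(c.matures or c.precursors for c in catalogs):
        raise ValueError("empty reference catalog")

    mat_seqs, mat_ids, mat_species = [], [], {}
    pre_list_seqs, pre_list_ids = [], []
    for cat in catalogs:
        for m in cat.matures:
            mat_seqs.append(m.seq)
            mat_ids.append(m.id)
            mat_species[m.id] = cat.species
        for p in cat.precursors:
            pre_list_seqs.append(p.seq)
            pre_list_ids.append(p.id)
            mat_species[p.id] = cat.species
    mature_index = UngappedIndex(mat_seqs, mat_ids) if mat_ids else None
    precursor_index = (
        UngappedIndex(pre_list_seqs, pre_list_ids) if pre_list_ids else None
    )

    hit_rows = []
    by_reference: dict[str, list[tuple[UniqueTag, AlignmentHit]]] = {}
    for tag in tags:
        candidates: list[tuple[tuple, AlignmentHit]] = []
        for kind, index, kind_rank in (
            ("mature", mature_index, 0),
            ("precursor", precursor_index, 1),
        ):
            if index is None:
                continue
            for ref_k, offset, mm in index.hits(tag.seq, max_mm):
                rid = index.ids[ref_k]
                hit = AlignmentHit(
                    tag_seq=tag.seq,
                    reference_id=rid,
                    species=mat_species[rid],
                    mismatches=mm,
                    offset=offset,
                    reference_kind=kind,
                )
                candidates.append(((mm, kind_rank, rid), hit))
        if not candidates:
            continue
        candidates.sort(key=lambda c: c[0])
        best = candidates[0][1]
        by_reference.setdefault(best.reference_id, []).append((tag, best))
        hit_rows.append(
            {
                "tag": tag.seq,
                "reference": best.reference_id,
                "species": best.species,
                "kind": best.reference_kind,
                "mismatches": best.mismatches,
                "offset": best.offset,
                "total_count": tag.total_count,
            }
        )
        tag.annotation_class = "miRNA_known"

    records = []
    for rid in sorted(by_reference):
        group = by_reference[rid]
        n_lib = len(group[0][0].counts)
        counts = [0] * n_lib
        for tag, _ in group:
            for k in range(n_lib):
                counts[k] += tag.counts[k]
        # representative mature sequence: the most abundant exact tag
        rep = min(group, key=lambda th: (th[1].mismatches, -th[0].total_count))
        records.append(
            MiRNARecord(
                name=rid,
                mature_seq=rep[0].seq,
                provenance="conserved",
                counts=counts,
                source_species=group[0][1].species,
                mismatches=min(h.mismatches for _, h in group),
            )
        )
    hit_table = pd.DataFrame(hit_rows)
    return records, hit_table
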