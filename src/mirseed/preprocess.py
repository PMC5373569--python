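"""Read cleaning, tag collapsing, length windowing and class annotation.

The cleaning stage trims the 3' sequencing adapter and discards
contaminating reads (adapter-only, oversize/no-insert, poly-A,
low-quality, ambiguous); surviving inserts are collapsed to unique tags
carrying per-library counts, windowed to 15-30 nt, and classified against
user-supplied labeled reference sets (the package's offline stand-in for
Nr/Rfam-style annotation) plus the known-miRNA catalog.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .io_formats import SequenceRecord, ReferenceCatalog
from ._match import UngappedIndex

#: class priority for annotation (a tag matching several classes gets the first)
CLASS_PRIORITY = ["miRNA_known", "rRNA", "tRNA", "snRNA", "snoRNA", "other"]


@dataclass
class UniqueTag:
    """A collapsed insert sequence with per-library counts."""

    seq: str
    counts: list[int]
    annotation_class: str = "unannotated"

    @property
    def total_count(self) -> int:
        return sum(self.counts)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LibraryStats:
    raw_reads: int = 0
    clean_reads: int = 0
    discards: Counter = field(default_factory=Counter)
    length_histogram_total: Counter = field(default_factory=Counter)
    length_histogram_unique: Counter = field(default_factory=Counter)

    @property
    def clean_fraction(self) -> float:
        return self.clean_reads / self.raw_reads if self.raw_reads else 0.0


def _find_adapter(seq: str, adapter: str, min_overlap: int = 5) -> int | None:
    """Start of the 3' adapter: longest suffix of the read matching a prefix
    of the adapter with <= 1 mismatch; None when no such overlap >= min_overlap."""
    n = len(seq)
    for p in range(n - min_overlap + 1):  # earliest start = longest overlap
        overlap = min(n - p, len(adapter))
        mm = 0
        for a, b in zip(seq[p : p + overlap], adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > 1:
                    break
        else:
            return p
    return None


def clean_reads(
    reads: Iterable[SequenceRecord],
    adapter: str,
    min_qual: float = 20.0,
    stats: LibraryStats | None = None,
    cycle_count: int | None = None,
) -> Iterator[SequenceRecord]:
    """Trim the 3' adapter and drop contaminating reads.

    Discard reasons (counted in ``stats.discards``): ``no_adapter`` (full
    cycle count without an adapter hit: no-insert or oversize insertion),
    ``no_insert`` (adapter at position 0), ``poly_a`` (insert >= 80% A),
    ``low_quality`` (mean Phred below ``min_qual``) and ``ambiguous``
    (insert contains N).  When ``cycle_count`` is given, adapter-less reads
    shorter than it are treated as already trimmed and kept.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    stats = stats if stats is not None else LibraryStats()
    for read in reads:
        stats.raw_reads += 1
        if read.qual is not None and sum(read.qual) / len(read.qual) < min_qual:
            stats.discards["low_quality"] += 1
            continue
        p = _find_adapter(read.seq, adapter)
        if p is None:
            if cycle_count is not None and len(read.seq) < cycle_count:
                p = len(read.seq)  # already trimmed upstream
            else:
                stats.discards["no_adapter"] += 1
                continue
        if p == 0:
            stats.discards["no_insert"] += 1
            continue
        insert = read.seq[:p]
        if "N" in insert:
            stats.discards["ambiguous"] += 1
            continue
        if insert.count("A") >= 0.8 * len(insert):
            stats.discards["poly_a"] += 1
            continue
        stats.clean_reads += 1
        stats.length_histogram_total[len(insert)] += 1
        qual = read.qual[:p] if read.qual is not None else None
        yield SequenceRecord(id=read.id, seq=insert, qual=qual)


def collapse(libraries: Sequence[Iterable[SequenceRecord]]) -> list[UniqueTag]:
    """One tag per distinct insert with per-library counts.

    The sum of tag totals equals the number of input reads (conservation).
    """
    n_lib = len(libraries)
    table: dict[str, list[int]] = {}
    for lib_idx, lib in enumerate(libraries):
        for read in lib:
            counts = table.setdefault(read.seq, [0] * n_lib)
            counts[lib_idx] += 1
    tags = [UniqueTag(seq=s, counts=c) for s, c in table.items()]
    tags.sort(key=lambda t: (-t.total_count, t.seq))
    return tags


def length_filter(tags: Iterable[UniqueTag], lo: int = 15, hi: int = 30) -> list[UniqueTag]:
    """Keep tags with lo <= length <= hi (inclusive bounds)."""
    return [t for t in tags if lo <= len(t.seq) <= hi]


def classify_tags(
    tags: Sequence[UniqueTag],
    decoys: dict[str, list[SequenceRecord]],
    known: ReferenceCatalog | None = None,
    max_mm: int = 1,
) -> pd.DataFrame:
    """Annotate each tag by small-RNA class; returns the class-frequency table.

    A tag matches a class when it aligns ungapped, fully within some member
    of that class's reference set, with at most ``max_mm`` substitutions.
    Classes are tried in priority order miRNA > rRNA > tRNA > snRNA >
    snoRNA > other; unmatched tags stay ``unannotated``.  Frequencies are
    reported both count-weighted ("total") and tag-weighted ("unique").
    """
    indexes: dict[str, UngappedIndex] = {}
    if known is not None and (known.matures or known.precursors):
        seqs = [m.seq for m in known.matures] + [p.seq for p in known.precursors]
        ids = [m.id for m in known.matures] + [p.id for p in known.precursors]
        indexes["miRNA_known"] = UngappedIndex(seqs, ids)
    for cls, records in decoys.items():
        if records:
            indexes[cls] = UngappedIndex([r.seq for r in records], [r.id for r in records])

    for tag in tags:
        tag.annotation_class = "unannotated"
        for cls in CLASS_PRIORITY:
            idx = indexes.get(cls)
            if idx is not None and idx.has_hit(tag.seq, max_mm):
                tag.annotation_class = cls
                break
    return class_frequencies(tags)


def class_frequencies(tags: Sequence[UniqueTag]) -> pd.DataFrame:
    """Class frequency table with 'total' (count-weighted) and 'unique'
    (tag-weighted) columns, each summing to 1."""
    classes = CLASS_PRIORITY + ["miRNA_novel", "unannotated"]
    total = Counter()
    unique = Counter()
    for t in tags:
        total[t.annotation_class] += t.total_count
        unique[t.annotation_class] += 1
    n_total = sum(total.values()) or 1
    n_unique = sum(unique.values()) or 1
    rows = [
        {
            "class": cls,
            "total_count": total.get(cls, 0),
            "unique_count": unique.get(cls, 0),
            "total_frequency": total.get(cls, 0) / n_total,
            "unique_frequency": unique.get(cls, 0) / n_unique,
        }
        for cls in classes
    ]
    return pd.DataFrame(rows).set_index("class")


def length_distribution(tags: Sequence[UniqueTag]) -> pd.DataFrame:
    """Insert-length histogram, total- and unique-weighted."""
    total = Counter()
    unique = Counter()
    for t in tags:
        total[len(t.seq)] += t.total_count
        unique[len(t.seq)] += 1
    lengths = sorted(set(total) | set(unique))
    return pd.DataFrame(
        {
            "length": lengths,
            "total_count": [total[l] for l in lengths],
            "unique_count": [unique[l] for l in lengths],
        }
    ).set_index("length")
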