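"""Readers and writers for the external formats the pipeline touches.

All sequences are normalized to an internal DNA alphabet (``ACGTN``; ``U``
becomes ``T`` on input).  RNA letters reappear only in user-facing miRNA
reports, via :func:`to_rna`.  Quality strings are Sanger/Phred+33.  Gzipped
files are accepted transparently by extension sniffing.

Genome coordinates produced anywhere in the package are 0-based, half-open,
with an explicit ``+``/``-`` strand; :func:`check_interval` asserts that
convention in one place.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA ``U`` to internal DNA ``T``; validate alphabet."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise FormatError("empty sequence")
    bad = set(s) - _DNA_ALPHABET
    if bad:
        raise FormatError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence as RNA for reports."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_interval(start: int, end: int, strand: str, length: int | None = None) -> None:
    """Assert the package-wide 0-based half-open interval convention."""
    if not (0 <= start < end):
        raise ValueError(f"invalid 0-based half-open interval [{start}, {end})")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if length is not None and end > length:
        raise ValueError(f"interval end {end} exceeds sequence length {length}")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream 4-line FASTQ records.

    Raises :class:`FormatError` naming the (1-based) record index on a
    malformed record, e.g. a seq/quality length mismatch.
    """
    index = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                index += 1
                yield SequenceRecord(
                    id=rec.id,
                    seq=str(rec.seq),
                    qual=list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise FormatError(f"malformed FASTQ record {index + 1}: {exc}") from exc


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; duplicate ids are a hard error (listed in the message)."""
    records = []
    seen: dict[str, int] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
            seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FormatError(f"duplicate FASTA ids: {dups}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (_BioRecord(Seq(r.seq), id=r.id, description="") for r in records),
            fh,
            "fasta",
        )


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else [40] * len(r.seq)
            rec = _BioRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = qual
            SeqIO.write(rec, fh, "fastq")


@dataclass
class ReferenceCatalog:
    """miRBase-style catalog: matures, precursors and their links.

    ``species`` is a three-letter code (``dre``, ``hsa``...).  Every mature
    must link to at least one precursor; a mature that is not a subsequence
    of its precursor (allowing 1 mismatch) triggers a warning on load.
    """

    species: str
    matures: list[SequenceRecord] = field(default_factory=list)
    precursors: list[SequenceRecord] = field(default_factory=list)
    links: dict[str, list[str]] = field(default_factory=dict)  # mature id -> precursor ids

    def __post_init__(self) -> None:
        prec = {p.id: p.seq for p in self.precursors}
        for m in self.matures:
            pids = self.links.get(m.id, [])
            if not pids:
                raise FormatError(f"mature {m.id!r} has no linked precursor")
            for pid in pids:
                if pid not in prec:
                    raise FormatError(f"mature {m.id!r} links unknown precursor {pid!r}")
                if not _subseq_within(m.seq, prec[pid], max_mm=1):
                    warnings.warn(
                        f"mature {m.id} not found within precursor {pid} "
                        f"(more than 1 mismatch)",
                        stacklevel=2,
                    )

    @property
    def mature_seqs(self) -> dict[str, str]:
        return {m.id: m.seq for m in self.matures}

    @property
    def precursor_seqs(self) -> dict[str, str]:
        return {p.id: p.seq for p in self.precursors}


def _subseq_within(query: str, ref: str, max_mm: int = 0) -> bool:
    n, m = len(query), len(ref)
    if n > m:
        return False
    for off in range(m - n + 1):
        mm = 0
        for a, b in zip(query, ref[off : off + n]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


def catalog_from_fastas(
    species: str,
    mature_path: str | Path,
    precursor_path: str | Path,
) -> ReferenceCatalog:
    """Build a catalog from mature/precursor FASTAs.

    Links are inferred by shared name stem (miRBase convention:
    ``dre-miR-10a-5p`` matures to ``dre-mir-10a``) falling back to substring
    containment when the stem is ambiguous.
    """
    matures = read_fasta(mature_path)
    precursors = read_fasta(precursor_path)
    prec_by_lower = {p.id.lower(): p.id for p in precursors}
    links: dict[str, list[str]] = {}
    for m in matures:
        stem = m.id.lower().replace("mir-", "mir-")
        for suffix in ("-5p", "-3p", ""):
            if suffix and stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        candidates = [prec_by_lower[k] for k in prec_by_lower if k == stem]
        if not candidates:
            candidates = [
                p.id for p in precursors if _subseq_within(m.seq, p.seq, max_mm=1)
            ]
        if candidates:
            links[m.id] = sorted(candidates)
    return ReferenceCatalog(species=species, matures=matures, precursors=precursors, links=links)


def write_newick(tree, path: str | Path) -> None:
    """Write a :class:`~mirseed.dollo_phylo.PhyloTree` as newick.

    Bootstrap supports, when present, become internal-node labels.  Requires
    >=2 leaves with unique labels.
    """
    # local import: dollo_phylo depends on this module for nothing, but keep
    # the layering acyclic at import time
    from . import dollo_phylo

    if not isinstance(tree, dollo_phylo.PhyloTree):
        tree = dollo_phylo.PhyloTree(tree)
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise FormatError(f"duplicate leaf labels: {sorted(leaves)}")
    with _open_text(path, "wt") as fh:
        fh.write(tree.newick() + "\n")


def read_gene2term(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (gene_id, term) TSV into gene -> terms."""
    table: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            table.setdefault(gene, []).append(term)
    return table


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals as (contig, start, end, strand); strand defaults '+'."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) > 5 else "+"
            check_interval(start, end, strand)
            out.append((contig, start, end, strand))
    return out
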