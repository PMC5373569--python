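"""Novel-miRNA discovery from genome-mapped unannotated tags.

Unannotated tags are mapped to the reference genome (both strands,
ungapped), candidate precursor windows are extracted around each locus and
folded, and six consensus criteria are applied:

1. the locus must not overlap a sense-strand exon (vacuous without an
   annotation; intergenic loci are admitted and flagged);
2. the mature must sit on one arm of the hairpin;
3. the mature/star duplex must show an exact 2-nt 3' overhang on the
   mature side;
4. no large internal loop or bulge (default > 8 nt fails);
5. precursor MFE below -18 kcal/mol (calibrated to the package's folding
   model; configurable);
6. supporting read count above 5 (i.e. >= 6).

Passing candidates that overlap on a locus merge, keeping the lowest-MFE
precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import SequenceRecord, revcomp, check_interval
from .preprocess import UniqueTag
from .known_annotation import MiRNARecord
from .rnafold import EnergyModel, HairpinStructure, fold, hairpin_metrics


@dataclass
class DiscoveryParams:
    max_mm: int = 0  # genome mapping mismatches
    max_genomic_hits: int = 10  # repetitive-tag cap
    flank: int = 100  # window flank beyond the tag
    mfe_max: float = -18.0  # kcal/mol, criterion 5
    min_reads: int = 5  # criterion 6: count must exceed this
    max_bulge: int = 8  # criterion 4
    overhang_tolerance: int = 0  # +/- around the 2-nt overhang, criterion 3


@dataclass
class PrecursorCandidate:
    contig: str
    start: int  # precursor window, 0-based half-open genomic
    end: int
    strand: str
    precursor_seq: str
    mature_range: tuple[int, int]  # within the (strand-oriented) window
    tag: UniqueTag
    structure: HairpinStructure
    criteria_flags: dict[str, bool] = field(default_factory=dict)
    flag_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.criteria_flags.values())


def map_tags(
    tags: list[UniqueTag],
    genome: list[SequenceRecord],
    max_mm: int = 0,
    max_genomic_hits: int = 10,
) -> list[tuple[UniqueTag, tuple[str, int, int, str]]]:
    """Ungapped genomic hits of each tag on both strands.

    Returns (tag, (contig, start, end, strand)) with forward-genome
    coordinates; tags exceeding ``max_genomic_hits`` loci are discarded as
    repetitive.
    """
    contigs = [(rec.id, rec.seq) for rec in genome]
    out = []
    for tag in tags:
        hits = []
        for contig, seq in contigs:
            n = len(seq)
            for query, strand in ((tag.seq, "+"), (revcomp(tag.seq), "-")):
                if max_mm == 0:
                    start = seq.find(query)
                    while start != -1:
                        hits.append((contig, start, start + len(query), strand))
                        start = seq.find(query, start + 1)
                else:
                    hits.extend(
                        (contig, s, s + len(query), strand)
                        for s in _approx_find(seq, query, max_mm)
                    )
        if 0 < len(hits) <= max_genomic_hits:
            for h in hits:
                check_interval(h[1], h[2], h[3])
                out.append((tag, h))
    return out


def _approx_find(seq: str, query: str, max_mm: int) -> list[int]:
    import numpy as np

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    if len(q) > len(arr):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, len(q))
    mm = (windows != q).sum(axis=1)
    return np.nonzero(mm <= max_mm)[0].tolist()


#: flank lengths scanned when excising a candidate stem-loop around a tag
FLANK_STEPS = (30, 45, 60, 80, 100)


def extract_candidates(
    hits: list[tuple[UniqueTag, tuple[str, int, int, str]]],
    genome: list[SequenceRecord],
    flank: int = 100,
    model: EnergyModel | None = None,
    params: DiscoveryParams | None = None,
) -> list[PrecursorCandidate]:
    """Excise and fold candidate precursor windows around each genomic hit.

    Windows place the tag at the 5' side with a 3' flank or at the 3' side
    with a 5' flank, scanning several flank lengths up to ``flank`` per
    side (folding an over-long window lets stray flank complementarity
    enclose the hairpin, so the stem-loop is searched at multiple
    excisions, as hairpin-prediction tools do internally).  Windows are
    truncated at contig boundaries; minus-strand windows are
    reverse-complemented before folding.  Per hit, the window kept is the
    lowest-MFE one satisfying the hairpin geometry criteria, else the
    lowest-MFE window overall.
    """
    p = params or DiscoveryParams()
    by_id = {rec.id: rec.seq for rec in genome}
    steps = sorted({min(flank, f) for f in (*FLANK_STEPS, flank)})
    candidates = []
    for tag, (contig, start, end, strand) in hits:
        seq = by_id[contig]
        n = len(seq)
        scored = []
        for f in steps:
            for wstart, wend in (
                (start, min(n, end + f)),  # 3' flank: tag at 5' side
                (max(0, start - f), end),  # 5' flank: tag at 3' side
            ):
                wseq = seq[wstart:wend]
                tag_lo, tag_hi = start - wstart, end - wstart
                if strand == "-":
                    wseq = revcomp(wseq)
                    tag_lo, tag_hi = len(wseq) - tag_hi, len(wseq) - tag_lo
                structure = fold(wseq, model)
                met = hairpin_metrics(structure, (tag_lo, tag_hi))
                geometry_ok = (
                    met.arm in ("5p", "3p")
                    and met.overhang_mature3 is not None
                    and abs(met.overhang_mature3 - 2) <= p.overhang_tolerance
                    and met.max_bulge <= p.max_bulge
                    and structure.mfe_kcal_mol < p.mfe_max
                )
                scored.append(
                    (
                        (not geometry_ok, structure.mfe_kcal_mol),
                        structure,
                        wstart,
                        wend,
                        (tag_lo, tag_hi),
                    )
                )
        scored.sort(key=lambda s: s[0])
        _, structure, wstart, wend, mrange = scored[0]
        candidates.append(
            PrecursorCandidate(
                contig=contig,
                start=wstart,
                end=wend,
                strand=strand,
                precursor_seq=structure.seq,
                mature_range=mrange,
                tag=tag,
                structure=structure,
            )
        )
    return candidates


def apply_criteria(
    cand: PrecursorCandidate,
    annotations: list[tuple[str, int, int, str]] | None = None,
    params: DiscoveryParams | None = None,
) -> bool:
    """Evaluate the six consensus criteria; flags record each pass/fail."""
    p = params or DiscoveryParams()
    flags = cand.criteria_flags
    reasons = cand.flag_reasons

    overlap_sense_exon = False
    if annotations:
        for contig, a_start, a_end, a_strand in annotations:
            if (
                contig == cand.contig
                and a_strand == cand.strand
                and cand.start < a_end
                and a_start < cand.end
            ):
                overlap_sense_exon = True
                break
    flags["criterion-1"] = not overlap_sense_exon
    if overlap_sense_exon:
        reasons["criterion-1"] = "locus overlaps a sense-strand exon"

    met = hairpin_metrics(cand.structure, cand.mature_range)
    flags["criterion-2"] = met.arm in ("5p", "3p")
    if not flags["criterion-2"]:
        reasons["criterion-2"] = "mature spans the hairpin apex or is unpaired"

    oh = met.overhang_mature3
    flags["criterion-3"] = oh is not None and abs(oh - 2) <= p.overhang_tolerance
    if not flags["criterion-3"]:
        reasons["criterion-3"] = f"mature 3' overhang {oh} != 2"

    flags["criterion-4"] = met.max_bulge <= p.max_bulge
    if not flags["criterion-4"]:
        reasons["criterion-4"] = f"bulge/internal loop of {met.max_bulge} nt"

    flags["criterion-5"] = cand.structure.mfe_kcal_mol < p.mfe_max
    if not flags["criterion-5"]:
        reasons["criterion-5"] = (
            f"MFE {cand.structure.mfe_kcal_mol:.1f} not below {p.mfe_max}"
        )

    flags["criterion-6"] = cand.tag.total_count > p.min_reads
    if not flags["criterion-6"]:
        reasons["criterion-6"] = (
            f"read support {cand.tag.total_count} <= {p.min_reads}"
        )
    return cand.passed


def call_novel(
    tags: list[UniqueTag],
    genome: list[SequenceRecord],
    annotations: list[tuple[str, int, int, str]] | None = None,
    params: DiscoveryParams | None = None,
    model: EnergyModel | None = None,
) -> tuple[list[MiRNARecord], pd.DataFrame]:
    """Full novel-discovery pass over unannotated tags.

    Returns novel MiRNARecords (overlapping passing candidates merged,
    lowest MFE kept) and a per-candidate criteria audit table.
    """
    p = params or DiscoveryParams()
    # miRNA_novel is admitted so repeated passes are idempotent
    unannotated = [
        t for t in tags if t.annotation_class in ("unannotated", "miRNA_novel")
    ]
    hits = map_tags(unannotated, genome, max_mm=p.max_mm, max_genomic_hits=p.max_genomic_hits)
    candidates = extract_candidates(hits, genome, flank=p.flank, model=model, params=p)
    audit_rows = []
    passing = []
    for cand in candidates:
        apply_criteria(cand, annotations, p)
        row = {
            "contig": cand.contig,
            "start": cand.start,
            "end": cand.end,
            "strand": cand.strand,
            "tag": cand.tag.seq,
            "reads": cand.tag.total_count,
            "mfe": cand.structure.mfe_kcal_mol,
            "passed": cand.passed,
        }
        row.update(cand.criteria_flags)
        audit_rows.append(row)
        if cand.passed:
            passing.append(cand)

    # merge candidates overlapping on the same contig+strand
    passing.sort(key=lambda c: (c.contig, c.strand, c.start))
    merged: list[list[PrecursorCandidate]] = []
    for cand in passing:
        if (
            merged
            and merged[-1][0].contig == cand.contig
            and merged[-1][0].strand == cand.strand
            and cand.start < max(c.end for c in merged[-1])
        ):
            merged[-1].append(cand)
        else:
            merged.append([cand])

    records = []
    for k, group in enumerate(merged):
        best = min(group, key=lambda c: c.structure.mfe_kcal_mol)
        n_lib = len(best.tag.counts)
        counts = [0] * n_lib
        seen = set()
        for c in group:
            if c.tag.seq in seen:
                continue
            seen.add(c.tag.seq)
            for i in range(n_lib):
                counts[i] += c.tag.counts[i]
            c.tag.annotation_class = "miRNA_novel"
        records.append(
            MiRNARecord(
                name=f"novel-mir-{k + 1}",
                mature_seq=best.tag.seq,
                provenance="novel",
                counts=counts,
                precursor_seq=best.precursor_seq,
                dotbracket=best.structure.dotbracket,
                locus=(best.contig, best.start, best.end, best.strand),
            )
        )
    audit = pd.DataFrame(audit_rows)
    return records, audit
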