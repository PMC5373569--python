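import numpy as np
import pytest

from mirseed.io_formats import SequenceRecord, revcomp
from mirseed.novel_discovery import (
    DiscoveryParams,
    apply_criteria,
    call_novel,
    extract_candidates,
    map_tags,
)
from mirseed.preprocess import UniqueTag
from mirseed.rnafold import fold


def _tag(seq, count=10):
    return UniqueTag(seq=seq, counts=[count])


def test_planted_tag_maps_to_its_locus(sim_run):
    truth = sim_run["truth"]
    genome = sim_run["genome"]
    h = truth.hairpins[0]
    if h.strand == "+":
        expected = (h.contig, h.start, h.start + len(h.mature_seq), "+")
    else:
        expected = (h.contig, h.end - len(h.mature_seq), h.end, "-")
    hits = map_tags([_tag(h.mature_seq)], genome)
    assert [loc for _, loc in hits] == [expected]


def test_absent_tag_has_no_hits():
    genome = [SequenceRecord(id="c", seq="ACGT" * 200)]
    assert map_tags([_tag("TTGGCCAATTGGCCAATTGGCC")], genome) == []


def test_duplicated_plant_reports_both_hits():
    insert = "TACAGTACTGTGATAACTGAAG"
    seq = "ACGTTTGC" * 10 + insert + "CCCCGGGTTTAA" * 5 + insert + "ACGTTTGC" * 10
    hits = map_tags([_tag(insert)], [SequenceRecord(id="c", seq=seq)])
    assert len(hits) == 2


def test_reverse_strand_hits_found():
    insert = "TACAGTACTGTGATAACTGAAG"
    seq = "AGCTTCGA" * 10 + revcomp(insert) + "AGCTTCGA" * 10
    hits = map_tags([_tag(insert)], [SequenceRecord(id="c", seq=seq)])
    assert [loc[3] for _, loc in hits] == ["-"]


def test_repetitive_tags_discarded():
    insert = "TACAGTACTGTGATAACTGAAG"
    seq = ("GGGCCCTTTAAA" + insert) * 12
    hits = map_tags([_tag(insert)], [SequenceRecord(id="c", seq=seq)], max_genomic_hits=10)
    assert hits == []


def test_window_truncated_at_contig_start():
    """A hit at position 0 must not raise; the 5' flank is truncated."""
    insert = "TACAGTACTGTGATAACTGAAG"
    genome = [SequenceRecord(id="c", seq=insert + "ACGTTGCA" * 20)]
    hits = map_tags([_tag(insert)], genome)
    cands = extract_candidates(hits, genome)
    assert len(cands) == 1
    assert cands[0].start >= 0


def test_planted_window_contains_full_precursor(sim_run):
    truth = sim_run["truth"]
    genome = sim_run["genome"]
    h = truth.hairpins[0]
    hits = map_tags([_tag(h.mature_seq)], genome)
    cands = extract_candidates(hits, genome)
    assert len(cands) == 1
    assert h.precursor_seq in cands[0].precursor_seq


def test_criteria_flags_name_each_failure(sim_run):
    truth = sim_run["truth"]
    genome = sim_run["genome"]
    h = truth.hairpins[0]
    hits = map_tags([_tag(h.mature_seq, count=10)], genome)
    (cand,) = extract_candidates(hits, genome)

    assert apply_criteria(cand) is True
    assert all(cand.criteria_flags.values())

    # criterion 5: borderline MFE of -17.5 is not below -18
    cand.criteria_flags.clear()
    original = cand.structure.mfe_kcal_mol
    cand.structure.mfe_kcal_mol = -17.5
    apply_criteria(cand)
    failed = [k for k, ok in cand.criteria_flags.items() if not ok]
    assert failed == ["criterion-5"]
    cand.structure.mfe_kcal_mol = original

    # criterion 6: support of 5 fails ("more than 5"), 6 passes
    cand.criteria_flags.clear()
    cand.tag.counts = [5]
    apply_criteria(cand)
    assert [k for k, ok in cand.criteria_flags.items() if not ok] == ["criterion-6"]
    cand.criteria_flags.clear()
    cand.tag.counts = [6]
    apply_criteria(cand)
    assert all(cand.criteria_flags.values())

    # criterion 2: a mature straddling the apex loop
    from mirseed.rnafold import hairpin_metrics

    lo, hi = hairpin_metrics(cand.structure, cand.mature_range).loop_span
    cand.criteria_flags.clear()
    cand.mature_range = (max(0, lo - 5), min(len(cand.precursor_seq), hi + 5))
    apply_criteria(cand)
    failed = [k for k, ok in cand.criteria_flags.items() if not ok]
    assert "criterion-2" in failed


def test_sense_exon_overlap_fails_criterion_one(sim_run):
    truth = sim_run["truth"]
    genome = sim_run["genome"]
    h = truth.hairpins[0]
    hits = map_tags([_tag(h.mature_seq)], genome)
    (cand,) = extract_candidates(hits, genome)
    exon = [(h.contig, h.start - 10, h.end + 10, h.strand)]
    apply_criteria(cand, annotations=exon)
    assert cand.criteria_flags["criterion-1"] is False
    antisense = [(h.contig, h.start - 10, h.end + 10, "-" if h.strand == "+" else "+")]
    cand.criteria_flags.clear()
    apply_criteria(cand, annotations=antisense)
    assert cand.criteria_flags["criterion-1"] is True


def test_default_run_recovers_plants_without_false_calls(sim_run):
    novel, audit = call_novel(sim_run["tags"], sim_run["genome"])
    loci = [(h.start, h.end, h.strand) for h in sim_run["truth"].hairpins]
    inside = sum(
        any(s < pe and ps < e and st == pst for ps, pe, pst in loci)
        for r in novel
        for _, s, e, st in [r.locus]
    )
    assert inside >= 0.9 * len(loci)
    assert len(novel) - inside == 0
    for r in novel:
        assert r.provenance == "novel" and r.precursor_seq and r.dotbracket


def test_shuffled_genome_negative_control(sim_run):
    rng = np.random.default_rng(2)
    letters = list(sim_run["genome"][0].seq)
    rng.shuffle(letters)
    shuffled = [SequenceRecord(id="chr1", seq="".join(letters))]
    novel, _ = call_novel(sim_run["tags"], shuffled)
    assert novel == []


def test_tightening_thresholds_shrinks_call_set(sim_run):
    base, _ = call_novel(sim_run["tags"], sim_run["genome"])
    strict_params = DiscoveryParams(mfe_max=-25.0, min_reads=50)
    strict, _ = call_novel(sim_run["tags"], sim_run["genome"], params=strict_params)
    base_loci = {r.locus for r in base}
    strict_loci = {r.locus for r in strict}
    assert len(strict) <= len(base)
    assert all(any(s[0] == b[0] and s[3] == b[3] and s[1] < b[2] and b[1] < s[2]
                   for b in base_loci) for s in strict_loci)


def test_two_arm_tags_merge_to_one_record(sim_run):
    truth = sim_run["truth"]
    genome = sim_run["genome"]
    h = truth.hairpins[0]
    star_tag = h.star_seq[:-2]  # the star without its terminal overhang
    tags = [_tag(h.mature_seq, count=20), _tag(star_tag, count=20)]
    novel, _ = call_novel(tags, genome)
    loci = [r.locus for r in novel]
    overlapping = [
        (a, b) for a in loci for b in loci
        if a is not b and a[0] == b[0] and a[3] == b[3] and a[1] < b[2] and b[1] < a[2]
    ]
    assert not overlapping, "overlapping candidates should have merged"
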