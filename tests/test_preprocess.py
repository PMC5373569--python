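import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirseed.io_formats import SequenceRecord
from mirseed.preprocess import (
    LibraryStats,
    UniqueTag,
    class_frequencies,
    classify_tags,
    clean_reads,
    collapse,
    length_filter,
)
from mirseed.synthetic_data import (
    SimulationConfig,
    load_decoys,
    make_genome,
    make_known_catalog,
    simulate_libraries,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _read(seq, qual=40):
    return SequenceRecord(id="r", seq=seq, qual=[qual] * len(seq))


def _clean(reads, **kw):
    stats = LibraryStats()
    kept = list(clean_reads(reads, ADAPTER, stats=stats, **kw))
    return kept, stats


def test_adapter_trimmed_from_insert():
    insert = "ACGTACGTACGTACGTACGTAC"
    kept, stats = _clean([_read(insert + ADAPTER)])
    assert [r.seq for r in kept] == [insert]
    assert stats.clean_reads == 1 and stats.raw_reads == 1


def test_adapter_found_with_one_mismatch():
    insert = "ACGTACGTACGTACGTACGTAC"
    mutated = "A" + ADAPTER[1:]
    kept, _ = _clean([_read(insert + mutated)])
    assert [r.seq for r in kept] == [insert]


def test_discard_reasons_are_counted():
    reads = [
        _read(ADAPTER + "ACGTACGTAC"),          # adapter at 0: no insert
        _read("A" * 20 + ADAPTER),              # poly-A
        _read("ACGTACGTACGTACGTACGTAC" + ADAPTER, qual=5),  # low quality
        _read("ACGNACGTACGTACGTACGTAC" + ADAPTER),  # ambiguous
        _read("C" * 40),                        # no adapter: oversize/no insert
    ]
    kept, stats = _clean(reads)
    assert kept == []
    assert stats.discards == {
        "no_insert": 1,
        "poly_a": 1,
        "low_quality": 1,
        "ambiguous": 1,
        "no_adapter": 1,
    }
    assert stats.raw_reads == stats.clean_reads + sum(stats.discards.values())


def test_short_reads_kept_when_cycle_count_known():
    kept, stats = _clean([_read("ACGTACGTACGTACGTAC")], cycle_count=50)
    assert [r.seq for r in kept] == ["ACGTACGTACGTACGTAC"]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 2), st.text(alphabet="ACGT", min_size=4, max_size=12)),
        min_size=0,
        max_size=60,
    )
)
def test_collapse_conserves_read_counts(assignments):
    n_lib = 3
    libraries = [[] for _ in range(n_lib)]
    for lib_idx, seq in assignments:
        libraries[lib_idx].append(SequenceRecord(id="r", seq=seq))
    tags = collapse(libraries)
    assert sum(t.total_count for t in tags) == len(assignments)
    assert len({t.seq for t in tags}) == len(tags)
    for t in tags:
        assert t.total_count == sum(t.counts) >= 1


def test_collapse_tracks_per_library_counts():
    lib1 = [SequenceRecord(id="a", seq="ACGT")] * 2
    lib2 = [SequenceRecord(id="b", seq="ACGT")] * 3 + [SequenceRecord(id="c", seq="ACGA")]
    tags = {t.seq: t for t in collapse([lib1, lib2])}
    assert tags["ACGT"].counts == [2, 3] and tags["ACGT"].total_count == 5
    assert tags["ACGA"].counts == [0, 1]


@pytest.mark.parametrize(
    "length,kept", [(14, False), (15, True), (30, True), (31, False)]
)
def test_length_filter_bounds_inclusive(length, kept):
    tags = [UniqueTag(seq="A" * length, counts=[1])]
    assert bool(length_filter(tags)) is kept


def test_length_filter_empty():
    assert length_filter([]) == []


def test_classification_priority_mirna_wins():
    decoy_seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    decoys = {"rRNA": [SequenceRecord(id="d", seq=decoy_seq)]}
    cat_mature = SequenceRecord(id="dre-miR-x", seq=decoy_seq[:22])
    cat_pre = SequenceRecord(id="dre-mir-x", seq=decoy_seq)
    from mirseed.io_formats import ReferenceCatalog

    catalog = ReferenceCatalog(
        species="dre", matures=[cat_mature], precursors=[cat_pre],
        links={"dre-miR-x": ["dre-mir-x"]},
    )
    tags = [UniqueTag(seq=decoy_seq[:22], counts=[4])]
    classify_tags(tags, decoys, catalog)
    assert tags[0].annotation_class == "miRNA_known"


def test_class_frequencies_sum_to_one():
    tags = [
        UniqueTag(seq="A" * 20, counts=[3], annotation_class="rRNA"),
        UniqueTag(seq="C" * 20, counts=[1], annotation_class="unannotated"),
        UniqueTag(seq="G" * 20, counts=[6], annotation_class="miRNA_known"),
    ]
    freq = class_frequencies(tags)
    assert freq["total_frequency"].sum() == pytest.approx(1.0)
    assert freq["unique_frequency"].sum() == pytest.approx(1.0)
    assert freq.loc["miRNA_known", "total_count"] == 6


def test_contaminant_fraction_recovered_in_classification():
    """With contaminant_fraction=0.3 the miRNA+unannotated share of total
    counts is ~0.7 (binomial error on the simulated composition)."""
    cfg = SimulationConfig(
        seed=9, n_planted_hairpins=5, n_known_mirnas=20,
        genome_length=30_000, contaminant_fraction=0.3, expression_mu=4.0,
        no_insert_fraction=0.0, polya_fraction=0.0, lowq_fraction=0.0,
    )
    genome, truth = make_genome(cfg)
    cat, _ = make_known_catalog(cfg)
    libs = simulate_libraries(cfg, truth, cat)
    cleaned = [list(clean_reads(lib, cfg.adapter)) for lib in libs]
    tags = length_filter(collapse(cleaned))
    freq = classify_tags(tags, load_decoys(), cat)
    mirna_like = (
        freq.loc["miRNA_known", "total_frequency"]
        + freq.loc["unannotated", "total_frequency"]
        + freq.loc["miRNA_novel", "total_frequency"]
    )
    assert mirna_like == pytest.approx(0.7, abs=0.03)
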