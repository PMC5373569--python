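import numpy as np
import pytest

from mirseed.dollo_phylo import PhyloTree, iter_nodes, leaf_set, random_rooted_tree
from mirseed.rnafold import fold
from mirseed.synthetic_data import (
    SimulationConfig,
    load_decoys,
    make_genome,
    make_known_catalog,
    make_utrs,
    simulate_family_evolution,
    simulate_libraries,
)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationConfig(error_rate=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(contaminant_fraction=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_planted_hairpins=-1)


def test_same_seed_gives_byte_identical_genomes():
    cfg = SimulationConfig(seed=7, n_planted_hairpins=5, genome_length=20_000)
    g1, t1 = make_genome(cfg)
    g2, t2 = make_genome(cfg)
    assert g1[0].seq == g2[0].seq
    assert [(h.start, h.end, h.strand) for h in t1.hairpins] == [
        (h.start, h.end, h.strand) for h in t2.hairpins
    ]


def test_no_plants_means_pure_random_genome():
    cfg = SimulationConfig(seed=3, n_planted_hairpins=0, genome_length=5_000)
    genome, truth = make_genome(cfg)
    assert truth.hairpins == [] and len(genome[0].seq) == 5_000


def test_planted_count_matches_request(default_cfg, sim_run):
    assert len(sim_run["truth"].hairpins) == default_cfg.n_planted_hairpins


def test_planted_precursors_are_stable_hairpins(sim_run):
    """At least 95% of plants fold below the -18 kcal/mol criterion (the
    construction verifies each, so in practice all do)."""
    mfes = [fold(h.precursor_seq).mfe_kcal_mol for h in sim_run["truth"].hairpins]
    assert np.mean([m < -18.0 for m in mfes]) >= 0.95


def test_error_free_inserts_come_from_truth_or_decoys(sim_run, default_cfg):
    truth_seqs = {h.mature_seq for h in sim_run["truth"].hairpins}
    truth_seqs |= {m.seq for m in sim_run["catalog"].matures}
    decoy_seqs = [r.seq for g in load_decoys().values() for r in g]
    sample = sim_run["cleaned"][0][:300]
    for read in sample:
        ok = read.seq in truth_seqs or any(read.seq in d for d in decoy_seqs)
        assert ok, f"unexpected insert {read.seq}"


def test_replicate_lognormal_correlation_closed_form():
    """corr(log counts) = sigma^2/(sigma^2+sigma_rep^2); simulated at n=1000."""
    sigma, sigma_rep = 1.2, 0.1
    expected = sigma**2 / (sigma**2 + sigma_rep**2)
    assert expected > 0.9
    rng = np.random.default_rng(11)
    base = rng.normal(5.0, sigma, 1000)
    rep1 = base + rng.normal(0, sigma_rep, 1000)
    rep2 = base + rng.normal(0, sigma_rep, 1000)
    observed = np.corrcoef(rep1, rep2)[0, 1]
    assert observed == pytest.approx(expected, abs=0.02)
    assert observed > 0.9


def test_true_counts_respect_planted_floor(sim_run, default_cfg):
    counts = sim_run["truth"].true_counts
    planted = [h.name for h in sim_run["truth"].hairpins]
    assert int(counts.loc[planted].min().min()) >= default_cfg.min_planted_count
    assert counts.shape == (
        default_cfg.n_known_mirnas + default_cfg.n_planted_hairpins,
        default_cfg.n_replicates,
    )


def test_library_simulation_is_seed_deterministic():
    cfg = SimulationConfig(seed=5, n_planted_hairpins=2, n_known_mirnas=5,
                           genome_length=10_000, expression_mu=3.0)
    genome, truth = make_genome(cfg)
    cat, _ = make_known_catalog(cfg)
    lib1 = simulate_libraries(cfg, truth, cat)
    lib2 = simulate_libraries(cfg, truth, cat)
    assert [r.seq for r in lib1[0]] == [r.seq for r in lib2[0]]


def test_family_evolution_without_loss_fills_gain_subtrees(rng):
    tree = random_rooted_tree([f"s{i}" for i in range(6)], rng)
    matrix, _ = simulate_family_evolution(tree, 40, loss_prob=0.0, seed=2)
    subtree_leafsets = {frozenset(leaf_set(n)) for n in iter_nodes(tree)}
    for fam in matrix.columns:
        present = frozenset(matrix.index[matrix[fam] == 1])
        if present:
            assert present in subtree_leafsets  # exactly some node's subtree
    # at least one family gained at the root spans everyone, typically
    assert matrix.shape == (6, 40)


def test_family_evolution_rejects_bad_loss_prob(rng):
    tree = random_rooted_tree(list("abcd"), rng)
    with pytest.raises(ValueError):
        simulate_family_evolution(tree, 5, loss_prob=0.7)


def test_planted_utr_sites_are_seed_complements():
    mirnas = {"m1": "TGAGGTAGTAGGTTGTATAGTT"}
    utrs, sites = make_utrs(5, mirnas, seed=4)
    assert len(sites) == 5
    for uid, pos, mid in sites:
        seq = next(u.seq for u in utrs if u.id == uid)
        assert seq[pos : pos + 7] == "CTACCTC"  # revcomp of seed GAGGTAG


def test_empty_utr_request():
    records, sites = make_utrs(0, {}, seed=1)
    assert records == [] and sites == []
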