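import numpy as np
import pytest

from mirseed.synthetic_data import (
    SimulationConfig,
    load_decoys,
    make_genome,
    make_known_catalog,
    simulate_libraries,
)
from mirseed.preprocess import clean_reads, collapse, length_filter, classify_tags
from mirseed.known_annotation import match_known


@pytest.fixture(scope="session")
def default_cfg():
    """The default synthetic study conditions: 4 replicates, 20 planted
    hairpins with read support >= 10, error-free reads, seed 1."""
    return SimulationConfig(seed=1, n_planted_hairpins=20)


@pytest.fixture(scope="session")
def sim_run(default_cfg):
    """One full synthetic run carried through preprocessing and annotation.

    Returns a dict with genome, truth, catalog, families, libraries,
    cleaned tags (length-filtered, classified, known-matched) — shared by
    the preprocessing, annotation, discovery and acceptance tests.
    """
    cfg = default_cfg
    genome, truth = make_genome(cfg)
    catalog, families = make_known_catalog(cfg)
    libraries = simulate_libraries(cfg, truth, catalog)
    cleaned = [list(clean_reads(lib, cfg.adapter)) for lib in libraries]
    tags = length_filter(collapse(cleaned))
    frequencies = classify_tags(tags, load_decoys(), catalog)
    conserved, hit_table = match_known(tags, [catalog])
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "catalog": catalog,
        "families": families,
        "libraries": libraries,
        "cleaned": cleaned,
        "tags": tags,
        "frequencies": frequencies,
        "conserved": conserved,
        "hit_table": hit_table,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
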