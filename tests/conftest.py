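import numpy as np
import pytest

import msrrbs as M
from msrrbs.genome import FragmentCatalog, Genome, digest_mspi, index_cpgs, select_inserts


@pytest.fixture(scope="session")
def small_genome():
    return M.simulate_genome({"chr1": 30000, "chr2": 20000}, seed=11)


@pytest.fixture(scope="session")
def catalog(small_genome):
    return select_inserts(digest_mspi(small_genome), 30, 200)


@pytest.fixture(scope="session")
def cpg_index(small_genome):
    return index_cpgs(small_genome)


@pytest.fixture(scope="session")
def cgis(small_genome):
    return M.call_cgis(small_genome)


@pytest.fixture(scope="session")
def whitelist():
    return M.make_barcode_whitelist(8, seed=7)


@pytest.fixture(scope="session")
def profiles(cpg_index, cgis):
    arch = M.MethylomeArchetype()
    return [M.simulate_cell_methylome(cpg_index, cgis, arch, seed=100 + i,
                                      cell_id=f"cell{i}")
            for i in range(4)]


@pytest.fixture(scope="session")
def error_free_pool(profiles, catalog, whitelist):
    """Error-free, deterministic pool used for round-trip tests."""
    cfg = M.PoolConfig(barcodes=whitelist[:4], reads_per_cell=800,
                       error_rate=0.0, conversion_failure=0.0,
                       spike_fraction=0.0, seed=42)
    pairs, truth = M.simulate_reads(profiles, catalog, cfg)
    return {"pairs": pairs, "truth": truth, "config": cfg}


@pytest.fixture(scope="session")
def clean_pool(error_free_pool, whitelist):
    cfg = M.DemuxConfig(whitelist=whitelist[:4])
    by_cell, unassigned, report = M.demultiplex(error_free_pool["pairs"], cfg)
    clean = M.trim_reads(by_cell, cfg, report)
    return {"clean": clean, "unassigned": unassigned, "report": report,
            "demux_config": cfg}


@pytest.fixture(scope="session")
def aligned_pool(clean_pool, catalog):
    index = M.build_bs_index(catalog)
    return M.align_pool(clean_pool["clean"], index)


@pytest.fixture(scope="session")
def callsets(aligned_pool, catalog, cpg_index):
    return {cell: M.pileup_calls(aps, catalog, cpg_index, cell_id=cell)
            for cell, aps in aligned_pool.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
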