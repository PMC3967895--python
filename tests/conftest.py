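import pytest

from mhctyper import copynumber as cn
from mhctyper import simulate as sim
from mhctyper.demux import demultiplex_run


@pytest.fixture(scope="session")
def small_pool():
    return sim.generate_allele_pool(40, seed=11)


@pytest.fixture(scope="session")
def small_run(small_pool):
    """A 30-individual simulated run under default error/chimera settings."""
    freqs = cn.HaplotypeClassFreqs((0.55, 0.43, 0.02), 0.02)
    genotypes = sim.sample_population(small_pool, freqs, 30, seed=12)
    scheme = sim.make_barcode_scheme([g.individual_id for g in genotypes], seed=13)
    params = sim.ReadSimParams(seed=14)
    reads, truth = sim.simulate_reads(genotypes, small_pool, scheme, params)
    return {
        "pool": small_pool,
        "genotypes": genotypes,
        "scheme": scheme,
        "params": params,
        "reads": reads,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_bins(small_run):
    result = demultiplex_run(
        small_run["reads"],
        small_run["scheme"],
        sim.DEFAULT_FW_PRIMER,
        sim.DEFAULT_RV_PRIMER,
    )
    return result
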