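import numpy as np
import pytest

import f1binmap as fb
from f1binmap.segtype import SiteTable


def build_pipeline(seed, n_chrom=3, snps_per_chrom=300, chrom_len_bp=10_000_000,
                   error_rate=0.01, missing_rate=0.05, n_progeny=176, with_maps=True,
                   mask=True):
    """Simulate, classify, filter and bin one population; optionally map it."""
    cfg = fb.SimConfig(n_progeny=n_progeny, n_chrom=n_chrom, snps_per_chrom=snps_per_chrom,
                       chrom_len_bp=chrom_len_bp, error_rate=error_rate,
                       missing_rate=missing_rate, seed=seed)
    pop, truth = fb.simulate_population(cfg)
    table = SiteTable.from_population(pop)
    if mask:
        table.mask_low_confidence()
    table.classify().segregation_test()
    kept, log = fb.filter_sites(table)
    bins = fb.make_bins(kept)
    out = {"cfg": cfg, "pop": pop, "truth": truth, "table": table, "kept": kept,
           "log": log, "bins": bins}
    if with_maps:
        maternal, paternal = fb.build_parental_maps(bins)
        consensus = fb.merge_consensus(maternal, paternal, bins)
        out.update(maternal=maternal, paternal=paternal, consensus=consensus)
    return out


@pytest.fixture(scope="session")
def small_run():
    """One fully mapped 3-chromosome population shared across tests."""
    return build_pipeline(seed=7)


@pytest.fixture(scope="session")
def small_grids(small_run):
    from f1binmap import qtlscan

    return qtlscan.transmission_probs(small_run["consensus"], small_run["bins"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
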