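import numpy as np
import pytest

from polymap import simdata
from polymap.gio import GenotypeMatrix, VariantSite


def make_matrix(codes, chrom="1", positions=None, refs=None, alts=None,
                vtypes=None):
    """GenotypeMatrix from a samples-x-sites list of lists."""
    codes = np.asarray(codes, dtype=np.int8)
    n, s = codes.shape
    positions = positions or [100 * (i + 1) for i in range(s)]
    sites = []
    for i in range(s):
        ref = refs[i] if refs else "A"
        alt = alts[i] if alts else "G"
        sites.append(VariantSite(chrom=chrom, pos=positions[i], ref=ref,
                                 alt=alt,
                                 vtype=vtypes[i] if vtypes else "SNP"))
    return GenotypeMatrix(sites=sites,
                          samples=[f"s{i}" for i in range(n)], codes=codes)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """Small fast cohort for unit tests (not the default study conditions)."""
    return simdata.SimConfig(
        chrom_lengths={"1": 2_000_000, "2": 3_000_000},
        n_sites_per_chrom=150, causal_chrom="2", causal_pos=1_500_000,
        sweep_halfwidth=200_000, n_f2=40, n_families=5, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simdata.simulate_backcross(tiny_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One backcross under the default study conditions."""
    return simdata.simulate_backcross(simdata.SimConfig(seed=0))
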