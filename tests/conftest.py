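import numpy as np
import pytest

from tagarray import HaplotypeMatrix, GenotypeMatrix, Site, SimConfig, simulate_panels


def make_sites(m, chrom="1", start=100, step=100):
    return [Site(chrom, start + k * step, "A", "G") for k in range(m)]


def make_haps(arr, positions=None, chrom="1"):
    """HaplotypeMatrix from an (n_haps, m) 0/1 array; n_haps must be even."""
    arr = np.asarray(arr, dtype=np.uint8)
    n, m = arr.shape
    if positions is None:
        sites = make_sites(m, chrom=chrom)
    else:
        sites = [Site(chrom, int(p), "A", "G") for p in positions]
    samples = [f"s{i}" for i in range(n // 2)]
    return HaplotypeMatrix(sites, samples, arr)


def make_genotypes(arr, positions=None, chrom="1"):
    arr = np.asarray(arr, dtype=np.int8)
    n, m = arr.shape
    if positions is None:
        sites = make_sites(m, chrom=chrom)
    else:
        sites = [Site(chrom, int(p), "A", "G") for p in positions]
    samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(sites, samples, arr)


@pytest.fixture(scope="session")
def sim_small():
    """A modest admixed region reused across modules: 60 study + 40
    reference diploids over 400 kb."""
    cfg = SimConfig(
        seed=11, n_study_samples=60, n_reference_samples=40, region_bp=400_000
    )
    study, reference, ann = simulate_panels(cfg)
    return cfg, study, reference, ann
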