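import numpy as np
import pytest

from crossblup import GenotypeMatrix


def make_geno(dosages, pops=None, ind_ids=None, marker_ids=None):
    """Convenience builder for small genotype panels in tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if pops is None:
        pops = ["P1"] * n
    if ind_ids is None:
        ind_ids = [f"i{k}" for k in range(n)]
    if marker_ids is None:
        marker_ids = [f"s{k}" for k in range(m)]
    return GenotypeMatrix(
        dosages=dosages,
        pop_labels=np.array(pops, dtype=object),
        individual_ids=np.array(ind_ids, dtype=object),
        marker_ids=np.array(marker_ids, dtype=object),
    )


@pytest.fixture(scope="session")
def small_sim():
    """One seeded three-population simulation reused across tests."""
    from crossblup import SimConfig, simulate

    cfg = SimConfig(seed=1234, m=200, n1=80, n2=80, n12=80)
    geno, truth, phen = simulate(cfg)
    return cfg, geno, truth, phen
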