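import numpy as np
import pytest

import varscape as vs


@pytest.fixture(scope="session")
def arm_center_genome():
    """Two 6-Mb chromosomes with 1.5-Mb arms at 8 cM/Mb flanking a 3-Mb
    center at 0.5 cM/Mb: 1-Mb windows resolve the arm/center contrast."""
    chroms = [("c1", 6_000_000), ("c2", 6_000_000)]
    domains = {name: [(1_500_000, 8.0), (3_000_000, 0.5), (1_500_000, 8.0)]
               for name, _ in chroms}
    spec = vs.SyntheticGenomeSpec(chromosomes=chroms, rate_domains=domains,
                                  seed=42)
    return vs.make_genome(spec)


@pytest.fixture(scope="session")
def arm_center_variants(arm_center_genome):
    params = vs.MutationModelParams(R=10.0, M_d=400.0)
    sim = vs.SimulationParams(params=params, seed=43)
    return vs.simulate_variants(arm_center_genome, sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_variant(chrom="c1", start=100, end=101, ref="A", alt="G",
                 isolates=("iso01",), **kw):
    return vs.VariantRecord(chrom=chrom, start=start, end=end, ref=ref,
                            alt=alt, isolates=frozenset(isolates), **kw)
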