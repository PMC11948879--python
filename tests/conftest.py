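import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methcohort import FrequencyTable
from methcohort.simulate import CohortSpec, make_reference, simulate_modbam

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(positions, samples, values, chrom="chr1"):
    """Small helper: build a table from plain lists (NaN = missing)."""
    sites = [(chrom, p) for p in positions]
    return FrequencyTable.from_records(sites, samples, np.asarray(values, float))


@pytest.fixture
def small_table():
    return make_table(
        [100, 200, 300],
        ["S1", "S2"],
        [[0.1, 0.9], [0.5, np.nan], [1.0, 0.0]],
    )


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """One shared simulated modBAM cohort: (spec, bam paths, fasta, truth)."""
    out = tmp_path_factory.mktemp("simbam")
    spec = CohortSpec(n_individuals=3, n_sites=12, depth=8, seed=11)
    reference = make_reference(spec.n_sites, spec.spacing, seed=5)
    bams, fasta, truth = simulate_modbam(spec, reference, out)
    return spec, bams, fasta, truth
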