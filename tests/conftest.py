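import numpy as np
import pytest

from grburden.annotations_io import (
    SamplePanel,
    SampleRecord,
    VariantAnnotation,
)
from grburden.synthetic_data import PopulationSpec, SimulationConfig, simulate_cohort


def make_annotation(rsid="rs1", chrom="1", pos=100, effect="A", other="G",
                    beta=0.05, state="ancestral", cadd=5.0):
    return VariantAnnotation(rsid, chrom, pos, effect, other, beta, state, cadd)


@pytest.fixture
def small_panel():
    return SamplePanel(
        [
            SampleRecord("S1", "CHB", "EAS", "male"),
            SampleRecord("S2", "CHB", "EAS", "female"),
            SampleRecord("S3", "GBR", "EUR", "male"),
            SampleRecord("S4", "GBR", "EUR", "female"),
        ]
    )


@pytest.fixture(scope="session")
def two_pop_config():
    return SimulationConfig(
        n_variants=20,
        populations=(
            PopulationSpec("POPA", "SUPA", 60, 0.1),
            PopulationSpec("POPB", "SUPB", 60, 0.02),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def cohort_files(two_pop_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(two_pop_config, outdir)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
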