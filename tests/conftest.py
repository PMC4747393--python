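import numpy as np
import pytest

from lynchmod.cohort import load_study_cohort
from lynchmod.synthetic import SimulationConfig, build_panel, simulate_cohort, write_fixture


@pytest.fixture(scope="session")
def study_subjects():
    return load_study_cohort()


@pytest.fixture(scope="session")
def toy_transcripts():
    """A small random panel of two-exon toy transcripts (both strands)."""
    config = SimulationConfig(
        seed=123,
        genes_per_group={"estrogen": 8, "oncogene": 8, "tumor_suppressor": 8, "other": 6},
        n_codons=60,
    )
    rng = np.random.default_rng(123)
    _panel, transcripts, _ = build_panel(config, rng)
    return transcripts


@pytest.fixture(scope="session")
def synthetic_cohort():
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_fixture_dir(synthetic_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(synthetic_cohort, out)
    return paths
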