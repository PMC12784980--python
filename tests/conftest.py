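import numpy as np
import pytest

from hmmpeaks.cli import analyze_tags
from hmmpeaks.genome_io import GenomeLayout
from hmmpeaks.simulate import SimulationSpec, generate_reads, sample_ground_truth


@pytest.fixture
def layout2m() -> GenomeLayout:
    return GenomeLayout((("chrT", 2_000_000),), bin_size=200)


@pytest.fixture(scope="session")
def small_sim():
    """50 narrow truth peaks at quality 1.0 on a 2 Mbp toy chromosome."""
    layout = GenomeLayout((("chrT", 2_000_000),), bin_size=200)
    spec = SimulationSpec(layout=layout, n_peaks=50, n_reads=200_000, quality=1.0, seed=7)
    truth = sample_ground_truth(spec)
    tags = generate_reads(truth, spec)
    return spec, truth, tags


@pytest.fixture(scope="session")
def small_result(small_sim):
    spec, truth, tags = small_sim
    return analyze_tags(tags, spec.layout, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
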