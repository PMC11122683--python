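import numpy as np
import pytest

from endrip.core import GenomeSpec
from endrip.pipeline import run_dsb_analysis, run_rloop_analysis
from endrip.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec.from_lengths({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default synthetic study (3 x 5 Mbp, 300 deDSB, 280 hybrid peaks)."""
    path = tmp_path_factory.mktemp("study")
    truth = simulate_dataset(SimulationConfig(seed=1), path)
    return path, truth


@pytest.fixture(scope="session")
def dsb_analysis(default_study):
    path, _ = default_study
    return run_dsb_analysis(path)


@pytest.fixture(scope="session")
def rloop_analysis(default_study):
    path, _ = default_study
    return run_rloop_analysis(path)
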