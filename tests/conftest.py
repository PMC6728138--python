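import numpy as np
import pytest

from mrblepep import (
    AssayDesign,
    make_code_map,
    make_ground_truth,
    simulate_assay,
)
from mrblepep.library_design import PVIVIT, Scaffold


@pytest.fixture
def pvivit() -> Scaffold:
    return PVIVIT


@pytest.fixture
def peptides48() -> list[str]:
    return [f"pep{i:03d}" for i in range(48)]


@pytest.fixture
def code_map48(peptides48):
    return make_code_map(48, n_channels=3, levels_per_channel=4, seed=7, peptides=peptides48)


@pytest.fixture
def truth48(peptides48):
    # log-spaced truths bracketed by the 62.5-2000 nM series
    return make_ground_truth(peptides48, kd_range_nM=(30.0, 3000.0), seed=7, log_spaced=True)


@pytest.fixture
def beads48(code_map48, truth48):
    return simulate_assay(code_map48, truth48, AssayDesign(seed=7))


@pytest.fixture
def noiseless_design():
    return AssayDesign(intensity_sigma=0.0, ratio_sigma=0.0, background=0.0, seed=0)
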