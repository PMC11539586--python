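import numpy as np
import pytest

import mixsim as mx


@pytest.fixture(scope="session")
def simple_table() -> mx.FrequencyTable:
    """Two-locus toy table with exact sums."""
    return mx.FrequencyTable(
        "toy",
        100,
        {
            "TPOX": {"8": 0.5, "9": 0.3, "11": 0.2},
            "TH01": {"6": 0.25, "7": 0.25, "9.3": 0.5},
        },
    )


@pytest.fixture(scope="session")
def codis_table() -> mx.FrequencyTable:
    """13-locus synthetic table passing the full QC ladder."""
    return mx.make_table(0.75, seed=11)


@pytest.fixture(scope="session")
def study_panel() -> list[mx.FrequencyTable]:
    """The 15-group synthetic panel spanning diversity 0.67-0.80."""
    spec = mx.SynthPanelSpec(diversity_targets=mx.evenly_spaced_targets(15), seed=2024)
    return mx.make_panel(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
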