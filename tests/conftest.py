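from pathlib import Path

import pytest

import tevckit as tk

DATA = Path(__file__).parent / "data"


@pytest.fixture
def env():
    return tk.Environment()


@pytest.fixture
def reference_perms():
    """The published-style permeability ratios used as generative ground truth."""
    return tk.PermeabilitySet({"K": 1.0, "Na": 0.63, "Cl": 0.03})


@pytest.fixture
def baths():
    return tk.standard_baths()


@pytest.fixture
def noiseless_cfg():
    """Deterministic, noise-free simulation for exact round trips."""
    return tk.SimulationConfig(noise_sd_uA=0.0, amplitude_cv=0.0, seed=7)


@pytest.fixture
def mini_trace_path():
    return DATA / "mini_traces.csv"
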