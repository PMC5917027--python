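import numpy as np
import pytest

from mitotempo import synthetic_data as sd
from mitotempo import serial_coalescent as sc


@pytest.fixture(scope="session")
def fixtures():
    return sd.toy_fixtures()


@pytest.fixture(scope="session")
def mountain_study():
    """A small-genome mountain-gorilla-like dataset for fast end-to-end tests."""
    design = sd.builtin_design("mountain", length=2000)
    mut = sd.default_mutation_model("mountain", length=2000)
    demo = sc.constant_model(3000.0)
    aln, meta, truth = sd.generate_study(design, demo, mut, seed=1234)
    return aln, meta, truth


@pytest.fixture(scope="session")
def grauer_study():
    design = sd.builtin_design("grauer", length=2000)
    mut = sd.default_mutation_model("grauer", length=2000)
    demo = sc.constant_model(3000.0)
    aln, meta, truth = sd.generate_study(design, demo, mut, seed=4321)
    return aln, meta, truth
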