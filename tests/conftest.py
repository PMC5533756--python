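"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from ibarlab.synthetic import _Builder, GeneratorConfig, parameter_table


@pytest.fixture
def builder():
    return _Builder


@pytest.fixture
def two_group_system():
    """A LYS residue (protein) 10 Å above a DOPC lipid, in a 60 Å box."""
    b = _Builder()
    b.place("DOPC", 1, "M", "DOPC", np.array([30.0, 30.0, 20.0]))
    b.place("LYS", 2, "A", "protein_A", np.array([30.0, 30.0, 30.0]))
    system, frame = b.build(np.array([60.0, 60.0, 60.0]))
    return system, frame


@pytest.fixture
def random_interface_system():
    """~100 heavy atoms of mixed residues at random positions (seeded)."""
    rng = np.random.default_rng(42)
    b = _Builder()
    rid = 1
    for _ in range(8):
        b.place(rng.choice(["LYS", "ARG", "GLU", "ASP", "SER"]), rid, "A",
                "protein_A", rng.uniform(5, 35, 3))
        rid += 1
    for _ in range(6):
        b.place(rng.choice(["DOPC", "DOPE", "DOPS"]), rid, "M",
                rng.choice(["DOPC", "DOPE", "DOPS"]), rng.uniform(5, 35, 3))
        rid += 1
    return b.build(np.array([40.0, 40.0, 40.0]))


@pytest.fixture(scope="session")
def small_membrane_cfg():
    """Scaled-down bilayer (same 4:4:1 composition) for fast profiles."""
    return GeneratorConfig(seed=7, n_dopc=160, n_dope=160, n_dops=40,
                           box=(235.0, 45.0, 150.0), n_frames=2,
                           noise_sd=0.0, jitter=0.0)


@pytest.fixture(scope="session")
def param_table():
    return parameter_table()
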