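"""Shared fixtures: small deterministic synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from grevol.seqio import read_tree


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def three_species_tree():
    return read_tree("((A:1.0,B:1.0)AB:0.5,C:1.5)ABC;")


@pytest.fixture(scope="session")
def four_taxon_tree():
    return read_tree("((s1:0.3,s2:0.3)n1:0.15,(s3:0.3,s4:0.3)n2:0.15)root;")
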