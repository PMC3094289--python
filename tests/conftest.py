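"""Shared fixtures: the packaged template and cached calibrated configs."""

from __future__ import annotations

import numpy as np
import pytest

from pscarbor.genotypes import load_genotype_config
from pscarbor.synthgen import calibrate_config
from pscarbor.templates import load_wildtype_template


@pytest.fixture(scope="session")
def template():
    return load_wildtype_template()


@pytest.fixture(scope="session")
def calibrated(template):
    """Factory returning calibrated packaged configs, cached per session
    (retention calibration runs a short internal Monte-Carlo)."""
    cache: dict = {}

    def get(name: str):
        if name not in cache:
            cache[name] = calibrate_config(load_genotype_config(name), template)
        return cache[name]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
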