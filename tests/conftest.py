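"""Shared fixtures: the transluminal scenario runs are expensive (tens of
seconds each), so the tumour and homogeneous-control runs are computed once
per session and shared by solver property tests and acceptance tests."""

import logging

import pytest

from kvfdwave.config import load_config
from kvfdwave.experiments import clinical_scenario

logging.getLogger("kvfdwave").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def table3_config():
    return load_config("prostate_table3")


@pytest.fixture(scope="session")
def clinical_run(table3_config):
    """Full 42 ms transluminal run with the tumour inclusion."""
    return clinical_scenario(table3_config, include_tumour=True)


@pytest.fixture(scope="session")
def control_run(table3_config):
    """Homogeneous (no-tumour) control of the same scenario."""
    return clinical_scenario(table3_config, include_tumour=False)
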