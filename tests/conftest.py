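"""Shared fixtures: arterial input, phantom geometry, workflow bundle."""

import numpy as np
import pytest

from neuropet._kinetics import fine_grid
from neuropet.core_io import WATER_FRAME_SCHEDULE
from neuropet.phantom import default_input, default_spec, make_phantom


@pytest.fixture(scope="session")
def arterial_input():
    return default_input()


@pytest.fixture(scope="session")
def water_grid():
    return fine_grid(10.0)


@pytest.fixture(scope="session")
def water_schedule():
    return WATER_FRAME_SCHEDULE


@pytest.fixture(scope="session")
def phantom_128():
    spec = default_spec(noise_percent=2.0, seed=0)
    atlas, structural = make_phantom(spec)
    return spec, atlas, structural


@pytest.fixture(scope="session")
def workflow_run(tmp_path_factory):
    """One full phantom workflow run, shared by the end-to-end tests."""
    from neuropet.pipeline import WorkflowConfig, run_workflow, write_phantom_bundle

    tmp = tmp_path_factory.mktemp("bundle")
    bundle = write_phantom_bundle(tmp, seed=0, noise_percent=5.0)
    config = WorkflowConfig.from_yaml(bundle["config"])
    result = run_workflow(config)
    return bundle, config, result
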