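import numpy as np
import pytest

from nasometry import sample_face, project


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def face():
    """One reproducible synthetic participant without head tilt."""
    return sample_face(11, overrides={"tilt_deg": 0.0, "hump_present": False})


@pytest.fixture(scope="session")
def hump_face():
    return sample_face(13, overrides={"tilt_deg": 0.0, "hump_present": True})


@pytest.fixture(scope="session")
def views(face):
    return {v: project(face, v) for v in ("frontal", "lateral", "mental")}


@pytest.fixture(scope="session")
def hump_views(hump_face):
    return {v: project(hump_face, v) for v in ("frontal", "lateral", "mental")}
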