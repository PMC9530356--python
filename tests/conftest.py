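import numpy as np
import pytest

from woundmetry.registration import MarkerReference
from woundmetry.synthetic import default_scene_spec, generate_scene, make_reference_marker


@pytest.fixture(scope="session")
def reference_marker() -> np.ndarray:
    return make_reference_marker()


@pytest.fixture(scope="session")
def marker_reference(reference_marker) -> MarkerReference:
    return MarkerReference.from_physical_side(reference_marker, 30.0)


@pytest.fixture(scope="session")
def ulcer_scene():
    """One deterministic single-ulcer scene with 5 deg marker rotation."""
    spec = default_scene_spec("ulceration", seed=3, rotation_deg=5.0)
    return generate_scene(spec)
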