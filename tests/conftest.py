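import numpy as np
import pytest

from mesomap import SyntheticTissueSpec, default_validation_spec, generate_centroid_field


@pytest.fixture(scope="session")
def square_spec():
    """Constant 10 μm spacing on a 150x150 μm square, seed 1."""
    return default_validation_spec(seed=1)


@pytest.fixture(scope="session")
def square_field(square_spec):
    field, truth = generate_centroid_field(square_spec)
    return field, truth


@pytest.fixture(scope="session")
def rendered_panel():
    """Three rendered validation images with ground truth (seeds 1-3)."""
    from mesomap import render_section_image

    panel = []
    for seed in (1, 2, 3):
        spec = default_validation_spec(seed=seed)
        field, truth = generate_centroid_field(spec)
        nuclear, label = render_section_image(field, spec)
        panel.append((spec, field, truth, nuclear, label))
    return panel


def interior_mask(points: np.ndarray, bounds: tuple[float, float, float, float], margin: float) -> np.ndarray:
    minx, miny, maxx, maxy = bounds
    return (
        (points[:, 0] > minx + margin)
        & (points[:, 0] < maxx - margin)
        & (points[:, 1] > miny + margin)
        & (points[:, 1] < maxy - margin)
    )
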