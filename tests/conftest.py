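import numpy as np
import pytest

from fasgaseg import RangeSet, TissueCatalogue, segment_image
from fasgaseg.phantom import generate_phantom, scaled_region_params, scaled_spec


@pytest.fixture(scope="session")
def catalogue():
    return TissueCatalogue.default()


@pytest.fixture(scope="session")
def ranges():
    return RangeSet()


@pytest.fixture(scope="session")
def sv_grid():
    """Exhaustive (s, v) grid at 0.01 resolution, as two 101x101 planes."""
    vals = np.round(np.arange(0, 101) * 0.01, 10)
    s, v = np.meshgrid(vals, vals, indexing="ij")
    return s, v


@pytest.fixture(scope="session")
def phantom_512():
    """A half-scale noise-free phantom plus its pipeline segmentation."""
    spec = scaled_spec(512, seed=1)
    image, truth, region_truth = generate_phantom(spec)
    result = segment_image(image, region_params=scaled_region_params(512))
    return spec, image, truth, region_truth, result


@pytest.fixture(scope="session")
def phantom_1024():
    """The full-scale noise-free phantom segmented with default parameters."""
    from fasgaseg import PhantomSpec

    spec = PhantomSpec(seed=11)
    image, truth, region_truth = generate_phantom(spec)
    result = segment_image(image)
    return spec, image, truth, region_truth, result
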