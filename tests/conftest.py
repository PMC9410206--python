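import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from radpipe import PhantomSpec, Sphere, generate_phantom  # noqa: E402
from radpipe.features import DiscretizedRoi  # noqa: E402


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noisy CT-like phantom with a radius-5 sphere lesion."""
    return generate_phantom(PhantomSpec(noise_sd=30.0, seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless phantom: lesion value 100 in a -1000 background."""
    return generate_phantom(
        PhantomSpec(
            lesions=(Sphere(center=(16, 16, 16), radius=5.0, intensity=100.0),),
            noise_sd=0.0,
            seed=0,
        )
    )


def roi_from_bins(bins: np.ndarray) -> DiscretizedRoi:
    """Wrap a raw bin array (0 = outside mask) as a DiscretizedRoi."""
    bins = np.asarray(bins, dtype=np.int64)
    return DiscretizedRoi(
        bins=bins,
        mask=bins > 0,
        bin_width=1.0,
        anchor=0.0,
        n_levels=int(bins.max()),
        spacing=(1.0, 1.0, 1.0),
    )
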