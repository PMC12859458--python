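import numpy as np
import pytest

from orgquant.core import DetectionSet, OrganoidInstance, instance_from_mask
from orgquant.synthgen import SynthConfig, generate_well


def disc_mask(radius: int) -> np.ndarray:
    """Boolean disc of the given radius, centered in a tight array."""
    side = 2 * radius + 1
    yy, xx = np.mgrid[:side, :side]
    return (yy - radius) ** 2 + (xx - radius) ** 2 <= radius**2


def square_instance(
    x0: int, y0: int, side: int, id: int, confidence: float = 1.0, source_tile=None
) -> OrganoidInstance:
    """Axis-aligned filled square at global (x0, y0)."""
    return instance_from_mask(
        np.ones((side, side), dtype=bool),
        id=id,
        confidence=confidence,
        offset=(x0, y0),
        source_tile=source_tile,
    )


def detset(instances, width=1024, height=1024, deduplicated=False) -> DetectionSet:
    return DetectionSet(
        instances=list(instances),
        image_width=width,
        image_height=height,
        deduplicated=deduplicated,
    )


@pytest.fixture(scope="session")
def small_well():
    """A 1024 px synthetic well with 12 organoids, shared across tests."""
    return generate_well(SynthConfig(width=1024, height=1024, n_organoids=12, seed=7))
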