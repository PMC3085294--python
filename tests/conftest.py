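import numpy as np
import pytest

from ebtbr.roi_geometry import CutoutImage
from ebtbr.synthetic import PhantomParams


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def make_cutout(pixels: np.ndarray, mask: np.ndarray | None = None) -> CutoutImage:
    """Cutout with an all-ones mask by default (pure-geometry tests)."""
    pixels = np.asarray(pixels)
    if mask is None:
        mask = np.ones(pixels.shape, dtype=np.uint8)
    return CutoutImage(pixels=pixels, mask=mask, offset=(0, 0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_params() -> PhantomParams:
    """A 1/5-scale phantom: fast enough for per-test pipeline runs."""
    return PhantomParams(rows=208, cols=278)
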