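import numpy as np
import pytest

from lesionrl.env import LesionImage


def make_image(size: int = 16, lesion_pixels=((10, 10),),
               image_id: str = "fixture") -> LesionImage:
    """Hand-built image: mid-gray raster with listed lesion pixels."""
    intensities = np.full((size, size), 0.5, dtype=np.float32)
    mask = np.zeros((size, size), dtype=bool)
    for r, c in lesion_pixels:
        mask[r, c] = True
        intensities[r, c] = 0.9
    return LesionImage(id=image_id, intensities=intensities, lesion_mask=mask)


def make_block_lesion_image(size: int, block_size: int, block: tuple[int, int],
                            image_id: str = "block-fixture") -> LesionImage:
    """Image whose lesion fills exactly one grid block."""
    intensities = np.full((size, size), 0.4, dtype=np.float32)
    mask = np.zeros((size, size), dtype=bool)
    r, c = block
    sl = (slice(r * block_size, (r + 1) * block_size),
          slice(c * block_size, (c + 1) * block_size))
    mask[sl] = True
    intensities[sl] = 0.9
    return LesionImage(id=image_id, intensities=intensities, lesion_mask=mask)


@pytest.fixture
def tiny_image() -> LesionImage:
    """16x16 image, 4-px blocks: the lesion pixel (10, 10) sits in block (2, 2)."""
    return make_image(16, lesion_pixels=((10, 10),))


@pytest.fixture
def tiny_block_size() -> int:
    return 4
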