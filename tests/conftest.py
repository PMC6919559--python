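import numpy as np
import pytest

from nucleval.mask_io import LabelMask


def make_mask(arr, image_id="m") -> LabelMask:
    return LabelMask(image_id=image_id, labels=np.asarray(arr, dtype=np.int64))


def random_blob_mask(rng: np.random.Generator, h: int, w: int, n: int) -> LabelMask:
    """Random overlapping-disc label mask; later discs may overwrite earlier ones."""
    lab = np.zeros((h, w), dtype=np.int64)
    yy, xx = np.mgrid[0:h, 0:w]
    for k in range(n):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rad = rng.uniform(1.5, max(2.0, min(h, w) / 5))
        d = np.hypot(yy - cy, xx - cx)
        sel = d <= rad
        if rng.random() < 0.5:
            sel = sel & (lab == 0)
        lab[sel] = k + 1
    return LabelMask(image_id="rand", labels=lab)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
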