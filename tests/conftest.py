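import numpy as np
import pytest

from scarvss import generate_study_dataset, subdivide


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study (small parents for speed): tiles + labels."""
    images, records = generate_study_dataset(7, size=(45, 45))
    tiles, labels, ids = [], [], []
    for img, rec in zip(images, records):
        for t, tile in enumerate(subdivide(img)):
            tiles.append(tile)
            labels.append(rec.vss_total)
            ids.append(f"{rec.image_id}_t{t}")
    return tiles, np.array(labels), ids
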