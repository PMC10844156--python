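import random

import pytest

from boxconcord.geometry_io import AnnotationSet, BoundingBox, Dataset, ImageFrame


def random_box(rng: random.Random, span: int = 24, max_side: int = 15) -> BoundingBox:
    """Integer-coordinate box; integer grids force frequent area/intersection ties."""
    x = rng.randint(0, span)
    y = rng.randint(0, span)
    w = rng.randint(1, max_side)
    h = rng.randint(1, max_side)
    return BoundingBox(x, y, x + w, y + h)


def random_instance(rng: random.Random, max_boxes: int = 4):
    na, nb = rng.randint(0, max_boxes), rng.randint(0, max_boxes)
    return (
        [random_box(rng) for _ in range(na)],
        [random_box(rng) for _ in range(nb)],
    )


def make_dataset(per_annotator: dict[str, dict[str, list[BoundingBox]]], frame=(200.0, 200.0)) -> Dataset:
    """Assemble a Dataset from nested {annotator: {image: [boxes]}} literals."""
    image_ids = sorted({i for d in per_annotator.values() for i in d})
    ds = Dataset(frames={i: ImageFrame(i, *frame) for i in image_ids})
    for aid, images in per_annotator.items():
        ds.add_annotator(AnnotationSet(aid, {i: list(b) for i, b in images.items()}))
    return ds


@pytest.fixture
def rng():
    return random.Random(982451)
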