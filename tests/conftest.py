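import numpy as np
import pytest

from cloudmorph import segment, synthgen


@pytest.fixture(scope="session")
def tissue12():
    """Noise-free 12-cell membrane tissue with ground-truth labels."""
    return synthgen.generate_membrane_volume(12, shape=(128, 128, 128), rng=0)


@pytest.fixture(scope="session")
def labels12(tissue12):
    """Segmentation of the 12-cell fixture with the default configuration."""
    return segment.segment_cells(tissue12.image)


@pytest.fixture(scope="session")
def cells20():
    """Twenty synthetic cells with their generative parameter table."""
    return synthgen.generate_dataset(20, rng=7)


def iou_against_truth(labels, truth):
    """Per-segmented-cell IoU against the best-overlapping truth label."""
    ious = []
    for lab in np.unique(labels)[1:]:
        m = labels == lab
        best = np.bincount(truth[m]).argmax()
        t = truth == best
        ious.append((m & t).sum() / (m | t).sum())
    return np.array(ious)
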