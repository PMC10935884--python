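import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from mdifp import FingerprintFrameSet, InteractionKey


@pytest.fixture
def toy_columns():
    return (
        InteractionKey("LIG1", "ARG96", "HBDonor"),
        InteractionKey("LIG1", "TYR272", "Hydrophobic"),
        InteractionKey("LIG1", "TYR272", "VdWContact"),
        InteractionKey("LIG1", "TRP206", "PiStacking"),
    )


@pytest.fixture
def toy_set(toy_columns):
    bits = np.array(
        [
            [1, 0, 1, 0],
            [1, 0, 1, 0],
            [0, 1, 0, 1],
            [1, 0, 1, 0],
            [1, 0, 1, 0],
        ],
        dtype=np.uint8,
    )
    return FingerprintFrameSet.from_bits(bits, toy_columns)


@pytest.fixture
def rng():
    return np.random.default_rng(20241)


def random_frame_set(rng, n_frames, columns):
    bits = (rng.random((n_frames, len(columns))) < 0.4).astype(np.uint8)
    return FingerprintFrameSet.from_bits(bits, columns)
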