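import numpy as np
import pytest

from mammocad.bdcnn import BDCNNConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cnn_config():
    """A scaled-down classifier config for fast unit tests (the full-size
    architecture is exercised in the acceptance tests)."""
    return BDCNNConfig(
        input_size=(32, 32),
        block_kernels=(8, 8, 8),
        block_kernel_sizes=(5, 3, 3),
        fc_nodes=32,
        batch_size=8,
        seed=0,
    )


def brute_force_filter(image: np.ndarray, mask: np.ndarray, op) -> np.ndarray:
    """Reference sliding min/max filter with edge replication.

    Independent oracle: explicit python loops over every pixel and every
    structuring-element cell, with out-of-bounds coordinates clamped to the
    nearest edge pixel.
    """
    h, w = image.shape
    mh, mw = mask.shape
    ar, ac = mh // 2, mw // 2
    out = np.empty_like(image)
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in range(mh):
                for dc in range(mw):
                    if not mask[dr, dc]:
                        continue
                    rr = min(max(r + dr - ar, 0), h - 1)
                    cc = min(max(c + dc - ac, 0), w - 1)
                    vals.append(image[rr, cc])
            out[r, c] = op(vals)
    return out


def brute_force_ssd(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Reference squared-difference distance map: explicit double loop."""
    th, tw = template.shape
    h, w = image.shape
    out = np.zeros((h - th + 1, w - tw + 1), dtype=np.float64)
    for i in range(h - th + 1):
        for j in range(w - tw + 1):
            d = 0.0
            for m in range(th):
                for n in range(tw):
                    diff = float(image[i + m, j + n]) - float(template[m, n])
                    d += diff * diff
            out[i, j] = d
    return out
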