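import numpy as np
import pytest

from rootpheno.segmentation import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_chain(rng, n_steps=30, size=None):
    """Random single-pixel 8-connected chain whose pixels touch only their
    chain predecessor/successor (a valid skeleton polyline).

    Returns (boolean mask, list of (row, col) in chain order).
    """
    size = size or (n_steps * 2 + 10)
    grid = np.zeros((size, size), dtype=bool)
    r = c = size // 2
    grid[r, c] = True
    chain = [(r, c)]
    moves = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    for _ in range(n_steps):
        rng.shuffle(moves)
        for dr, dc in moves:
            rr, cc = r + dr, c + dc
            if not (0 < rr < size - 1 and 0 < cc < size - 1) or grid[rr, cc]:
                continue
            # candidate must be 8-adjacent only to the current chain head
            neigh = grid[rr - 1 : rr + 2, cc - 1 : cc + 2]
            if neigh.sum() == 1:
                grid[rr, cc] = True
                chain.append((rr, cc))
                r, c = rr, cc
                break
        else:
            break
    return grid, chain


def polyline_length(chain):
    """Euclidean length of the polyline through the pixel centers."""
    pts = np.asarray(chain, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def make_blobs(rng, shape=(96, 96), sigma=4.0, frac=0.25):
    """Random smooth blob mask for property tests (guaranteed non-empty)."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.normal(size=shape), sigma)
    mask = noise > np.quantile(noise, 1 - frac)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    return BinaryMask(mask)


def count_components(mask, connectivity=2):
    from skimage.measure import label

    _, n = label(np.asarray(mask).astype(bool), connectivity=connectivity, return_num=True)
    return n
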