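import numpy as np
import pytest

from giantcell.synth import SynthSpec, generate_tissue
from giantcell.tissue import LabeledTissue


@pytest.fixture(scope="session")
def small_tissue():
    """~100-cell synthetic tissue shared by read-only tests."""
    tissue, table = generate_tissue(
        SynthSpec(n_cells=100, shape=(160, 160), seed=7)
    )
    return tissue, table


@pytest.fixture(scope="session")
def stomatal_tissue():
    tissue, table = generate_tissue(
        SynthSpec(n_cells=120, shape=(200, 200), seed=11, n_stomata=4)
    )
    return tissue, table


@pytest.fixture()
def four_cell_block():
    """2×2 block of four equal 8×8 square cells."""
    labels = np.zeros((16, 16), dtype=np.int32)
    labels[:8, :8] = 1
    labels[:8, 8:] = 2
    labels[8:, :8] = 3
    labels[8:, 8:] = 4
    return LabeledTissue(labels, pixel_size=1.0)


def brute_force_adjacency(labels, connectivity=4, min_contact=1):
    """Exhaustive scan over all adjacent pixel pairs (independent oracle)."""
    from collections import Counter

    H, W = labels.shape
    shifts = [(0, 1), (1, 0)]
    if connectivity == 8:
        shifts += [(1, 1), (1, -1)]
    counts = Counter()
    for r in range(H):
        for c in range(W):
            a = labels[r, c]
            if a == 0:
                continue
            for dr, dc in shifts:
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    b = labels[rr, cc]
                    if b != 0 and b != a:
                        counts[(min(a, b), max(a, b))] += 1
    return {pair: n for pair, n in counts.items() if n >= min_contact}
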