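import numpy as np
import pytest

from blowdown.rasters import HeightRaster


@pytest.fixture
def flat_chm():
    """Uniform 22.2 m canopy, 1.25 m pixels, 20x20."""
    return HeightRaster(np.full((20, 20), 22.2), 1.25)


@pytest.fixture
def checker_chm():
    """Alternating low/high canopy for gap-labeling edge cases."""
    v = np.full((10, 10), 25.0)
    v[::2, ::2] = 1.0
    return HeightRaster(v, 1.25)


def flood_fill_sizes(mask: np.ndarray) -> list[int]:
    """Brute-force 8-connected component sizes (independent of skimage)."""
    visited = np.zeros(mask.shape, dtype=bool)
    sizes = []
    for si, sj in zip(*np.nonzero(mask)):
        if visited[si, sj]:
            continue
        stack = [(si, sj)]
        visited[si, sj] = True
        size = 0
        while stack:
            a, b = stack.pop()
            size += 1
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    na, nb = a + da, b + db
                    if (
                        0 <= na < mask.shape[0]
                        and 0 <= nb < mask.shape[1]
                        and mask[na, nb]
                        and not visited[na, nb]
                    ):
                        visited[na, nb] = True
                        stack.append((na, nb))
        sizes.append(size)
    return sorted(sizes)
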