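from collections import deque

import numpy as np
import pytest

from dendroquant import Calibration


@pytest.fixture
def cluster_calibration() -> Calibration:
    """The 95 px = 5 µm calibration of the cluster-analysis images."""
    return Calibration(pixel_size_um=5.0 / 95.0)


@pytest.fixture
def unit_calibration() -> Calibration:
    return Calibration(pixel_size_um=1.0)


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[int]:
    """Brute-force connected-component areas via BFS (test oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            area = 0
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                area += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            areas.append(area)
    return areas
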