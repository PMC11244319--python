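"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive per-pixel loops and BFS so they share
no code path with the implementation they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from phenotray import CalibrationReference


@pytest.fixture
def calib_10px_per_cm() -> CalibrationReference:
    return CalibrationReference(a=100.0, b=10.0)


def disc_pixels_bruteforce(center, radius, shape=None):
    """All integer (row, col) with ||p - center|| <= radius, by full scan."""
    r0 = int(np.floor(center[0] - radius)) - 1
    r1 = int(np.ceil(center[0] + radius)) + 1
    c0 = int(np.floor(center[1] - radius)) - 1
    c1 = int(np.ceil(center[1] + radius)) + 1
    pixels = []
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                if shape is None or (0 <= r < shape[0] and 0 <= c < shape[1]):
                    pixels.append((r, c))
    return pixels


def flood_fill_components(mask, connectivity=8):
    """Connected-component areas by BFS flood fill; returns sorted area list."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros(mask.shape, dtype=bool)
    areas = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                area = 0
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    cr, cc = queue.popleft()
                    area += 1
                    for dr, dc in neigh:
                        nr, nc = cr + dr, cc + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                areas.append(area)
    return sorted(areas)


def exhaustive_otsu_variances(gray):
    """Between-class variance for every candidate threshold t in 0..255.

    Classes are {v <= t} and {v > t}; returns a length-256 array.
    """
    hist = np.zeros(256)
    for v in np.asarray(gray).ravel():
        hist[int(v)] += 1
    n = hist.sum()
    variances = np.zeros(256)
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        variances[t] = w0 * w1 * (mu0 - mu1) ** 2
    return variances
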