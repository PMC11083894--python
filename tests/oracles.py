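"""Brute-force reference implementations used only as test oracles.

Each function recomputes an image operation by direct definition —
per-voxel neighborhood scans, breadth-first flood fills — independent of
the scipy-based production code paths.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def median_oracle(a: np.ndarray, radius: int) -> np.ndarray:
    """Per-voxel sorted-neighborhood median with reflected edges."""
    r = radius
    pad = np.pad(a, r, mode="symmetric") if r else a
    out = np.empty_like(a)
    for z, y, x in np.ndindex(a.shape):
        neigh = pad[z : z + 2 * r + 1, y : y + 2 * r + 1, x : x + 2 * r + 1]
        out[z, y, x] = np.median(neigh)
    return out


def _min_filter_oracle(a: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    hz, hy, hx = (s // 2 for s in footprint.shape)
    pad = np.pad(a, ((hz, hz), (hy, hy), (hx, hx)), mode="symmetric")
    out = np.empty(a.shape, dtype=a.dtype)
    fp = footprint.astype(bool)
    for z, y, x in np.ndindex(a.shape):
        neigh = pad[z : z + footprint.shape[0], y : y + footprint.shape[1], x : x + footprint.shape[2]]
        out[z, y, x] = neigh[fp].min()
    return out


def _max_filter_oracle(a: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    hz, hy, hx = (s // 2 for s in footprint.shape)
    pad = np.pad(a, ((hz, hz), (hy, hy), (hx, hx)), mode="symmetric")
    out = np.empty(a.shape, dtype=a.dtype)
    fp = footprint.astype(bool)
    for z, y, x in np.ndindex(a.shape):
        neigh = pad[z : z + footprint.shape[0], y : y + footprint.shape[1], x : x + footprint.shape[2]]
        out[z, y, x] = neigh[fp].max()
    return out


def tophat_oracle(a: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """White top-hat: input minus (erosion then dilation), clipped at 0."""
    opened = _max_filter_oracle(_min_filter_oracle(a, footprint), footprint)
    return np.clip(a.astype(np.float64) - opened, 0.0, None)


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_labels(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Connected components by BFS, labels in raster order of first voxel."""
    offs = _neighbor_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_label = 0
    for start in np.ndindex(mask.shape):
        if not mask[start] or labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not labels[n]:
                        labels[n] = next_label
                        queue.append(n)
    return labels


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Foreground plus any background region not 6-connected to the border."""
    bg = ~mask
    reached = np.zeros(mask.shape, dtype=bool)
    queue = deque()
    for idx in np.ndindex(mask.shape):
        if bg[idx] and any(idx[i] in (0, mask.shape[i] - 1) for i in range(3)):
            reached[idx] = True
            queue.append(idx)
    offs = _neighbor_offsets(6)
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offs:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                if bg[n] and not reached[n]:
                    reached[n] = True
                    queue.append(n)
    return mask | (bg & ~reached)


def mip_oracle(a: np.ndarray) -> np.ndarray:
    """Per-(y, x) max over z by exhaustive scan."""
    out = np.full(a.shape[1:], -np.inf)
    for z in range(a.shape[0]):
        for y in range(a.shape[1]):
            for x in range(a.shape[2]):
                out[y, x] = max(out[y, x], a[z, y, x])
    return out


def roi_mean_oracle(img: np.ndarray, y0: int, x0: int, h: int, w: int) -> float:
    """ROI mean by explicit sum / count."""
    total = 0.0
    n = 0
    for y in range(y0, y0 + h):
        for x in range(x0, x0 + w):
            total += float(img[y, x])
            n += 1
    return total / n
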