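"""Independent brute-force oracles for the low-level mask operators.

Everything here is deliberately naive (flood fill, O(n^2) pairwise
distances) and shares no code with the implementation it checks.
"""

from collections import deque

import numpy as np

_ALL_OFFSETS = [(dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)]


def neighbourhood_offsets(connectivity: int):
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return [o for o in _ALL_OFFSETS if sum(abs(v) for v in o) <= rank]


def flood_fill_components(data: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS labelling of connected components; labels 1..K, 0 background."""
    offsets = neighbourhood_offsets(connectivity)
    labels = np.zeros(data.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(data)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (0 <= nx < data.shape[0] and 0 <= ny < data.shape[1]
                        and 0 <= nz < data.shape[2]
                        and data[nx, ny, nz] and not labels[nx, ny, nz]):
                    labels[nx, ny, nz] = current
                    queue.append((nx, ny, nz))
    return labels


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def boundary(data: np.ndarray) -> np.ndarray:
    """Foreground voxels with a background (or out-of-bounds) 6-neighbour."""
    out = np.zeros(data.shape, dtype=bool)
    for x, y, z in zip(*np.nonzero(data)):
        for dx, dy, dz in neighbourhood_offsets(6):
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < data.shape[0] and 0 <= ny < data.shape[1]
                    and 0 <= nz < data.shape[2]) or not data[nx, ny, nz]:
                out[x, y, z] = True
                break
    return out


def _pairwise_min_mm(src: np.ndarray, dst: np.ndarray, spacing) -> np.ndarray:
    """Per src voxel: distance (mm) to the nearest dst voxel, by full O(n^2) scan."""
    s = np.argwhere(src) * np.asarray(spacing)
    d = np.argwhere(dst) * np.asarray(spacing)
    diff = s[:, None, :] - d[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)


def brute_hd95(a: np.ndarray, b: np.ndarray, spacing) -> float:
    ba, bb = boundary(a), boundary(b)
    d_ab = _pairwise_min_mm(ba, bb, spacing)
    d_ba = _pairwise_min_mm(bb, ba, spacing)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def brute_directed_p95(src: np.ndarray, dst: np.ndarray, spacing) -> float:
    return float(np.percentile(_pairwise_min_mm(boundary(src), dst, spacing), 95))


def brute_min_distance(a: np.ndarray, b: np.ndarray, spacing) -> float:
    if (a & b).any():
        return 0.0
    return float(_pairwise_min_mm(a, b, spacing).min())
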