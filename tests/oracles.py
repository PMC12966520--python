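"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy.ndimage morphology so they exercise a
different code path than the package: pure-Python BFS/flood fill on
voxel sets, direct set arithmetic for overlap metrics.
"""

from collections import deque

import numpy as np

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _neighbors(connectivity=6):
    if connectivity == 6:
        return list(_OFFSETS_6)
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(mask, connectivity=6):
    """All connected components of a binary mask, by BFS over voxel sets."""
    mask = np.asarray(mask) != 0
    voxels = set(map(tuple, np.argwhere(mask)))
    offs = _neighbors(connectivity)
    comps = []
    while voxels:
        seed = voxels.pop()
        comp = {seed}
        q = deque([seed])
        while q:
            v = q.popleft()
            for o in offs:
                nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if nb in voxels:
                    voxels.discard(nb)
                    comp.add(nb)
                    q.append(nb)
        out = np.zeros(mask.shape, dtype=bool)
        idx = np.array(sorted(comp))
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        comps.append(out)
    return comps


def geodesic_distance(component, seeds, connectivity=6):
    """BFS geodesic distance (in steps) from the seed set inside a component.

    Returns an int array with -1 for unreachable/background voxels.
    """
    component = np.asarray(component) != 0
    seeds = np.asarray(seeds) != 0
    dist = np.full(component.shape, -1, dtype=np.int64)
    offs = _neighbors(connectivity)
    q = deque()
    for v in map(tuple, np.argwhere(seeds & component)):
        dist[v] = 0
        q.append(v)
    shape = component.shape
    while q:
        v = q.popleft()
        d = dist[v]
        for o in offs:
            nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if not all(0 <= nb[i] < shape[i] for i in range(3)):
                continue
            if component[nb] and dist[nb] < 0:
                dist[nb] = d + 1
                q.append(nb)
    return dist


def brute_dilate(mask, iterations=1, connectivity=6):
    """Morphological dilation by explicit voxel-neighbour enumeration."""
    mask = np.asarray(mask) != 0
    offs = _neighbors(connectivity)
    shape = mask.shape
    current = set(map(tuple, np.argwhere(mask)))
    for _ in range(iterations):
        added = set()
        for v in current:
            for o in offs:
                nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= nb[i] < shape[i] for i in range(3)):
                    added.add(nb)
        current |= added
    out = np.zeros(shape, dtype=bool)
    for v in current:
        out[v] = True
    return out


def dice_oracle(a, b):
    a = np.asarray(a) != 0
    b = np.asarray(b) != 0
    inter = np.count_nonzero(a & b)
    total = np.count_nonzero(a) + np.count_nonzero(b)
    if total == 0:
        return 1.0
    return 2.0 * inter / total


def min_pair_distance(a, b):
    """Minimal voxel-centre Euclidean distance between two masks."""
    av = np.argwhere(np.asarray(a) != 0).astype(float)
    bv = np.argwhere(np.asarray(b) != 0).astype(float)
    best = np.inf
    for v in av:
        d = np.sqrt(((bv - v) ** 2).sum(axis=1)).min()
        best = min(best, d)
    return best
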