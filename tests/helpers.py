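"""Shared test utilities and independent brute-force oracles."""

from collections import deque
from itertools import product

import numpy as np

from rimsift import BinaryMask


def make_mask(data, voxel=0.5):
    return BinaryMask(np.asarray(data, dtype=np.uint8),
                      np.diag([voxel, voxel, voxel, 1.0]))


def sort_percentile(values, p):
    """Sort-based percentile oracle: interpolate at index (n-1)*p/100."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * p / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def bfs_components(mask, connectivity):
    """Independent flood-fill oracle for connected-component labeling."""
    if connectivity == 6:
        neigh = [d for d in product((-1, 0, 1), repeat=3) if sum(map(abs, d)) == 1]
    elif connectivity == 18:
        neigh = [d for d in product((-1, 0, 1), repeat=3)
                 if 1 <= sum(map(abs, d)) <= 2]
    else:
        neigh = [d for d in product((-1, 0, 1), repeat=3) if any(d)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for idx in np.ndindex(mask.shape):
        if mask[idx] and not seen[idx]:
            q = deque([idx])
            seen[idx] = True
            comp = {idx}
            while q:
                cur = q.popleft()
                for d in neigh:
                    nb = tuple(c + o for c, o in zip(cur, d))
                    if all(0 <= c < s for c, s in zip(nb, mask.shape)) \
                            and mask[nb] and not seen[nb]:
                        seen[nb] = True
                        comp.add(nb)
                        q.append(nb)
            comps.append(comp)
    return comps
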