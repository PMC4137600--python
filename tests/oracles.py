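"""Independent brute-force oracles used by the test suite.

These implement the set definitions directly (double loops, BFS flood
fill) and share no code with the package's vectorized implementations.
"""

from collections import deque

import numpy as np


def dilate_oracle(a: np.ndarray, offsets) -> np.ndarray:
    """c foreground iff c = a + b for some foreground a, offset b (clipped)."""
    out = np.zeros_like(a, dtype=bool)
    shape = a.shape
    for idx in zip(*np.nonzero(a)):
        for b in offsets:
            c = tuple(int(i) + int(o) for i, o in zip(idx, b))
            if all(0 <= ci < n for ci, n in zip(c, shape)):
                out[c] = True
    return out


def erode_oracle(a: np.ndarray, offsets) -> np.ndarray:
    """x foreground iff a[x + b] foreground for every b (out-of-bounds = bg)."""
    out = np.zeros_like(a, dtype=bool)
    shape = a.shape
    for idx in np.ndindex(shape):
        ok = True
        for b in offsets:
            c = tuple(int(i) + int(o) for i, o in zip(idx, b))
            if not all(0 <= ci < n for ci, n in zip(c, shape)) or not a[c]:
                ok = False
                break
        out[idx] = ok
    return out


def flood_fill_partition(a: np.ndarray, neighbor_offsets) -> list:
    """Connected components as a list of frozensets of voxel index tuples,
    found by breadth-first flood fill."""
    a = np.asarray(a, dtype=bool)
    seen = np.zeros_like(a, dtype=bool)
    comps = []
    shape = a.shape
    for start in zip(*np.nonzero(a)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            cur = q.popleft()
            comp.add(cur)
            for off in neighbor_offsets:
                nb = tuple(int(i) + int(o) for i, o in zip(cur, off))
                if all(0 <= ci < n for ci, n in zip(nb, shape)) \
                        and a[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        comps.append(frozenset(comp))
    return comps


def partition_of_label_map(label_map: np.ndarray) -> set:
    """Canonical partition {frozenset(voxels of each label)} of a label map."""
    out = {}
    for idx in zip(*np.nonzero(label_map)):
        out.setdefault(int(label_map[idx]), set()).add(idx)
    return {frozenset(v) for v in out.values()}
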