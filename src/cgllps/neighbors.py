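"""Pair-list construction for periodic orthorhombic boxes.

Uses a KD-tree with periodic wrapping when the search radius fits within
half the smallest box length, and falls back to the exact all-pairs list
otherwise (small systems / tight boxes).  Bonded (1-2) pairs are excluded
from the nonbonded lists.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def all_pairs(n: int) -> np.ndarray:
    i, j = np.triu_indices(n, k=1)
    return np.column_stack([i, j]).astype(np.int64)


def pair_list(
    positions: np.ndarray,
    box: np.ndarray,
    cutoff: float,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Pairs with minimum-image distance < ``cutoff``.

    The returned list is a superset filter for the force kernels (which
    re-check per-term cutoffs), so it may be built with a skin added to
    ``cutoff``.
    """
    n = len(positions)
    box = np.asarray(box, dtype=float)
    if cutoff < min(box) / 2.0 and n > 1:
        wrapped = positions - box * np.floor(positions / box)
        # cKDTree requires coordinates strictly inside [0, L)
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray").astype(np.int64)
    else:
        pairs = all_pairs(n)
    if exclude is not None and len(exclude) > 0 and len(pairs) > 0:
        key = pairs[:, 0] * n + pairs[:, 1]
        lo = np.minimum(exclude[:, 0], exclude[:, 1])
        hi = np.maximum(exclude[:, 0], exclude[:, 1])
        bad = lo * n + hi
        pairs = pairs[~np.isin(key, bad)]
    return pairs
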