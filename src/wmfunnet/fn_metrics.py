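"""Parcellation comparison and interhemispheric symmetry.

Two parcellations are compared by the Dice coefficient between every pair
of regions. Symmetry is quantified by mirroring voxels through the
midsagittal plane (world x = 0): the global score is the adjacency Dice
between the left- and right-hemisphere co-membership matrices of voxels
with a labelled mirror partner; the per-network variant Dices every
left-restricted network against every mirrored right-restricted network,
so both self-symmetric networks (diagonal) and contralateral pairs
(off-diagonal) show up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fn_cluster import Parcellation, adjacency_dice

__all__ = ["DiceMatrix", "dice_matrix", "symmetry_global", "symmetry_per_fn", "mirror_voxels"]


@dataclass
class DiceMatrix:
    matrix: np.ndarray
    row_ids: list[int]
    col_ids: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_ids, columns=self.col_ids)


def dice_matrix(parc_a: Parcellation, parc_b: Parcellation) -> DiceMatrix:
    """Dice coefficient between every region of ``parc_a`` and ``parc_b``:
    entry (i, j) = 2|A_i n B_j| / (|A_i| + |B_j|) over voxel sets."""
    vol_a = parc_a.volume
    vol_b = parc_b.volume
    if vol_a.shape != vol_b.shape:
        raise ValueError("parcellations are on different grids")
    ids_a = list(range(1, parc_a.K + 1))
    ids_b = list(range(1, parc_b.K + 1))
    out = np.zeros((len(ids_a), len(ids_b)))
    flagged = []
    for i, a in enumerate(ids_a):
        A = vol_a == a
        na = int(A.sum())
        if na == 0:
            flagged.append(("a", a))
            continue
        for j, b in enumerate(ids_b):
            B = vol_b == b
            nb = int(B.sum())
            if nb == 0:
                if (("b", b)) not in flagged:
                    flagged.append(("b", b))
                continue
            out[i, j] = 2.0 * int((A & B).sum()) / (na + nb)
    if flagged:
        warnings.warn(f"empty regions get zero Dice rows/columns: {flagged}", stacklevel=2)
    return DiceMatrix(out, ids_a, ids_b)


def mirror_voxels(ijk: np.ndarray, affine: np.ndarray, shape: tuple[int, ...]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Reflect voxel coordinates through the world x = 0 plane.

    Returns the mirrored integer coordinates and a mask of voxels whose
    reflection lands inside the grid. The reflection is an involution for
    every in-grid voxel.
    """
    ijk = np.asarray(ijk)
    hom = np.column_stack([ijk, np.ones(len(ijk))])
    world = hom @ affine.T
    world[:, 0] *= -1
    inv = np.linalg.inv(affine)
    back = world @ inv.T
    mirrored = np.round(back[:, :3]).astype(int)
    in_grid = np.all((mirrored >= 0) & (mirrored < np.array(shape)), axis=1)
    return mirrored, in_grid


def _hemisphere_split(parc: Parcellation):
    """Left-hemisphere labelled voxels with a labelled in-grid mirror.

    Returns (left_labels, right_labels) in mirrored-correspondence order;
    midline voxels (|world x| < half a voxel) are excluded.
    """
    vol = parc.volume
    affine = parc.affine
    ijk = np.argwhere(vol > 0)
    hom = np.column_stack([ijk, np.ones(len(ijk))])
    x_world = (hom @ affine.T)[:, 0]
    half_voxel = 0.5 * np.sqrt((affine[:3, 0] ** 2).sum())
    left = ijk[x_world < -half_voxel]
    right_exists = ijk[x_world > half_voxel]
    if len(left) == 0 or len(right_exists) == 0:
        raise ValueError("all labelled voxels lie in one hemisphere; no mirrored pairs")
    mirrored, in_grid = mirror_voxels(left, affine, vol.shape)
    keep = in_grid.copy()
    keep[in_grid] &= vol[tuple(mirrored[in_grid].T)] > 0
    left = left[keep]
    mirrored = mirrored[keep]
    if len(left) == 0:
        raise ValueError("no mirrored voxel pairs are labelled in both hemispheres")
    left_labels = vol[tuple(left.T)]
    right_labels = vol[tuple(mirrored.T)]
    return left_labels, right_labels


def symmetry_global(parc: Parcellation, chunk: int = 100) -> float:
    """Interhemispheric symmetry score for the whole parcellation in
    [0, 1]: the chunked adjacency Dice between the co-membership matrices
    of the left and (mirrored) right hemisphere labels. Invariant to
    relabeling; 1 for a perfectly mirror-symmetric parcellation."""
    left_labels, right_labels = _hemisphere_split(parc)
    return adjacency_dice(left_labels, right_labels, chunk=chunk)


def symmetry_per_fn(parc: Parcellation) -> DiceMatrix:
    """Dice of every left-restricted network against every mirrored
    right-restricted network; diagonal entries flag self-symmetric
    networks, off-diagonal entries contralateral pairs."""
    left_labels, right_labels = _hemisphere_split(parc)
    ids = list(range(1, parc.K + 1))
    out = np.zeros((parc.K, parc.K))
    flagged = []
    for i, a in enumerate(ids):
        A = left_labels == a
        if not A.any():
            flagged.append(("left", a))
    for j, b in enumerate(ids):
        B = right_labels == b
        if not B.any():
            flagged.append(("right", b))
    for i, a in enumerate(ids):
        A = left_labels == a
        for j, b in enumerate(ids):
            B = right_labels == b
            denom = int(A.sum()) + int(B.sum())
            out[i, j] = 2.0 * int((A & B).sum()) / denom if denom else 0.0
    if flagged:
        warnings.warn(f"networks absent from a hemisphere: {flagged}", stacklevel=2)
    return DiceMatrix(out, ids, ids)
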