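"""Group-level WM and GM mask construction.

The WM mask is stringent (by default every participant must have WM
probability > 0.6 at a voxel) so that no GM signal contaminates the WM
clustering; the GM mask is lenient (>= 20% of participants classify the
voxel as GM) and excludes the WM mask. Subcortical gray structures that
segmentation tends to mislabel as WM (high iron content) can be forced
into the GM mask via a label image. Voxels with no usable signal in more
than 20% of participants are dropped from both masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .images import BoldImage, TissueProbMaps, save_nifti

__all__ = [
    "GroupMask",
    "build_wm_group_mask",
    "build_gm_group_mask",
    "drop_empty_voxels",
]


@dataclass
class GroupMask:
    """A binary mask on the common grid with its raster-ordered voxel list."""

    mask: np.ndarray
    affine: np.ndarray
    tissue: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_indices(self) -> np.ndarray:
        """(N, 3) integer voxel coordinates in raster (C) order."""
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def extract(self, bold: BoldImage) -> np.ndarray:
        """In-mask voxel series as an (N, T) array in raster order."""
        return bold.data[self.mask]

    def save(self, path) -> None:
        save_nifti(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), path)


def _check_grids(tpms: list[TissueProbMaps]) -> None:
    shape = tpms[0].shape
    for i, t in enumerate(tpms):
        if t.shape != shape:
            raise ValueError(f"participant {i} tissue maps are on a different grid {t.shape} vs {shape}")


def build_wm_group_mask(
    tpms: list[TissueProbMaps], prob_thr: float = 0.6, group_pct: float = 100.0
) -> GroupMask:
    """Voxels where at least ``group_pct`` % of participants have WM
    probability strictly above ``prob_thr``."""
    if not tpms:
        raise ValueError("need at least one participant")
    _check_grids(tpms)
    counts = sum((t.wm > prob_thr).astype(int) for t in tpms)
    frac = counts / len(tpms) * 100.0
    mask = frac >= group_pct
    return GroupMask(
        mask,
        tpms[0].affine,
        tissue="WM",
        provenance={"prob_thr": prob_thr, "group_pct": group_pct, "n_participants": len(tpms)},
    )


def build_gm_group_mask(
    tpms: list[TissueProbMaps],
    wm_mask: GroupMask,
    subcortical_labels: np.ndarray | None = None,
    group_pct: float = 20.0,
) -> tuple[GroupMask, GroupMask]:
    """GM group mask, plus the (possibly shrunken) WM mask.

    A voxel enters the GM mask if at least ``group_pct`` % of participants
    classify it as GM (GM the largest of the three tissue probabilities)
    and it is not in the WM mask — or unconditionally if it lies in a
    nonzero voxel of ``subcortical_labels``, in which case it is also
    removed from the WM mask so the two stay disjoint.
    """
    if not tpms:
        raise ValueError("need at least one participant")
    _check_grids(tpms)
    gm_class = sum(
        ((t.gm >= t.wm) & (t.gm >= t.csf) & (t.gm > 0)).astype(int) for t in tpms
    )
    frac = gm_class / len(tpms) * 100.0
    wm = wm_mask.mask.copy()
    gm = (frac >= group_pct) & ~wm
    if subcortical_labels is not None:
        sub = np.asarray(subcortical_labels) != 0
        gm = gm | sub
        wm = wm & ~sub
    new_wm = GroupMask(
        wm, wm_mask.affine, tissue="WM",
        provenance={**wm_mask.provenance, "subcortical_removed": subcortical_labels is not None},
    )
    gm_mask = GroupMask(
        gm, wm_mask.affine, tissue="GM",
        provenance={"group_pct": group_pct, "n_participants": len(tpms),
                    "subcortical_added": subcortical_labels is not None},
    )
    assert not (gm_mask.mask & new_wm.mask).any(), "WM and GM group masks must be disjoint"
    return gm_mask, new_wm


def drop_empty_voxels(
    mask: GroupMask, bolds: list[BoldImage], pct: float = 20.0
) -> GroupMask:
    """Remove voxels whose series carries no signal (all-zero, zero
    variance, or non-finite) in strictly more than ``pct`` % of
    participants."""
    if not bolds:
        raise ValueError("need at least one participant")
    bad_counts = np.zeros(mask.mask.shape, dtype=int)
    for bold in bolds:
        if bold.data.shape[:3] != mask.mask.shape:
            raise ValueError("BOLD grid does not match the group mask")
        series = bold.data[mask.mask]  # (N, T)
        bad = (~np.isfinite(series)).any(axis=1) | (series.std(axis=1) == 0)
        bad_counts[mask.mask] += bad.astype(int)
    frac = bad_counts / len(bolds) * 100.0
    keep = mask.mask & ~(frac > pct)
    return GroupMask(
        keep, mask.affine, tissue=mask.tissue,
        provenance={**mask.provenance, "empty_voxel_pct": pct,
                    "n_dropped": int(mask.mask.sum() - keep.sum())},
    )
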