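"""Functional-network construction by correlation-distance K-means.

Each in-mask voxel is represented by its functional-connectivity profile
(Pearson correlation with a deterministic subsample of mask voxels),
aggregated across participants by Fisher-z averaging. Rows of the
resulting N x Ns matrix are the data points, columns the features, and
K-means with correlation distance (1 - Pearson r between a row and a
centroid) groups the voxels into K functional networks.

The number of networks K is chosen by a stability cross-validation: the
feature set is split into ncv interleaved folds, each fold is clustered
independently, and fold agreement is scored by the Dice coefficient
between chunked co-membership (adjacency) matrices. Stable K values show
up as local peaks of the mean Dice curve; the K-means distortion (mean
correlation distance of each point to its centroid) provides the usual
elbow diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import nibabel as nib
import numpy as np
import pandas as pd

from .images import BoldImage, save_nifti
from .group_masks import GroupMask

__all__ = [
    "GroupFCMatrix",
    "Parcellation",
    "KScanResult",
    "build_group_fc",
    "kmeans_networks",
    "correlation_kmeans",
    "adjacency_dice",
    "crossval_k_scan",
]

Z_CLIP = 1.0 - 1e-7


@dataclass
class GroupFCMatrix:
    """Group-averaged voxel FC features: rows = all N mask voxels, columns
    = the Ns stride-subsampled voxels."""

    matrix: np.ndarray
    col_indices: np.ndarray
    stride: int
    note: str = ""

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Parcellation:
    """Integer voxel labels 1..K over a group mask (0 = background)."""

    labels: np.ndarray
    K: int
    mask: GroupMask | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError("labels must lie in 1..K")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    @property
    def volume(self) -> np.ndarray:
        if self.mask is None:
            raise ValueError("parcellation has no mask geometry")
        vol = np.zeros(self.mask.mask.shape, dtype=np.int16)
        vol[self.mask.mask] = self.labels
        return vol

    @property
    def affine(self) -> np.ndarray:
        if self.mask is None:
            raise ValueError("parcellation has no mask geometry")
        return self.mask.affine

    def save(self, path) -> None:
        save_nifti(nib.Nifti1Image(self.volume, self.affine), path)

    @classmethod
    def from_volume(cls, volume: np.ndarray, affine: np.ndarray,
                    tissue: str = "WM") -> "Parcellation":
        volume = np.asarray(volume, dtype=int)
        mask = GroupMask(volume > 0, affine, tissue=tissue)
        labels = volume[mask.mask]
        return cls(labels=labels, K=int(volume.max()), mask=mask)


@dataclass
class KScanResult:
    """Per-K clustering stability (mean adjacency Dice) and distortion."""

    table: pd.DataFrame  # columns: K, mean_dice, distortion
    params: dict = field(default_factory=dict)

    def candidate_ks(self) -> list[int]:
        """K values at local maxima of the mean Dice curve.

        Plateaus count once: a run of equal Dice values that beats the
        distinct values on both sides is reported at its largest K (the
        most detailed parcellation sustaining that stability). Endpoints
        qualify when they beat their single neighbour.
        """
        d = self.table["mean_dice"].to_numpy()
        ks = self.table["K"].to_numpy()
        out = []
        i = 0
        while i < len(d):
            j = i
            while j + 1 < len(d) and d[j + 1] == d[i]:
                j += 1
            left_ok = i == 0 or d[i] > d[i - 1]
            right_ok = j == len(d) - 1 or d[j] > d[j + 1]
            if left_ok and right_ok:
                out.append(int(ks[j]))
            i = j + 1
        return out

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm; zero-variance rows -> 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = np.where(norms > 0, Xc / np.where(norms == 0, 1.0, norms), 0.0)
    return Xn


def build_group_fc(
    bolds: list[BoldImage],
    mask: GroupMask,
    stride: int | str = "auto",
    memory_budget_bytes: int = 2 * 1024**3,
) -> GroupFCMatrix:
    """Group FC feature matrix over the mask voxels.

    Per participant, every mask voxel's series is Pearson-correlated with
    every stride-th mask voxel's series (columns chosen deterministically
    as raster indices 0, stride, 2*stride, ...). The per-participant
    matrices are Fisher-z transformed, averaged, and transformed back.
    ``stride='auto'`` keeps the full N x N matrix when it fits the memory
    budget, otherwise falls back to 2 for WM and 3 for GM.
    """
    if not bolds:
        raise ValueError("need at least one participant")
    N = mask.n_voxels
    if N == 0:
        raise ValueError("empty group mask")
    if stride == "auto":
        if N * N * 8 <= memory_budget_bytes:
            stride = 1
        else:
            stride = 2 if mask.tissue.upper() == "WM" else 3
    stride = int(stride)
    cols = np.arange(0, N, stride)
    zsum = np.zeros((N, len(cols)))
    for bold in bolds:
        series = mask.extract(bold)  # (N, T)
        T = series.shape[1]
        Xn = _standardize_rows(series)
        degenerate = (Xn == 0).all(axis=1)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance voxel series; their correlations set to 0",
                stacklevel=2,
            )
        r = Xn @ Xn[cols].T
        np.clip(r, -Z_CLIP, Z_CLIP, out=r)
        zsum += np.arctanh(r)
    group_r = np.tanh(zsum / len(bolds))
    return GroupFCMatrix(
        matrix=group_r, col_indices=cols, stride=stride,
        note=f"Fisher-z average of {len(bolds)} participants",
    )


class _EmptyCluster(RuntimeError):
    pass


def _kmeanspp_init(Xn: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under correlation distance (rows pre-normalised)."""
    n = Xn.shape[0]
    centers = np.empty((K, Xn.shape[1]))
    idx = rng.integers(n)
    centers[0] = Xn[idx]
    d = 1.0 - Xn @ centers[0]
    d = np.maximum(d, 0.0)
    for k in range(1, K):
        total = d.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d / total)
        centers[k] = Xn[idx]
        d = np.minimum(d, np.maximum(1.0 - Xn @ centers[k], 0.0))
    return centers


def correlation_kmeans(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int = 200,
) -> tuple[np.ndarray, float]:
    """One Lloyd run of K-means with correlation distance.

    Rows are centred and scaled to unit norm, so 1 - r equals half the
    squared Euclidean distance; centroids are re-standardised after each
    update (the standard 'correlation' K-means variant). Returns 0-based
    labels and the distortion (mean distance of points to their centroid).
    Raises ``_EmptyCluster`` if a cluster empties out.
    """
    Xn = _standardize_rows(np.asarray(X, dtype=float))
    n = Xn.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"need 1 <= K <= {n}, got K={K}")
    C = _standardize_rows(_kmeanspp_init(Xn, K, rng))
    labels = np.full(n, -1)
    for _ in range(max_iter):
        sims = Xn @ C.T
        new_labels = np.argmax(sims, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(K):
            members = Xn[labels == k]
            if members.shape[0] == 0:
                raise _EmptyCluster(f"cluster {k} emptied")
            C[k] = members.mean(axis=0)
        C = _standardize_rows(C)
    dists = 1.0 - (Xn @ C.T)[np.arange(n), labels]
    return labels, float(np.mean(np.maximum(dists, 0.0)))


def _best_of_reps(
    X: np.ndarray, K: int, reps: int, seed_seq: np.random.SeedSequence,
    retry_cap: int = 5,
) -> tuple[np.ndarray, float]:
    best_labels, best_dist = None, np.inf
    children = seed_seq.spawn(reps)
    for child in children:
        rng = np.random.default_rng(child)
        for _attempt in range(retry_cap):
            try:
                labels, dist = correlation_kmeans(X, K, rng)
                break
            except _EmptyCluster:
                continue
        else:
            raise RuntimeError(f"K-means failed to keep {K} non-empty clusters after {retry_cap} retries")
        if dist < best_dist:
            best_labels, best_dist = labels, dist
    return best_labels, best_dist


def kmeans_networks(
    fc: GroupFCMatrix,
    K: int,
    reps: int = 10,
    seed: int | None = None,
    mask: GroupMask | None = None,
) -> tuple[Parcellation, float]:
    """Cluster the FC rows into K functional networks.

    Runs ``reps`` seeded k-means++ initialisations and keeps the solution
    with the smallest distortion. Labels are reported 1..K.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > fc.n_voxels:
        raise ValueError(f"K={K} exceeds the number of voxels {fc.n_voxels}")
    labels, dist = _best_of_reps(fc.matrix, K, reps, np.random.SeedSequence(seed))
    return Parcellation(labels=labels + 1, K=K, mask=mask), dist


def adjacency_dice(
    labels_a: np.ndarray, labels_b: np.ndarray, chunk: int = 100
) -> float:
    """Dice agreement between the co-membership structures of two
    labelings, computed over contiguous voxel chunks.

    For each chunk the within-chunk adjacency matrices (1 where two voxels
    share a cluster; diagonal excluded) are compared by Dice; the mean over
    chunks is returned. A chunk with no co-membership in either labeling
    scores 1 (perfect agreement on "nothing co-clustered"). Invariant to
    relabeling either input.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be equal-length 1D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 voxels")
    dices = []
    for start in range(0, n, chunk):
        ca = a[start : start + chunk]
        cb = b[start : start + chunk]
        if ca.size < 2:
            continue
        A = ca[:, None] == ca[None, :]
        B = cb[:, None] == cb[None, :]
        np.fill_diagonal(A, False)
        np.fill_diagonal(B, False)
        sa = int(A.sum())
        sb = int(B.sum())
        if sa + sb == 0:
            dices.append(1.0)
        else:
            dices.append(2.0 * int((A & B).sum()) / (sa + sb))
    return float(np.mean(dices))


def crossval_k_scan(
    fc: GroupFCMatrix,
    k_range: range | list[int] = range(2, 23),
    ncv: int = 4,
    chunk: int = 100,
    reps: int = 10,
    seed: int | None = None,
) -> KScanResult:
    """Stability scan over K.

    Features are partitioned into ``ncv`` interleaved folds (feature j ->
    fold j mod ncv); for every K each fold matrix is clustered
    independently and all fold pairs are scored with the chunked adjacency
    Dice. The distortion column comes from a full-feature clustering at
    each K.
    """
    if ncv < 2:
        raise ValueError("ncv must be at least 2")
    if fc.n_features < 2 * ncv:
        raise ValueError(f"need at least {2 * ncv} features for {ncv} folds")
    ks = list(k_range)
    fold_cols = [np.arange(fc.n_features) % ncv == f for f in range(ncv)]
    root = np.random.SeedSequence(seed)
    rows = []
    for K in ks:
        # every fold at a given K reuses the same seeded initial conditions,
        # so identical fold inputs yield identical clusterings and fold
        # disagreement reflects the data, not the initialisation
        fold_labels = []
        for f in range(ncv):
            sub = fc.matrix[:, fold_cols[f]]
            labels, _ = _best_of_reps(sub, K, reps, np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(K, 0)))
            fold_labels.append(labels)
        dices = [
            adjacency_dice(fold_labels[i], fold_labels[j], chunk=chunk)
            for i, j in combinations(range(ncv), 2)
        ]
        _, distortion = _best_of_reps(
            fc.matrix, K, reps, np.random.SeedSequence(entropy=root.entropy, spawn_key=(K, 1))
        )
        rows.append({"K": K, "mean_dice": float(np.mean(dices)), "distortion": distortion})
    table = pd.DataFrame(rows)
    return KScanResult(
        table=table,
        params={"k_range": ks, "ncv": ncv, "chunk": chunk, "reps": reps, "seed": seed},
    )
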