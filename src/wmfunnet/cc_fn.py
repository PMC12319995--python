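"""Corpus-callosum sub-parcellation by connectivity to WM networks.

Each corpus-callosum voxel is partially correlated with every WM
functional network's average time series, controlling for the other K-1
network series. The partial correlations are Fisher-z transformed per
participant, a one-sample t-statistic across participants is computed per
(voxel, network), and each voxel is assigned to the network with the
maximal t (winner take all).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CCAssignment", "partial_correlation", "assign_cc_voxels"]

Z_CLIP = 1.0 - 1e-7


def partial_correlation(x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None) -> float:
    """Partial Pearson correlation of ``x`` and ``y`` controlling for the
    columns of ``Z``: the correlation of their OLS residuals against
    [intercept, Z]. A zero-variance residual yields 0 with a warning."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    T = x.size
    if y.size != T:
        raise ValueError("series length mismatch")
    if Z is None or (hasattr(Z, "size") and Z.size == 0):
        D = np.ones((T, 1))
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != T:
            raise ValueError("control series length mismatch")
        if T <= Z.shape[1] + 2:
            raise ValueError("too few time points for the number of controls")
        D = np.column_stack([np.ones(T), Z])
    targets = np.column_stack([x, y])
    coef, *_ = np.linalg.lstsq(D, targets, rcond=None)
    resid = targets - D @ coef
    sx, sy = np.linalg.norm(resid, axis=0)
    # residual norm tiny relative to the input scale -> fully explained by Z
    scale = np.linalg.norm(targets - targets.mean(axis=0), axis=0)
    degenerate = (sx <= 1e-8 * max(scale[0], 1e-300)) or (sy <= 1e-8 * max(scale[1], 1e-300))
    if degenerate:
        warnings.warn("degenerate (zero-variance) residual in partial correlation", stacklevel=2)
        return 0.0
    return float(resid[:, 0] @ resid[:, 1] / (sx * sy))


@dataclass
class CCAssignment:
    """Winner-take-all labels over CC voxels with the per-network t-maps."""

    labels: np.ndarray  # (n_cc,), values 1..K
    t: np.ndarray  # (n_cc, K)
    n_participants: int
    z: np.ndarray | None = None  # (n_participants, n_cc, K) Fisher-z maps

    def __post_init__(self) -> None:
        assert self.labels.shape[0] == self.t.shape[0]
        # each voxel's label points at the row-maximal t
        row_max = np.nanmax(self.t, axis=1)
        chosen = self.t[np.arange(len(self.labels)), self.labels - 1]
        assert np.all((chosen == row_max) | ~np.isfinite(row_max))

    @property
    def K(self) -> int:
        return self.t.shape[1]


def assign_cc_voxels(
    cc_series: np.ndarray,
    fn_series: np.ndarray,
    keep_z: bool = False,
) -> CCAssignment:
    """Assign CC voxels to WM networks.

    Parameters
    ----------
    cc_series : (n_participants, n_cc_voxels, T)
        Per-participant time series of each CC voxel. The CC voxels must
        have been removed from the WM mask before the network average
        series were computed.
    fn_series : (n_participants, K, T)
        Per-participant average series of each WM network.

    For every participant, voxel v and network k, r(v, k) is the partial
    correlation of the voxel series with network k's series controlling
    for the other K-1 networks; z = atanh(r) (clipped); t(v, k) is the
    one-sample t across participants; the label is argmax_k t with ties
    going to the smallest k.
    """
    cc_series = np.asarray(cc_series, dtype=float)
    fn_series = np.asarray(fn_series, dtype=float)
    if cc_series.ndim != 3 or fn_series.ndim != 3:
        raise ValueError("expected (participants, voxels, T) and (participants, K, T) arrays")
    P, n_cc, T = cc_series.shape
    Pf, K, Tf = fn_series.shape
    if P != Pf or T != Tf:
        raise ValueError("participant count / series length mismatch between CC and FN series")
    if P < 3:
        raise ValueError("one-sample t across participants needs at least 3 participants")
    if K < 2:
        raise ValueError("need at least 2 networks")

    z = np.empty((P, n_cc, K))
    for p in range(P):
        fns = fn_series[p]  # (K, T)
        vox = cc_series[p]  # (n_cc, T)
        for k in range(K):
            controls = np.delete(fns, k, axis=0).T  # (T, K-1)
            D = np.column_stack([np.ones(T), controls])
            # residualise the target network and all voxel series in one solve
            targets = np.vstack([fns[k][None, :], vox]).T  # (T, 1 + n_cc)
            coef, *_ = np.linalg.lstsq(D, targets, rcond=None)
            resid = targets - D @ coef
            ry = resid[:, 0]
            rx = resid[:, 1:]
            ny = np.linalg.norm(ry)
            nx = np.linalg.norm(rx, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (rx.T @ ry) / np.where(nx * ny == 0, 1.0, nx * ny)
            r[(nx == 0) | (ny == 0)] = 0.0
            z[p, :, k] = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))

    zbar = z.mean(axis=0)
    zsd = z.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = zbar / (zsd / np.sqrt(P))
    # identical z across participants: sd 0 -> +/- inf by the sign of the mean, 0 for zero mean
    degen = zsd == 0
    t[degen] = np.sign(zbar[degen]) * np.inf
    t[degen & (zbar == 0)] = 0.0
    labels = np.argmax(t, axis=1) + 1  # argmax breaks ties at the smallest index
    return CCAssignment(labels=labels, t=t, n_participants=P, z=z if keep_z else None)
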