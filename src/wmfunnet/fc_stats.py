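"""Region time series, FC matrices, and edge-wise group statistics.

Average time series are extracted per functional network (or atlas ROI),
optionally re-filtered into narrower frequency bands. Pearson FC matrices
are computed per participant, and each FC edge is fitted with an ordinary
least-squares model against participant covariates; the named predictor's
t and two-sided p are corrected across edges by Benjamini-Hochberg FDR or
Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .denoise import bandpass_series
from .images import BoldImage

__all__ = [
    "TimeSeriesSet",
    "EdgeStats",
    "extract_avg_ts",
    "extract_avg_ts_set",
    "band_filtered_ts",
    "fc_matrix",
    "edge_glm",
    "correct_multiple",
]

Z_CLIP = 1.0 - 1e-7


@dataclass
class TimeSeriesSet:
    """Region-average series for a cohort: (participants, regions, T)."""

    data: np.ndarray
    region_ids: list
    tr: float
    band: tuple[float, float] | None = None
    participant_ids: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (participants, regions, T)")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite entries in time series")
        if self.data.shape[1] != len(self.region_ids):
            raise ValueError("region id / data mismatch")

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def extract_avg_ts(bold: BoldImage, label_volume: np.ndarray,
                   region_ids: list[int] | None = None) -> tuple[np.ndarray, list[int]]:
    """Unweighted mean series per labelled region.

    Returns ``(series, flagged)`` where ``series`` is (n_regions, T) in
    ascending label order (or the order of ``region_ids``) and ``flagged``
    lists empty regions (their series are zero).
    """
    label_volume = np.asarray(label_volume)
    if label_volume.shape != bold.data.shape[:3]:
        raise ValueError("parcellation grid does not match the BOLD grid")
    if region_ids is None:
        region_ids = [int(v) for v in np.unique(label_volume) if v != 0]
    if not region_ids:
        raise ValueError("no labelled regions overlap the BOLD image")
    out = np.zeros((len(region_ids), bold.n_volumes))
    flagged = []
    for i, rid in enumerate(region_ids):
        members = label_volume == rid
        if not members.any():
            flagged.append(rid)
            continue
        out[i] = bold.data[members].mean(axis=0)
    if flagged:
        warnings.warn(f"empty regions (zero series): {flagged}", stacklevel=2)
    return out, flagged


def extract_avg_ts_set(
    bolds: list[BoldImage],
    label_volume: np.ndarray,
    participant_ids: list | None = None,
) -> TimeSeriesSet:
    """Stack per-participant region averages into one TimeSeriesSet."""
    region_ids = [int(v) for v in np.unique(np.asarray(label_volume)) if v != 0]
    series = np.stack([extract_avg_ts(b, label_volume, region_ids)[0] for b in bolds])
    return TimeSeriesSet(series, region_ids, tr=bolds[0].tr, participant_ids=participant_ids)


def band_filtered_ts(ts: TimeSeriesSet, bands: list[tuple[float, float]]) -> list[TimeSeriesSet]:
    """Re-filter the region series into each requested band."""
    out = []
    for low, high in bands:
        filtered = bandpass_series(ts.data, ts.tr, low, high, axis=2)
        out.append(TimeSeriesSet(filtered, ts.region_ids, ts.tr, band=(low, high),
                                 participant_ids=ts.participant_ids))
    return out


def fc_matrix(ts_a: TimeSeriesSet, ts_b: TimeSeriesSet | None = None) -> np.ndarray:
    """Per-participant Pearson FC.

    Square (participants, R, R) when ``ts_b`` is None — symmetric with a
    unit diagonal — else rectangular (participants, Ra, Rb). Zero-variance
    regions get zero correlations (flagged by warning).
    """
    A = ts_a.data
    square = ts_b is None
    B = A if square else ts_b.data
    if B.shape[0] != A.shape[0] or B.shape[2] != A.shape[2]:
        raise ValueError("participant count / series length mismatch")
    P = A.shape[0]
    out = np.empty((P, A.shape[1], B.shape[1]))
    n_degenerate = 0
    for p in range(P):
        Xa = _std_rows(A[p])
        Xb = Xa if square else _std_rows(B[p])
        n_degenerate += int((Xa == 0).all(axis=1).sum())
        r = Xa @ Xb.T
        np.clip(r, -1.0, 1.0, out=r)
        if square:
            r = (r + r.T) / 2.0
            np.fill_diagonal(r, 1.0)
        out[p] = r
    if n_degenerate:
        warnings.warn(f"{n_degenerate} zero-variance region series; correlations set to 0",
                      stacklevel=2)
    return out


def _std_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    return np.where(norms > 0, Xc / np.where(norms == 0, 1.0, norms), 0.0)


@dataclass
class EdgeStats:
    """Edge-wise GLM results with multiple-comparison correction."""

    table: pd.DataFrame  # row_region, col_region, beta, t, p, q, significant
    predictor: str
    n_total: int
    alpha: float
    method: str
    alpha_corrected: float | None = None
    params: dict = field(default_factory=dict)

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)


def _edge_index(n_rows: int, n_cols: int, square: bool) -> tuple[np.ndarray, np.ndarray]:
    if square:
        iu = np.triu_indices(n_rows, k=1)
        return iu
    ii, jj = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return ii.ravel(), jj.ravel()


def edge_glm(
    fc_stack: np.ndarray,
    covariates: pd.DataFrame,
    predictor: str,
    participant_ids: list | None = None,
    square: bool | None = None,
    fisher_z: bool = True,
    method: str = "fdr",
    alpha: float = 0.05,
    row_ids: list | None = None,
    col_ids: list | None = None,
) -> EdgeStats:
    """Fit every FC edge against the participant covariates.

    ``fc_stack`` is (participants, R1, R2); the first column of
    ``covariates`` is the participant identifier and all remaining columns
    enter the design (plus an intercept). The t and two-sided p of the
    ``predictor`` coefficient are reported per edge, with FDR (BH) or
    Bonferroni correction across edges. Square symmetric stacks use the
    strict upper triangle (n(n-1)/2 edges); rectangular stacks all cells.
    FC values are Fisher-z transformed before fitting by default.
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    if fc_stack.ndim != 3:
        raise ValueError("fc_stack must be (participants, rows, cols)")
    P, n_rows, n_cols = fc_stack.shape
    if square is None:
        square = n_rows == n_cols and np.allclose(fc_stack, np.swapaxes(fc_stack, 1, 2))

    id_col = covariates.columns[0]
    cov = covariates.set_index(id_col)
    if participant_ids is not None:
        missing = [i for i in participant_ids if i not in cov.index]
        if missing:
            raise ValueError(f"participants missing from the covariates table: {missing}")
        cov = cov.loc[participant_ids]
    if len(cov) != P:
        raise ValueError(f"covariates rows ({len(cov)}) != participants in FC stack ({P})")
    if predictor not in cov.columns:
        raise ValueError(f"predictor {predictor!r} not among covariates {list(cov.columns)}")

    X = np.column_stack([np.ones(P), cov.to_numpy(dtype=float)])
    names = ["intercept", *cov.columns]
    if np.std(cov[predictor].to_numpy(dtype=float)) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank-deficient (collinear columns)")

    ii, jj = _edge_index(n_rows, n_cols, square)
    Y = fc_stack[:, ii, jj]  # (P, n_edges)
    if fisher_z:
        Y = np.arctanh(np.clip(Y, -Z_CLIP, Z_CLIP))
    n_edges = Y.shape[1]

    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, n_edges)
    resid = Y - X @ beta
    dof = P - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough participants for the design")
    sigma2 = (resid**2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    j = names.index(predictor)
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[j] / se
    t = np.where(se == 0, 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), dof)

    qc = correct_multiple(p, method=method, alpha=alpha, n_total=n_edges)
    row_ids = row_ids if row_ids is not None else list(range(1, n_rows + 1))
    col_ids = col_ids if col_ids is not None else list(range(1, n_cols + 1))
    table = pd.DataFrame({
        "row_region": [row_ids[i] for i in ii],
        "col_region": [col_ids[i] for i in jj],
        "beta": beta[j],
        "t": t,
        "p": p,
        "q": qc["q"] if qc["q"] is not None else np.nan,
        "significant": qc["significant"],
    })
    return EdgeStats(
        table=table, predictor=predictor, n_total=n_edges, alpha=alpha, method=method,
        alpha_corrected=qc["alpha_corrected"],
        params={"fisher_z": fisher_z, "dof": dof, "design_columns": names, "square": square},
    )


def correct_multiple(
    p: np.ndarray, method: str = "fdr", alpha: float = 0.05, n_total: int | None = None
) -> dict:
    """Multiple-comparison correction across edges.

    ``fdr`` returns Benjamini-Hochberg step-up adjusted q-values
    (significant iff q <= alpha); ``bonferroni`` returns
    alpha_corrected = alpha / n_total (significant iff p <= alpha_corrected).
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if n_total is None:
        n_total = p.size
    if method == "fdr":
        # Benjamini-Hochberg step-up: q_(i) = min_{j >= i} p_(j) * m / j
        m = p.size
        order = np.argsort(p, kind="stable")
        q_sorted = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, p[order[i]] * m / (i + 1))
            q_sorted[i] = running
        q = np.empty(m)
        q[order] = q_sorted
        return {"q": q, "significant": q <= alpha, "alpha_corrected": None}
    if method == "bonferroni":
        alpha_corrected = alpha / n_total
        return {"q": None, "significant": p <= alpha_corrected, "alpha_corrected": alpha_corrected}
    raise ValueError(f"unknown correction method {method!r}")
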