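"""Head-motion quality control.

Framewise displacement (FD) summarises rigid-body realignment parameters as
a per-volume scalar: the absolute backward differences of the three
translations (mm) plus the three rotation differences converted to mm as
arc length on a sphere of radius 50 mm. Participants are excluded by three
independent rules on the FD trace (maximum, mean, and fraction of volumes
above a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import BoldImage

__all__ = [
    "load_motion_params",
    "FDTrace",
    "ExclusionDecision",
    "compute_fd",
    "apply_motion_exclusion",
    "exclusion_grid",
    "pairwise_variance",
    "qc_signal_report",
]

MOTION_COLUMNS = ("tx", "ty", "tz", "pitch", "roll", "yaw")

#: Default exclusion thresholds: max FD 5 mm, mean FD 0.2 mm, and no more
#: than 20% of volumes above 0.2 mm.
DEFAULT_THRESHOLDS = {"max": 5.0, "mean": 0.2, "frac_threshold": 0.2, "frac_limit": 0.2}


def load_motion_params(path: str | Path) -> np.ndarray:
    """Read a realignment-parameter text file (6 whitespace-separated
    columns: translations in mm, rotations in radians; one row per volume)."""
    params = np.loadtxt(str(path), ndmin=2)
    if params.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 motion columns (tx ty tz pitch roll yaw), got {params.shape[1]}"
        )
    return params


@dataclass
class FDTrace:
    """Per-volume framewise displacement with its summary statistics."""

    fd: np.ndarray
    head_radius: float
    frac_threshold: float = 0.2

    @property
    def max_fd(self) -> float:
        return float(np.max(self.fd))

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd))

    @property
    def frac_above(self) -> float:
        return float(np.mean(self.fd > self.frac_threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"volume_index": np.arange(len(self.fd)), "fd_mm": self.fd})


@dataclass
class ExclusionDecision:
    excluded: bool
    reasons: set[str]
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.excluded == bool(self.reasons)


def compute_fd(motion: np.ndarray, head_radius: float = 50.0, frac_threshold: float = 0.2) -> FDTrace:
    """Framewise displacement from a T x 6 rigid-body parameter table.

    fd[t] = |dtx| + |dty| + |dtz| + r * (|dpitch| + |droll| + |dyaw|)
    with backward differences and fd[0] = 0; rotations (radians) are scaled
    by the head radius ``r`` (mm) to an arc length.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be T x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("at least 2 volumes are required to compute FD")
    bad = ~np.isfinite(motion)
    if bad.any():
        row = int(np.nonzero(bad.any(axis=1))[0][0])
        raise ValueError(f"non-finite motion parameter at row {row}")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + head_radius * diffs[:, 3:].sum(axis=1)
    return FDTrace(fd=fd, head_radius=head_radius, frac_threshold=frac_threshold)


def apply_motion_exclusion(fd: FDTrace, thresholds: dict[str, float] | None = None) -> ExclusionDecision:
    """Apply the three exclusion rules, each with a strict ``>`` comparison.

    A participant is excluded if max FD > ``max`` (mm), mean FD > ``mean``
    (mm), or the fraction of volumes with FD > ``frac_threshold`` exceeds
    ``frac_limit``. All triggered reasons are reported.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    reasons: set[str] = set()
    if fd.max_fd > thr["max"]:
        reasons.add("max_fd")
    if fd.mean_fd > thr["mean"]:
        reasons.add("mean_fd")
    frac = float(np.mean(fd.fd > thr["frac_threshold"]))
    if frac > thr["frac_limit"]:
        reasons.add("frac_above")
    return ExclusionDecision(excluded=bool(reasons), reasons=reasons, thresholds=thr)


def exclusion_grid(
    fd_traces: dict[str, FDTrace],
    max_grid: np.ndarray | list[float] = (1, 2, 3, 4, 5, 6),
    mean_grid: np.ndarray | list[float] = (0.1, 0.15, 0.2, 0.25, 0.3),
) -> pd.DataFrame:
    """Number of participants rejected over a grid of thresholds.

    A non-interactive replacement for threshold exploration: each row gives
    a (max, mean) threshold pair and the count of participants that the
    three rules would exclude at those settings.
    """
    rows = []
    for mx in max_grid:
        for mn in mean_grid:
            thr = {"max": float(mx), "mean": float(mn)}
            n = sum(apply_motion_exclusion(t, thr).excluded for t in fd_traces.values())
            rows.append({"max_fd_mm": float(mx), "mean_fd_mm": float(mn), "n_excluded": n})
    return pd.DataFrame(rows)


def pairwise_variance(bold: BoldImage, mask: np.ndarray | None = None) -> np.ndarray:
    """DVARS-like series: variance over in-mask voxels of the difference
    between consecutive volumes; entry 0 is 0 by convention."""
    if bold.n_volumes < 2:
        raise ValueError("pairwise variance requires at least 2 volumes")
    if mask is None:
        mask = np.any(bold.data != 0, axis=3)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    series = bold.data[mask]  # (n_vox, T)
    diffs = np.diff(series, axis=1)
    out = np.zeros(bold.n_volumes)
    out[1:] = diffs.var(axis=0)
    return out


def qc_signal_report(
    raw_global: np.ndarray,
    motion: np.ndarray,
    nuisance: np.ndarray | None,
    clean_global: np.ndarray,
    out_prefix: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix among QC signals.

    Columns: raw global mean, the 6 motion parameters, any nuisance
    regressors, and the cleaned global mean. Zero-variance series get a
    zero correlation row/column and are flagged. With ``out_prefix`` the
    matrix is saved as CSV and as a heat-map figure.
    """
    cols: dict[str, np.ndarray] = {"raw_global": np.asarray(raw_global, dtype=float)}
    motion = np.asarray(motion, dtype=float)
    for i, name in enumerate(MOTION_COLUMNS):
        cols[name] = motion[:, i]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != len(raw_global):
            nuisance = nuisance.T
        for i in range(nuisance.shape[1]):
            cols[f"nuisance{i + 1:02d}"] = nuisance[:, i]
    cols["clean_global"] = np.asarray(clean_global, dtype=float)
    lengths = {len(v) for v in cols.values()}
    if len(lengths) != 1:
        raise ValueError(f"QC series have mismatched lengths: {sorted(lengths)}")

    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    sd = X.std(axis=0)
    flagged = [names[i] for i in np.nonzero(sd == 0)[0]]
    Xc = X - X.mean(axis=0)
    Xn = Xc / np.where(sd == 0, 1.0, sd)
    corr = (Xn.T @ Xn) / len(X)
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=names, columns=names)
    if flagged:
        warnings.warn(f"zero-variance QC series: {flagged}", stacklevel=2)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        df.to_csv(out_prefix.with_suffix(".csv"))
        _save_corr_figure(df, out_prefix.with_suffix(".png"))
    return df, flagged


def _save_corr_figure(df: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(df) + 2, 0.5 * len(df) + 1.5))
    im = ax.imshow(df.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(df)), df.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
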