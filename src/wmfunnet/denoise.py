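"""Temporal denoising and tissue-separated spatial smoothing.

The denoising chain, applied in order: discard initial volumes (scanner
magnetisation settling), regress out nuisance signals (the Friston-24
motion expansion plus CSF signals), band-pass filter each voxel series with
a second-order zero-phase Butterworth filter, and finally smooth the gray
and white matter compartments separately so that GM and WM signals do not
mix across the tissue boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .images import BoldImage, TissueProbMaps

__all__ = [
    "NuisanceDesign",
    "discard_initial",
    "build_csf_mask",
    "extract_csf_regressors",
    "friston24",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass",
    "bandpass_series",
    "smooth_by_tissue",
    "tissue_assignment",
    "preprocess",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceDesign:
    """A T x p regression design; always carries an intercept column."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix / label mismatch")
        if "intercept" not in self.labels:
            raise ValueError("design must include an intercept column")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def degenerate_columns(self) -> list[str]:
        sd = self.matrix.std(axis=0)
        return [
            lab
            for lab, s in zip(self.labels, sd)
            if lab != "intercept" and (s == 0 or not np.isfinite(s))
        ]


def discard_initial(bold: BoldImage, n: int = 10) -> BoldImage:
    """Drop the first ``n`` volumes; TR and affine are preserved."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= bold.n_volumes:
        raise ValueError(f"cannot discard {n} of {bold.n_volumes} volumes")
    if n == 0:
        return bold
    return bold.with_data(bold.data[..., n:])


def build_csf_mask(tpm: TissueProbMaps, threshold: float = 0.95) -> tuple[np.ndarray, bool]:
    """Binary CSF mask: voxels with CSF probability strictly above
    ``threshold``. Returns ``(mask, flagged)`` where ``flagged`` marks an
    empty mask (the participant's segmentation should be re-checked)."""
    mask = tpm.csf > threshold
    flagged = not bool(mask.any())
    if flagged:
        warnings.warn(
            f"no voxel exceeds the CSF probability threshold {threshold}; participant flagged",
            stacklevel=2,
        )
    return mask, flagged


def extract_csf_regressors(
    bold: BoldImage, csf_mask: np.ndarray, mode: str = "mean", k: int = 5
) -> np.ndarray:
    """CSF nuisance regressors: the mask-average series (``mean``, default),
    the first ``k`` principal-component score series (``pca``), or none.

    PCA is run on the T x n_mask matrix of demeaned CSF voxel series;
    components are ordered by decreasing explained variance and their sign
    fixed so the largest-magnitude spatial loading is positive.
    """
    T = bold.n_volumes
    if mode == "none":
        return np.empty((T, 0))
    csf_mask = np.asarray(csf_mask, dtype=bool)
    n_vox = int(csf_mask.sum())
    if n_vox == 0:
        raise ValueError("CSF mask is empty")
    series = bold.data[csf_mask].T  # (T, n_vox)
    if mode == "mean":
        return series.mean(axis=1, keepdims=True)
    if mode == "pca":
        if n_vox < k:
            raise ValueError(f"PCA mode needs >= {k} CSF voxels, mask has {n_vox}")
        X = series - series.mean(axis=0)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        scores = U[:, :k] * s[:k]
        for j in range(k):
            i_max = np.argmax(np.abs(Vt[j]))
            if Vt[j, i_max] < 0:
                scores[:, j] *= -1
        return scores
    raise ValueError(f"unknown CSF mode {mode!r}")


def friston24(motion: np.ndarray) -> np.ndarray:
    """The 24-parameter motion expansion: the 6 rigid-body parameters,
    their squares, their backward-difference derivatives (first row 0), and
    the squared derivatives — in that column order."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be T x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("at least 2 volumes required")
    deriv = np.zeros_like(motion)
    deriv[1:] = np.diff(motion, axis=0)
    return np.column_stack([motion, motion**2, deriv, deriv**2])


def build_nuisance_design(
    motion: np.ndarray | None, csf: np.ndarray | None
) -> NuisanceDesign:
    """Assemble intercept + Friston-24 + CSF regressors into one design."""
    blocks = []
    labels: list[str] = []
    T = None
    if motion is not None:
        f24 = friston24(motion)
        blocks.append(f24)
        labels += [f"friston{i + 1:02d}" for i in range(24)]
        T = f24.shape[0]
    if csf is not None and csf.size:
        csf = np.atleast_2d(np.asarray(csf, dtype=float))
        if csf.shape[0] == 1:
            csf = csf.T
        blocks.append(csf)
        labels += (
            ["csf_mean"] if csf.shape[1] == 1 else [f"csf_pc{i + 1}" for i in range(csf.shape[1])]
        )
        T = csf.shape[0] if T is None else T
    if T is None:
        raise ValueError("no regressors supplied")
    blocks.append(np.ones((T, 1)))
    labels.append("intercept")
    return NuisanceDesign(np.column_stack(blocks), labels)


def regress_nuisance(
    bold: BoldImage, design: NuisanceDesign, mask: np.ndarray | None = None
) -> BoldImage:
    """Replace each (in-mask) voxel series by its OLS residual against the
    design. Degenerate (zero-variance) columns are dropped with a warning;
    residuals are orthogonal to every retained column."""
    if design.n_volumes != bold.n_volumes:
        raise ValueError(
            f"design has {design.n_volumes} rows but BOLD has {bold.n_volumes} volumes"
        )
    degenerate = design.degenerate_columns()
    keep = [i for i, lab in enumerate(design.labels) if lab not in degenerate]
    if degenerate:
        warnings.warn(f"dropping degenerate design columns: {degenerate}", stacklevel=2)
    X = design.matrix[:, keep]
    if X.shape[1] == 0:
        raise ValueError("all design columns degenerate")

    if mask is None:
        mask = np.ones(bold.data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    Y = bold.data[mask].T  # (T, n_vox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = bold.data.copy()
    out[mask] = resid.T
    return bold.with_data(out)


def _butter_band(tr: float, low: float, high: float):
    nyq = 1.0 / (2.0 * tr)
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got [{low}, {high}]")
    if high >= nyq:
        raise ValueError(f"upper cutoff {high} Hz must be below Nyquist {nyq:.4g} Hz")
    if low == 0:
        return signal.butter(2, high, btype="lowpass", fs=1.0 / tr)
    return signal.butter(2, [low, high], btype="bandpass", fs=1.0 / tr)


def bandpass_series(arr: np.ndarray, tr: float, low: float = 0.01, high: float = 0.15,
                    axis: int = -1) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass along ``axis``."""
    arr = np.asarray(arr, dtype=float)
    b, a = _butter_band(tr, low, high)
    min_len = 3 * max(len(a), len(b))  # filtfilt edge-padding requirement
    if arr.shape[axis] <= min_len:
        raise ValueError(
            f"series of length {arr.shape[axis]} too short for zero-phase "
            f"filtering (needs more than {min_len} samples)"
        )
    return signal.filtfilt(b, a, arr, axis=axis)


def bandpass(bold: BoldImage, low: float = 0.01, high: float = 0.15) -> BoldImage:
    """Band-pass every voxel series (default 0.01-0.15 Hz); the filter is
    applied forward-backward, so the output is zero-phase and DC-free."""
    return bold.with_data(bandpass_series(bold.data, bold.tr, low, high, axis=3))


def tissue_assignment(tpm: TissueProbMaps) -> tuple[np.ndarray, np.ndarray]:
    """Hard GM/WM assignment for smoothing: a voxel belongs to the tissue
    with the larger of (gm, wm) probability, provided that probability
    exceeds 0.5; otherwise it is unassigned."""
    wm_wins = tpm.wm >= tpm.gm
    wm_mask = wm_wins & (tpm.wm > 0.5)
    gm_mask = ~wm_wins & (tpm.gm > 0.5)
    return gm_mask, wm_mask


def _masked_smooth(data4d: np.ndarray, mask: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Normalised masked Gaussian convolution: constants inside the mask are
    preserved and nothing leaks across the mask boundary."""
    w = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    num = ndimage.gaussian_filter(
        data4d * mask[..., None], sigma=(*sigma_vox, 0.0)
    )
    out = np.zeros_like(data4d)
    valid = mask & (w > 1e-12)
    out[valid] = num[valid] / w[valid][:, None]
    return out


def smooth_by_tissue(
    bold: BoldImage,
    tpm: TissueProbMaps,
    fwhm: float = 4.0,
    mode: str = "separate",
) -> tuple[BoldImage, dict]:
    """Gaussian smoothing (FWHM in mm) within GM and WM independently
    (``separate``, default), over all voxels (``whole``), or not at all
    (``none``). In ``separate`` mode voxels assigned to neither tissue are
    zeroed; their count is reported as ``n_holes``."""
    if mode == "none":
        return bold, {"mode": mode, "n_holes": 0}
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma_vox = fwhm * FWHM_TO_SIGMA / bold.voxel_size
    if mode == "whole":
        smoothed = ndimage.gaussian_filter(bold.data, sigma=(*sigma_vox, 0.0))
        return bold.with_data(smoothed), {"mode": mode, "n_holes": 0}
    if mode != "separate":
        raise ValueError(f"unknown smoothing mode {mode!r}")
    gm_mask, wm_mask = tissue_assignment(tpm)
    out = _masked_smooth(bold.data, gm_mask, sigma_vox)
    out += _masked_smooth(bold.data, wm_mask, sigma_vox)
    brain = np.any(bold.data != 0, axis=3)
    holes = brain & ~gm_mask & ~wm_mask
    return bold.with_data(out), {"mode": mode, "n_holes": int(holes.sum())}


def preprocess(
    bold: BoldImage,
    motion: np.ndarray | None,
    tpm: TissueProbMaps,
    n_discard: int = 10,
    csf_mode: str = "mean",
    csf_k: int = 5,
    csf_threshold: float = 0.95,
    band: tuple[float, float] = (0.01, 0.15),
    fwhm: float = 4.0,
    smooth_mode: str = "separate",
) -> tuple[BoldImage, dict]:
    """Run the full denoising chain: discard -> nuisance regression ->
    band-pass -> tissue-separated smoothing. Motion rows for discarded
    volumes are dropped so the design aligns with the analysed volumes.

    Returns the cleaned image and a report (CSF mask size, dropped design
    columns, smoothing holes).
    """
    report: dict = {"n_discard": n_discard}
    bold = discard_initial(bold, n_discard)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)[n_discard:]
    csf = None
    if csf_mode != "none":
        csf_mask, flagged = build_csf_mask(tpm, csf_threshold)
        report["csf_mask_voxels"] = int(csf_mask.sum())
        report["csf_mask_empty"] = flagged
        if not flagged:
            csf = extract_csf_regressors(bold, csf_mask, mode=csf_mode, k=csf_k)
    if motion is not None or csf is not None:
        design = build_nuisance_design(motion, csf)
        report["design_columns"] = list(design.labels)
        bold = regress_nuisance(bold, design)
    if band is not None:
        bold = bandpass(bold, *band)
        report["band_hz"] = list(band)
    bold, smooth_report = smooth_by_tissue(bold, tpm, fwhm=fwhm, mode=smooth_mode)
    report.update(smooth_report)
    return bold, report
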