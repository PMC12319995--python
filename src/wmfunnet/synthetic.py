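"""Multi-participant phantom datasets with planted network structure.

The phantom emulates the statistical structure the pipeline assumes: a
brain-like grid with a GM shell, a WM core, a CSF centre and a
corpus-callosum-like slab; K planted networks whose voxel series are a
band-limited latent time course plus white noise (amplitude ratio set by
``snr``); low-frequency drift and a CSF-coupled nuisance signal that the
denoising chain should remove; rigid-body motion traces (still, drifting,
or spiky); and, for group studies, a planted Fisher-z difference in the
latent correlation of one network pair between two participant groups.

It does not model hemodynamics, physiological noise spectra, spatial
autocorrelation of noise, or scanner artifacts — phantom-passing tests
demonstrate the pipeline's algorithmic behaviour, not its robustness to
every property of real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .denoise import bandpass_series
from .images import BoldImage, TissueProbMaps, save_nifti

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "make_phantom",
           "generate_group_phantom", "make_group_phantom"]


@dataclass
class PhantomSpec:
    """Study conditions for one phantom dataset.

    Defaults: a 24x24x24 grid of 3 mm voxels, T=200 volumes at tr=1 s,
    20 participants, 4 planted networks at snr 1 with latents band-limited
    to the pipeline's default pass band.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    tr: float = 1.0
    n_volumes: int = 200
    n_participants: int = 20
    k_true: int = 4
    geometry: str = "blocks"  # "blocks" | "mirrored-pairs"
    n_contralateral_pairs: int = 1  # only for mirrored-pairs geometry
    snr: float = 1.0
    latent_band: tuple[float, float] = (0.01, 0.15)
    latent_share: float = 0.5  # fraction of latent variance shared across participants
    include_cc: bool = True
    motion: dict = field(default_factory=lambda: {"kind": "still"})
    drift_amp: float = 2.0
    csf_coupling: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    group_effect: dict | None = None  # {"edge": (i, j), "delta_z": float}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be at least 2")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.geometry not in ("blocks", "mirrored-pairs"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if min(self.shape) < 10:
            raise ValueError("grid too small: need at least 10 voxels per axis")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world map placing the grid centre at world origin, so
        the midsagittal plane (world x = 0) bisects the grid."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = -self.voxel_size * (np.array(self.shape) - 1) / 2.0
        return aff


@dataclass
class Phantom:
    """In-memory phantom dataset plus its ground truth."""

    spec: PhantomSpec
    bolds: list[BoldImage]
    tpms: list[TissueProbMaps]
    motion: list[np.ndarray]
    wm_truth: np.ndarray  # label volume, 1..k_true over WM voxels (CC excluded)
    gm_truth: np.ndarray
    cc_truth: np.ndarray  # label volume over CC voxels: the driving network id
    wm_latents: np.ndarray  # (P, k_true, T)
    gm_latents: np.ndarray
    covariates: pd.DataFrame | None = None

    @property
    def participant_ids(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.spec.n_participants)]


def _geometry(spec: PhantomSpec):
    """Carve the grid into GM shell, WM core, CSF centre and CC slab, and
    plant network labels."""
    nx, ny, nz = spec.shape
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    margin, shell = 1, 2

    brain = np.zeros(spec.shape, dtype=bool)
    brain[margin:nx - margin, margin:ny - margin, margin:nz - margin] = True
    core = np.zeros(spec.shape, dtype=bool)
    lo = margin + shell
    core[lo:nx - lo, lo:ny - lo, lo:nz - lo] = True

    csf = np.zeros(spec.shape, dtype=bool)
    csf[cx - 1:cx + 1, cy - 1:cy + 1, cz - 1:cz + 1] = True

    cc = np.zeros(spec.shape, dtype=bool)
    if spec.include_cc:
        # an interhemispheric slab just above the CSF centre
        cc[lo:nx - lo, cy - 1:cy + 1, cz + 1:cz + 3] = True
        cc &= core & ~csf

    gm = brain & ~core
    wm = core & ~csf & ~cc

    wm_truth = _plant_labels(wm, spec)
    gm_truth = _plant_labels_axis(gm, spec.k_true, axis=2)
    cc_truth = np.zeros(spec.shape, dtype=np.int16)
    if spec.include_cc:
        cc_idx = np.argwhere(cc)
        order = np.lexsort((cc_idx[:, 2], cc_idx[:, 1], cc_idx[:, 0]))
        groups = np.array_split(np.arange(len(cc_idx)), spec.k_true)
        for g, rows in enumerate(groups):
            sel = cc_idx[order[rows]]
            cc_truth[tuple(sel.T)] = g + 1
    return gm, wm, csf, cc, wm_truth, gm_truth, cc_truth


def _plant_labels_axis(mask: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Split mask voxels into k near-equal contiguous slabs along an axis."""
    out = np.zeros(mask.shape, dtype=np.int16)
    idx = np.argwhere(mask)
    order = np.argsort(idx[:, axis], kind="stable")
    groups = np.array_split(np.arange(len(idx)), k)
    for g, rows in enumerate(groups):
        sel = idx[order[rows]]
        out[tuple(sel.T)] = g + 1
    if any(len(r) == 0 for r in groups):
        raise ValueError(f"grid too small to plant {k} non-empty networks")
    return out


def _plant_labels(wm: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.geometry == "blocks":
        return _plant_labels_axis(wm, spec.k_true, axis=0)
    # mirrored-pairs: partition the left half, mirror to the right; the first
    # n_contralateral_pairs left groups get a partner label on the right, the
    # rest keep the same label in both hemispheres (self-symmetric).
    n_pairs = spec.n_contralateral_pairs
    n_groups = spec.k_true - n_pairs
    if n_groups < n_pairs or n_groups < 1:
        raise ValueError("k_true too small for the requested number of contralateral pairs")
    nx = wm.shape[0]
    out = np.zeros(wm.shape, dtype=np.int16)
    left = wm.copy()
    left[nx // 2:, :, :] = False
    left_groups = _plant_labels_axis(left, n_groups, axis=2)
    idx = np.argwhere(left)
    mirror = idx.copy()
    mirror[:, 0] = nx - 1 - idx[:, 0]
    labels = left_groups[tuple(idx.T)]
    out[tuple(idx.T)] = labels
    right_labels = labels.copy()
    for g in range(n_pairs):
        right_labels[labels == g + 1] = n_groups + g + 1
    out[tuple(mirror.T)] = right_labels
    return out


def _band_limited_noise(rng: np.random.Generator, n_series: int, T: int,
                        tr: float, band: tuple[float, float]) -> np.ndarray:
    """Standardised band-limited Gaussian series, shape (n_series, T)."""
    raw = rng.standard_normal((n_series, T))
    filt = bandpass_series(raw, tr, *band, axis=1)
    sd = filt.std(axis=1, keepdims=True)
    return (filt - filt.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)


def _participant_latents(rng, group_latents, spec: PhantomSpec) -> np.ndarray:
    share = spec.latent_share
    K, T = group_latents.shape
    own = _band_limited_noise(rng, K, T, spec.tr, spec.latent_band)
    lat = np.sqrt(share) * group_latents + np.sqrt(1 - share) * own
    sd = lat.std(axis=1, keepdims=True)
    return (lat - lat.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)


def _motion_trace(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    T = spec.n_volumes
    m = np.zeros((T, 6))
    kind = spec.motion.get("kind", "still")
    if kind == "still":
        return m
    if kind == "drift":
        ramp = np.linspace(0, spec.motion.get("amplitude", 0.5), T)
        m[:, 0] = ramp
        m[:, 3] = ramp / 100.0
        return m
    if kind == "spiky":
        n_spikes = int(spec.motion.get("n_spikes", 1))
        amp = float(spec.motion.get("amplitude", 6.0))
        # step changes in tx: each spike shows up as exactly one FD excursion
        vols = rng.choice(np.arange(2, T - 1, 2), size=n_spikes, replace=False)
        for v in sorted(vols):
            m[v:, 0] += amp
        return m
    raise ValueError(f"unknown motion model {kind!r}")


def generate_phantom(spec: PhantomSpec, covariates: pd.DataFrame | None = None,
                     group_of: np.ndarray | None = None) -> Phantom:
    """Build the phantom in memory. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    gm, wm, csf, cc, wm_truth, gm_truth, cc_truth = _geometry(spec)
    P, T, K = spec.n_participants, spec.n_volumes, spec.k_true

    group_wm = _band_limited_noise(rng, K, T, spec.tr, spec.latent_band)
    group_gm = _band_limited_noise(rng, K, T, spec.tr, spec.latent_band)

    t_axis = np.arange(T) * spec.tr
    drift_base = np.sin(2 * np.pi * 0.003 * t_axis)

    wm_tissue = wm | cc
    tpm_wm = np.where(wm_tissue, 0.9, np.where(gm, 0.05, 0.0))
    tpm_gm = np.where(gm, 0.9, np.where(wm_tissue, 0.05, 0.0))
    tpm_csf = np.where(csf, 0.99, np.where(gm | wm_tissue, 0.02, 0.0))
    affine = spec.affine
    tpm = TissueProbMaps(tpm_gm, tpm_wm, tpm_csf, affine)

    bolds, tpms, motions = [], [], []
    wm_lat = np.empty((P, K, T))
    gm_lat = np.empty((P, K, T))
    effect = spec.group_effect
    for p in range(P):
        lw = _participant_latents(rng, group_wm, spec)
        lg = _participant_latents(rng, group_gm, spec)
        if effect is not None and group_of is not None and group_of[p] == 1:
            i, j = effect["edge"]
            r = float(np.tanh(effect["delta_z"]))
            mixed = np.sqrt(1 - r**2) * lw[j - 1] + r * lw[i - 1]
            sd = mixed.std()
            lw[j - 1] = (mixed - mixed.mean()) / (sd if sd else 1.0)
        wm_lat[p] = lw
        gm_lat[p] = lg

        csf_sig = _band_limited_noise(rng, 1, T, spec.tr, spec.latent_band)[0]
        phase = rng.uniform(0, 2 * np.pi)
        drift = np.sin(2 * np.pi * 0.003 * t_axis + phase)

        data = np.zeros((*spec.shape, T))
        noise = rng.standard_normal((int(gm.sum() + wm.sum() + cc.sum() + csf.sum()), T))
        pos = 0

        def take(n):
            nonlocal pos
            block = noise[pos:pos + n]
            pos += n
            return block

        common = spec.csf_coupling * csf_sig + spec.drift_amp * drift + spec.baseline
        for region_mask, truth in ((wm, wm_truth), (gm, gm_truth), (cc, cc_truth)):
            idx = np.argwhere(region_mask)
            if len(idx) == 0:
                continue
            labels = truth[tuple(idx.T)]
            lat = lw if truth is not gm_truth else lg
            sig = spec.snr * lat[labels - 1]
            data[tuple(idx.T)] = sig + spec.noise_sd * take(len(idx)) + common
        idx = np.argwhere(csf)
        data[tuple(idx.T)] = spec.baseline + 3.0 * csf_sig + spec.noise_sd * take(len(idx))

        bolds.append(BoldImage(data, affine, spec.tr))
        tpms.append(tpm)
        motions.append(_motion_trace(rng, spec))

    return Phantom(
        spec=spec, bolds=bolds, tpms=tpms, motion=motions,
        wm_truth=wm_truth, gm_truth=gm_truth, cc_truth=cc_truth,
        wm_latents=wm_lat, gm_latents=gm_lat, covariates=covariates,
    )


def generate_group_phantom(spec: PhantomSpec, n_per_group: int) -> Phantom:
    """Two-group phantom: the second group carries the planted Fisher-z
    difference at the designated network pair. Returns the phantom with a
    covariates table (id, group)."""
    if spec.group_effect is None:
        raise ValueError("spec.group_effect must be set for a group phantom")
    from dataclasses import replace

    spec = replace(spec, n_participants=2 * n_per_group)
    group_of = np.repeat([0, 1], n_per_group)
    ids = [f"sub-{i + 1:02d}" for i in range(2 * n_per_group)]
    covariates = pd.DataFrame({"participant_id": ids, "group": group_of})
    return generate_phantom(spec, covariates=covariates, group_of=group_of)


def _write_participant(root: Path, pid: str, bold: BoldImage, tpm: TissueProbMaps,
                       motion: np.ndarray) -> None:
    func = root / pid / "func"
    anat = root / pid / "anat"
    func.mkdir(parents=True, exist_ok=True)
    anat.mkdir(parents=True, exist_ok=True)
    bold.save(func / f"{pid}_task-rest_bold.nii.gz")
    np.savetxt(func / f"rp_{pid}.txt", motion, fmt="%.8f")
    for tissue in ("gm", "wm", "csf"):
        arr = getattr(tpm, tissue).astype(np.float32)
        save_nifti(nib.Nifti1Image(arr, tpm.affine),
                   anat / f"{pid}_label-{tissue.upper()}_probseg.nii.gz")


def make_phantom(spec: PhantomSpec, out_dir: str | Path,
                 phantom: Phantom | None = None) -> Phantom:
    """Write a phantom as a BIDS-like tree plus a ground-truth bundle.

    Same spec + same seed produce byte-identical files (NIfTI gzip streams
    are written with a fixed mtime).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if phantom is None:
        phantom = generate_phantom(spec)
    for pid, bold, tpm, motion in zip(phantom.participant_ids, phantom.bolds,
                                      phantom.tpms, phantom.motion):
        _write_participant(out_dir, pid, bold, tpm, motion)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    affine = spec.affine
    save_nifti(nib.Nifti1Image(phantom.wm_truth, affine), truth_dir / "wm_labels.nii.gz")
    save_nifti(nib.Nifti1Image(phantom.gm_truth, affine), truth_dir / "gm_labels.nii.gz")
    save_nifti(nib.Nifti1Image(phantom.cc_truth, affine), truth_dir / "cc_labels.nii.gz")
    truth = {"spec": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(spec).items()},
             "participants": phantom.participant_ids}
    (truth_dir / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
    if phantom.covariates is not None:
        phantom.covariates.to_csv(out_dir / "covariates.csv", index=False)
    return phantom


def make_group_phantom(spec: PhantomSpec, n_per_group: int, out_dir: str | Path) -> Phantom:
    phantom = generate_group_phantom(spec, n_per_group)
    return make_phantom(phantom.spec, out_dir, phantom=phantom)
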