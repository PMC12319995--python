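"""Dataset inventory and acquisition-consistency checking.

Walks a (BIDS-like or custom) participant tree, verifies that the
functional, tissue-map and motion files exist, reads the acquisition
parameters (TR, voxel size, volume count) from the image headers without
loading the data, and reports participants whose parameters deviate from
the cohort's modal set.
"""

from __future__ import annotations

import glob as globmod
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import pandas as pd

__all__ = ["Layout", "ParticipantEntry", "DatasetManifest", "ConsistencyReport",
           "scan_dataset", "check_consistency"]


@dataclass
class Layout:
    """Glob templates (with an ``{id}`` placeholder) locating each
    participant's files under the dataset root. Defaults follow a
    BIDS-like tree as written by the phantom generator."""

    participant_glob: str = "sub-*"
    bold: str = "{id}/func/{id}*bold.nii*"
    gm: str = "{id}/anat/{id}*GM*.nii*"
    wm: str = "{id}/anat/{id}*WM*.nii*"
    csf: str = "{id}/anat/{id}*CSF*.nii*"
    motion: str = "{id}/func/rp_{id}*.txt"


@dataclass
class ParticipantEntry:
    id: str
    bold_path: Path | None = None
    tpm_paths: dict = field(default_factory=dict)
    motion_path: Path | None = None
    tr: float | None = None
    voxel_size: tuple | None = None
    n_volumes: int | None = None
    missing: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        """Missing BOLD or tissue maps excludes; missing motion only warns."""
        return any(m in ("bold", "gm", "wm", "csf", "header") for m in self.missing)


@dataclass
class DatasetManifest:
    root: Path
    participants: list[ParticipantEntry]

    def __post_init__(self) -> None:
        for p in self.participants:
            for path in [p.bold_path, p.motion_path, *p.tpm_paths.values()]:
                assert path is None or Path(path).exists(), f"manifest path vanished: {path}"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            vox = p.voxel_size
            rows.append({
                "participant_id": p.id,
                "tr_s": p.tr,
                "voxel_x_mm": vox[0] if vox else None,
                "voxel_y_mm": vox[1] if vox else None,
                "voxel_z_mm": vox[2] if vox else None,
                "n_volumes": p.n_volumes,
                "missing": ";".join(p.missing),
                "excluded": p.excluded,
            })
        return pd.DataFrame(rows)


@dataclass
class ConsistencyReport:
    modal_params: tuple | None
    consistent: list[str]
    deviating: list[str]
    missing: list[str]
    histograms: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sets = [set(self.consistent), set(self.deviating), set(self.missing)]
        assert sum(len(s) for s in sets) == len(set().union(*sets)), \
            "consistent/deviating/missing must be disjoint"


def _resolve(root: Path, template: str, pid: str) -> Path | None:
    hits = sorted(globmod.glob(str(root / template.format(id=pid))))
    return Path(hits[0]) if hits else None


def scan_dataset(root: str | Path, layout: Layout | None = None) -> DatasetManifest:
    """Inventory every participant directory under ``root``.

    Header fields (TR, voxel size, volume count) are read lazily from the
    BOLD header. An unreadable header flags the participant rather than
    aborting the scan; an empty root is an error.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    layout = layout or Layout()
    pids = sorted(p.name for p in root.glob(layout.participant_glob) if p.is_dir())
    if not pids:
        raise ValueError(f"no participant directories matching {layout.participant_glob!r} under {root}")

    entries = []
    for pid in pids:
        entry = ParticipantEntry(id=pid)
        entry.bold_path = _resolve(root, layout.bold, pid)
        if entry.bold_path is None:
            entry.missing.append("bold")
        for tissue in ("gm", "wm", "csf"):
            path = _resolve(root, getattr(layout, tissue), pid)
            if path is None:
                entry.missing.append(tissue)
            else:
                entry.tpm_paths[tissue] = path
        entry.motion_path = _resolve(root, layout.motion, pid)
        if entry.motion_path is None:
            entry.missing.append("motion")
            entry.warnings.append("no motion-parameter file (may be computed upstream)")
        if entry.bold_path is not None:
            try:
                img = nib.load(str(entry.bold_path))
                zooms = img.header.get_zooms()
                entry.voxel_size = tuple(round(float(z), 2) for z in zooms[:3])
                entry.tr = round(float(zooms[3]), 3) if len(zooms) > 3 else None
                entry.n_volumes = int(img.shape[3]) if len(img.shape) > 3 else 1
            except Exception as exc:  # noqa: BLE001 - flag, don't abort the scan
                entry.missing.append("header")
                entry.warnings.append(f"unreadable header: {exc}")
                warnings.warn(f"{pid}: unreadable BOLD header ({exc})", stacklevel=2)
        entries.append(entry)
    return DatasetManifest(root=root, participants=entries)


def check_consistency(manifest: DatasetManifest, out_dir: str | Path | None = None
                      ) -> ConsistencyReport:
    """Identify the modal (TR, voxel size, n_volumes) parameter set and the
    participants deviating from it; optionally write participant_list.csv.

    Read-only with respect to image data and idempotent. TR is compared at
    1 ms and voxel sizes at 0.01 mm resolution; ties between parameter
    sets break towards the first-seen set.
    """
    if not manifest.participants:
        raise ValueError("empty manifest")
    missing = [p.id for p in manifest.participants if p.excluded]
    candidates = [p for p in manifest.participants if not p.excluded]

    def key(p: ParticipantEntry):
        return (round(p.tr, 3) if p.tr is not None else None,
                tuple(round(v, 2) for v in p.voxel_size) if p.voxel_size else None,
                p.n_volumes)

    counts: Counter = Counter(key(p) for p in candidates)
    modal = None
    if counts:
        best = max(counts.values())
        seen = []
        for p in candidates:
            k = key(p)
            if k not in seen:
                seen.append(k)
        modal = next(k for k in seen if counts[k] == best)

    consistent = [p.id for p in candidates if key(p) == modal]
    deviating = [p.id for p in candidates if key(p) != modal]

    hist = {
        "tr_s": Counter(p.tr for p in candidates),
        "voxel_size_mm": Counter(p.voxel_size for p in candidates),
        "n_volumes": Counter(p.n_volumes for p in candidates),
    }
    table = manifest.to_frame()
    table["deviating"] = table["participant_id"].isin(deviating)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "participant_list.csv", index=False)
    return ConsistencyReport(
        modal_params=modal, consistent=consistent, deviating=deviating,
        missing=missing, histograms=hist, table=table,
    )
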