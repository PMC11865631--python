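"""On-disk representation of MRE datasets.

A dataset is a directory holding a 2D magnitude image and a stack of
phase-offset images as NIfTI-1 files plus a JSON sidecar with the
acquisition metadata.  ROI masks travel as 0/1 integer NIfTI volumes,
result tables as RFC-4180 CSV.

Coordinate convention (used throughout the package): images are indexed
``(row, col)`` with 0-based pixel indices, pixel centres at integer
coordinates, and physical position = index * pixel_spacing_mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "MREDataset",
    "ROIMask",
    "save_dataset",
    "load_dataset",
    "save_mask",
    "load_mask",
    "write_results_csv",
]

#: in-plane spacing for an 18 cm FOV sampled on a 128 matrix
DEFAULT_PIXEL_SPACING_MM = 180.0 / 128  # 1.40625

_META_KEYS = (
    "frequency_hz",
    "n_offsets",
    "pixel_spacing_mm",
    "actuator_position",
    "side",
    "subject_id",
    "encoding_scale_rad_per_um",
)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of a single-slice MRE dataset.

    Parameters
    ----------
    frequency_hz
        Mechanical vibration frequency (60, 80 or 100 Hz in the target
        protocol; any positive value is accepted).
    n_offsets
        Number of phase offsets sampled over one vibration period.
    pixel_spacing_mm
        Isotropic in-plane pixel spacing.
    actuator_position
        ``"VAP"`` (vertical, waves travel along the muscle-fibre
        direction) or ``"HAP"`` (horizontal, waves travel across it).
    side
        ``"left"`` or ``"right"``.
    subject_id
        Free-form identifier.
    encoding_scale_rad_per_um
        Motion-encoding efficiency: phase radians accrued per micron of
        tissue displacement.
    """

    frequency_hz: float
    n_offsets: int = 4
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    actuator_position: str = "VAP"
    side: str = "left"
    subject_id: str = "S00"
    encoding_scale_rad_per_um: float = 0.02

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ValueError(f"frequency_hz must be > 0, got {self.frequency_hz}")
        if self.n_offsets < 3:
            raise ValueError(f"n_offsets must be >= 3, got {self.n_offsets}")
        if not self.pixel_spacing_mm > 0:
            raise ValueError(
                f"pixel_spacing_mm must be > 0, got {self.pixel_spacing_mm}"
            )
        if self.actuator_position not in ("VAP", "HAP"):
            raise ValueError(f"unknown actuator_position {self.actuator_position!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class MREDataset:
    """A 2D magnitude image plus the phase-offset stack that encodes the wave.

    ``magnitude`` has shape ``(H, W)``; ``phase_stack`` has shape
    ``(n_offsets, H, W)`` with values in radians.
    """

    magnitude: np.ndarray
    phase_stack: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float32)
        self.phase_stack = np.asarray(self.phase_stack, dtype=np.float32)
        if self.magnitude.ndim != 2:
            raise ValueError("magnitude must be 2D")
        if self.phase_stack.ndim != 3:
            raise ValueError("phase_stack must be 3D (offset, row, col)")
        if self.phase_stack.shape[1:] != self.magnitude.shape:
            raise ValueError(
                "shape mismatch: magnitude "
                f"{self.magnitude.shape} vs phase slices {self.phase_stack.shape[1:]}"
            )
        if self.phase_stack.shape[0] != self.meta.n_offsets:
            raise ValueError(
                f"phase_stack has {self.phase_stack.shape[0]} offsets, "
                f"meta says {self.meta.n_offsets}"
            )
        if not np.all(np.isfinite(self.phase_stack)):
            raise ValueError("phase_stack contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


@dataclass
class ROIMask:
    """Boolean pixel mask with a label (e.g. ``"UT"`` or ``"background"``)."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError(f"mask {self.label!r} has no true pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _nifti(arr: np.ndarray, spacing_mm: float) -> nib.Nifti1Image:
    affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
    return nib.Nifti1Image(np.asarray(arr), affine)


def save_dataset(ds: MREDataset, path: str | Path) -> None:
    """Write ``magnitude.nii.gz``, ``phase.nii.gz`` and ``meta.json`` to *path*.

    The phase stack is stored with the offset axis last (NIfTI volume
    axis), so a 4-offset acquisition yields a H x W x 4 file.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sp = ds.meta.pixel_spacing_mm
    nib.save(_nifti(ds.magnitude.astype(np.float32), sp), path / "magnitude.nii.gz")
    phase = np.moveaxis(ds.phase_stack.astype(np.float32), 0, -1)
    nib.save(_nifti(phase, sp), path / "phase.nii.gz")
    meta = {k: getattr(ds.meta, k) for k in _META_KEYS}
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_dataset(path: str | Path) -> MREDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    path = Path(path)
    sidecar = path / "meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    raw = json.loads(sidecar.read_text())
    missing = [k for k in _META_KEYS if k not in raw]
    if missing:
        raise KeyError(f"sidecar {sidecar} missing required keys: {missing}")
    meta = AcquisitionMeta(**{k: raw[k] for k in _META_KEYS})
    magnitude = np.asanyarray(nib.load(path / "magnitude.nii.gz").dataobj).astype(
        np.float32
    )
    phase = np.asanyarray(nib.load(path / "phase.nii.gz").dataobj).astype(np.float32)
    if phase.ndim != 3:
        raise ValueError(f"phase file in {path} is not a 3D stack")
    phase = np.moveaxis(phase, -1, 0)
    return MREDataset(magnitude=magnitude, phase_stack=phase, meta=meta)


def save_mask(roi: ROIMask, path: str | Path, pixel_spacing_mm: float) -> None:
    nib.save(_nifti(roi.mask.astype(np.uint8), pixel_spacing_mm), Path(path))


def load_mask(path: str | Path, label: str = "") -> ROIMask:
    arr = np.asanyarray(nib.load(Path(path)).dataobj)
    return ROIMask(mask=arr > 0, label=label)


def write_results_csv(records: list[dict], path: str | Path) -> None:
    """Write flat records as a CSV with a stable column order.

    All records must share the same keys; column order follows the first
    record.  An empty list produces a header-only file (no columns).
    """
    path = Path(path)
    if not records:
        path.write_text("\n")
        return
    keys = list(records[0].keys())
    for i, rec in enumerate(records):
        if list(rec.keys()) != keys:
            raise ValueError(
                f"record {i} keys {sorted(rec)} differ from first record {sorted(keys)}"
            )
    pd.DataFrame.from_records(records, columns=keys).to_csv(path, index=False)
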