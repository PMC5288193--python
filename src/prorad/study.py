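"""The in-memory container for one co-registered mpMRI study and its NIfTI I/O.

All volumes share one voxel grid; the pipeline refuses resampling, matching a
workflow where T2w, ADC and DCE have already been fused.  Shapes are
(nx, ny, nz) for static volumes and (nx, ny, nz, n_timepoints) for the DCE
series, with time in the fourth dimension as in 4-D NIfTI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, MaskError

#: Mask names every study must provide.
REQUIRED_MASKS = ("prostate", "pz", "tz", "urethra", "nat_pz", "nat_tz")


@dataclass
class MpMRIStudy:
    """One patient's co-registered multiparametric MRI study.

    Attributes
    ----------
    t2w, adc : (nx, ny, nz) arrays.  ADC in um^2/s.
    dce : (nx, ny, nz, T) array of concentration-proportional enhancement.
    t_min : (T,) DCE frame times in minutes, t=0 at injection.
    voxel_size_mm : physical spacing per axis.
    masks : named boolean volumes; must include :data:`REQUIRED_MASKS`.
    rois : biopsy-target masks, one per biopsy, keys like ``"roi_01"``.
    roi_zones : for each ROI, which zone ("pz" or "tz") it sits in.
    ece : extracapsular extension flag (semantic radiology input, 0/1).
    """

    t2w: np.ndarray
    adc: np.ndarray
    dce: np.ndarray
    t_min: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    masks: dict[str, np.ndarray]
    rois: dict[str, np.ndarray] = field(default_factory=dict)
    roi_zones: dict[str, str] = field(default_factory=dict)
    ece: int = 0
    patient_id: str = "P000"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = self.t2w.shape
        if self.adc.shape != shape:
            raise ConfigurationError("ADC grid differs from T2w grid")
        if self.dce.shape[:3] != shape or self.dce.shape[3] != len(self.t_min):
            raise ConfigurationError("DCE grid/time axis inconsistent")
        missing = [m for m in REQUIRED_MASKS if m not in self.masks]
        if missing:
            raise MaskError(f"missing required mask(s): {', '.join(missing)}")
        for name, m in list(self.masks.items()) + list(self.rois.items()):
            if m.shape != shape:
                raise MaskError(f"mask '{name}' is not on the study grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2w.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def validate_partition(self, atol: int = 0) -> None:
        """Assert PZ, TZ and urethra partition the prostate voxelwise."""
        pz, tz, ur = (self.masks[k] for k in ("pz", "tz", "urethra"))
        union = pz | tz | ur
        overlap = (pz & tz) | (pz & ur) | (tz & ur)
        n_bad = int((union != self.masks["prostate"]).sum() + overlap.sum())
        if n_bad > atol:
            raise MaskError(f"PZ/TZ/urethra do not partition the prostate "
                            f"({n_bad} violating voxels)")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_study(study: MpMRIStudy, out_dir) -> dict[str, str]:
    """Write a study as NIfTI volumes plus a JSON sidecar; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_size_mm)
    paths: dict[str, str] = {}

    def _w(name, arr, dtype):
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), p)
        paths[name] = str(p)

    _w("t2w", study.t2w, np.float32)
    _w("adc", study.adc, np.float32)
    _w("dce", study.dce, np.float32)
    for name, m in study.masks.items():
        _w(f"mask_{name}", m, np.uint8)
    for name, m in study.rois.items():
        _w(f"mask_{name}", m, np.uint8)
    meta = {
        "patient_id": study.patient_id,
        "t_min": list(map(float, study.t_min)),
        "voxel_size_mm": list(map(float, study.voxel_size_mm)),
        "roi_zones": study.roi_zones,
        "ece": int(study.ece),
        "metadata": study.metadata,
    }
    mp = out / "study.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["study_json"] = str(mp)
    return paths


def load_study(study_dir) -> MpMRIStudy:
    """Load a study written by :func:`save_study` (or hand-assembled with the
    same layout) from ``study_dir``."""
    d = Path(study_dir)
    meta_path = d / "study.json"
    if not meta_path.exists():
        raise ConfigurationError(f"no study.json in {d}")
    meta = json.loads(meta_path.read_text())

    def _r(name):
        p = d / f"{name}.nii.gz"
        if not p.exists():
            raise ConfigurationError(f"missing volume {p.name} in {d}")
        return np.asarray(nib.load(p).get_fdata())

    masks = {}
    for name in REQUIRED_MASKS:
        p = d / f"mask_{name}.nii.gz"
        if not p.exists():
            raise MaskError(f"missing required mask file mask_{name}.nii.gz")
        masks[name] = np.asarray(nib.load(p).get_fdata()) > 0.5
    rois = {}
    for p in sorted(d.glob("mask_roi_*.nii.gz")):
        rois[p.name[len("mask_"):-len(".nii.gz")]] = np.asarray(nib.load(p).get_fdata()) > 0.5
    return MpMRIStudy(
        t2w=_r("t2w"), adc=_r("adc"), dce=_r("dce"),
        t_min=np.asarray(meta["t_min"], dtype=float),
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        masks=masks, rois=rois, roi_zones=dict(meta.get("roi_zones", {})),
        ece=int(meta.get("ece", 0)), patient_id=meta.get("patient_id", "P000"),
        metadata=meta.get("metadata", {}),
    )
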