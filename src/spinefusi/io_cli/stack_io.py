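"""NIfTI + JSON-sidecar persistence for image stacks and masks.

Axis order on disk matches memory: depth (rows, increasing downward),
width (cols), time.  The sidecar carries acquisition metadata that NIfTI
headers cannot express losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from ..preprocess.percent import PercentChangeStack
from ..synthetic_data.phantom import PDStack

__all__ = [
    "save_pd_stack",
    "load_pd_stack",
    "save_percent_stack",
    "load_percent_stack",
    "save_mask",
    "load_mask",
]

_REQUIRED_KEYS = ("pixel_pitch_mm", "frame_rate_hz", "baseline_frames")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(pitch_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pitch_mm
    return aff


def save_pd_stack(stack: PDStack, path: str | Path) -> Path:
    """Write the stack as NIfTI with a JSON sidecar; lossless round-trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(stack.data.astype(np.float64), _affine(stack.pixel_pitch_mm))
    nib.save(img, path)
    sidecar = {
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "frame_rate_hz": stack.frame_rate_hz,
        "baseline_frames": stack.baseline_frames,
        "metadata": stack.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_pd_stack(path: str | Path) -> PDStack:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _REQUIRED_KEYS:
        if key not in sidecar:
            raise KeyError(f"sidecar {sidecar_path} is missing required key {key!r}")
    data = np.asanyarray(nib.load(path).dataobj, dtype=np.float64)
    return PDStack(
        data=data,
        pixel_pitch_mm=sidecar["pixel_pitch_mm"],
        frame_rate_hz=sidecar["frame_rate_hz"],
        baseline_frames=sidecar["baseline_frames"],
        metadata=sidecar.get("metadata", {}),
    )


def save_percent_stack(pct: PercentChangeStack, path: str | Path) -> Path:
    """Percent-change stack: data volume plus baseline map and mask volumes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(1.0)
    nib.save(nib.Nifti1Image(pct.data.astype(np.float64), aff), path)
    stem = str(path)
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    nib.save(
        nib.Nifti1Image(pct.baseline_mean_map.astype(np.float64), aff),
        stem + "_baseline.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(pct.analysis_mask.astype(np.uint8), aff),
        stem + "_mask.nii.gz",
    )
    sidecar = {
        "frame_rate_hz": pct.frame_rate_hz,
        "baseline_frames": pct.baseline_frames,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_percent_stack(path: str | Path) -> PercentChangeStack:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("frame_rate_hz", "baseline_frames"):
        if key not in sidecar:
            raise KeyError(f"sidecar {sidecar_path} is missing required key {key!r}")
    stem = str(path)
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    data = np.asanyarray(nib.load(path).dataobj, dtype=np.float64)
    baseline = np.asanyarray(nib.load(stem + "_baseline.nii.gz").dataobj, dtype=np.float64)
    mask = np.asanyarray(nib.load(stem + "_mask.nii.gz").dataobj).astype(bool)
    return PercentChangeStack(
        data=data,
        baseline_mean_map=baseline,
        analysis_mask=mask,
        frame_rate_hz=sidecar["frame_rate_hz"],
        baseline_frames=sidecar["baseline_frames"],
    )


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(1.0)), path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(Path(path)).dataobj).astype(bool)
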