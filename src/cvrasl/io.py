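"""File formats: NIfTI volumes/series, two-column breathing traces, sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import AslAcquisitionParams, BreathingTrace

__all__ = [
    "FormatError",
    "read_nifti",
    "write_nifti",
    "read_trace",
    "write_trace",
    "read_asl_params",
    "write_asl_params",
]


class FormatError(RuntimeError):
    """Malformed or unreadable input file."""


def write_nifti(data: np.ndarray,
                path: str | Path,
                voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                tr: float | None = None) -> Path:
    """Write a 3D/4D array as NIfTI-1 with a diagonal voxel-size affine."""
    path = Path(path)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = tuple(voxel_size) + ((tr,) if tr is not None and data.ndim == 4 else ())
    img.header.set_zooms(zooms[: data.ndim])
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path):
    """Read a NIfTI file; returns (data array, voxel_size mm, tr or None)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several types for bad headers
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return data, voxel_size, tr


def write_trace(trace: BreathingTrace, path: str | Path) -> Path:
    path = Path(path)
    header = "time_s petco2_mmhg"
    np.savetxt(path, np.column_stack([trace.time, trace.petco2]),
               header=header, fmt="%.6f")
    return path


def read_trace(path: str | Path) -> BreathingTrace:
    """Read a two-column (time s, PetCO2 mmHg) whitespace-delimited trace.

    Lines starting with '#' are comments.  Non-monotone or malformed time
    columns raise FormatError.
    """
    path = Path(path)
    try:
        arr = np.loadtxt(path, comments="#")
    except Exception as exc:
        raise FormatError(f"cannot parse trace file {path}: {exc}") from exc
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FormatError(f"trace file {path} must have two numeric columns")
    try:
        return BreathingTrace(time=arr[:, 0], petco2=arr[:, 1])
    except ValueError as exc:
        raise FormatError(f"invalid trace in {path}: {exc}") from exc


def write_asl_params(params: AslAcquisitionParams, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "plds_ms": [p * 1000.0 for p in params.plds],
        "tau_ms": params.tau * 1000.0,
        "flip_deg": params.flip_deg,
        "alpha": params.alpha,
        "t1b_s": params.t1b,
        "dti_ms": params.dti * 1000.0,
        "lambda_blood": params.lambda_blood,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_asl_params(path: str | Path) -> AslAcquisitionParams:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        return AslAcquisitionParams(
            plds=tuple(p / 1000.0 for p in payload["plds_ms"]),
            tau=payload["tau_ms"] / 1000.0,
            flip_deg=payload["flip_deg"],
            alpha=payload["alpha"],
            t1b=payload["t1b_s"],
            dti=payload.get("dti_ms", 665.0) / 1000.0,
            lambda_blood=payload.get("lambda_blood", 0.9),
        )
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"invalid ASL parameter sidecar {path}: {exc}") from exc
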