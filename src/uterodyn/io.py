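"""Reading and writing sessions and result tables.

A session directory holds 4D NIfTI label and signal volumes, a JSON sidecar
with per-frame timestamps and acquisition parameters, and (for phantoms) a
ground-truth event CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicSeries, GridGeometry, LABEL_LEGEND

LABELS_NAME = "labels.nii"
SIGNAL_NAME = "signal.nii"
SIDECAR_NAME = "session.json"
GROUND_TRUTH_NAME = "ground_truth.csv"


def write_session(
    series: DynamicSeries,
    outdir: str | Path,
    ground_truth: pd.DataFrame | None = None,
    compress: bool = False,
) -> Path:
    """Write a session directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    affine = series.grid.affine
    # NIfTI wants spatial axes first: (x, y, z, t)
    labels = np.moveaxis(series.labels, 0, -1).astype(np.uint8)
    signal = np.moveaxis(series.signal, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(labels, affine), outdir / (LABELS_NAME + suffix))
    nib.save(nib.Nifti1Image(signal, affine), outdir / (SIGNAL_NAME + suffix))
    sidecar = {
        "timestamps_s": series.timestamps_s.tolist(),
        "te_ms": series.te_ms,
        "tr_min_s": series.tr_min_s,
        "grid": {
            "shape": list(series.grid.shape),
            "in_plane_mm": list(series.grid.in_plane_mm),
            "slice_thickness_mm": series.grid.slice_thickness_mm,
            "slice_spacing_mm": series.grid.slice_spacing_mm,
        },
        "labels": {str(k): v for k, v in LABEL_LEGEND.items()},
        "provenance": _jsonable(series.provenance),
    }
    (outdir / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    if ground_truth is not None:
        ground_truth.to_csv(outdir / GROUND_TRUTH_NAME, index=False)
    return outdir


def read_session(session_dir: str | Path) -> tuple[DynamicSeries, pd.DataFrame | None]:
    """Read a session directory written by :func:`write_session`."""
    session_dir = Path(session_dir)
    sidecar = json.loads((session_dir / SIDECAR_NAME).read_text())
    grid = GridGeometry(
        shape=tuple(sidecar["grid"]["shape"]),
        in_plane_mm=tuple(sidecar["grid"]["in_plane_mm"]),
        slice_thickness_mm=sidecar["grid"]["slice_thickness_mm"],
        slice_spacing_mm=sidecar["grid"]["slice_spacing_mm"],
    )
    labels = np.moveaxis(np.asanyarray(_load_nifti(session_dir, LABELS_NAME).dataobj), -1, 0)
    signal = np.moveaxis(np.asanyarray(_load_nifti(session_dir, SIGNAL_NAME).dataobj), -1, 0)
    series = DynamicSeries(
        timestamps_s=np.asarray(sidecar["timestamps_s"], dtype=float),
        labels=labels.astype(np.uint8),
        signal=signal.astype(float),
        grid=grid,
        te_ms=float(sidecar["te_ms"]),
        tr_min_s=sidecar.get("tr_min_s"),
        provenance=sidecar.get("provenance", {}),
    )
    gt_path = session_dir / GROUND_TRUTH_NAME
    ground_truth = pd.read_csv(gt_path) if gt_path.exists() else None
    return series, ground_truth


def _load_nifti(session_dir: Path, base: str):
    for name in (base, base + ".gz"):
        p = session_dir / name
        if p.exists():
            return nib.load(p)
    raise FileNotFoundError(f"{base}[.gz] not found in {session_dir}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
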