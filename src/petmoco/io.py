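"""File formats: 4D NIfTI volumes with a frame-timing JSON sidecar
(BIDS-PET-style keys), uint8 NIfTI masks, and CSV curves/motion tables.

Units are stated in every CSV header; NIfTI affines are diagonal in the
phantom's voxel size (the simulator has no anatomical orientation).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicPETSeries, FrameSchedule, InputFunction, MotionVector
from .core import MotionEstimate

MOTION_COLUMNS = ["frame", "tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def write_series(series: DynamicPETSeries, path) -> None:
    """4D NIfTI plus ``<stem>.json`` sidecar with the frame schedule."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    sidecar = {
        "frame_start_s": [float(t) for t in series.schedule.starts],
        "frame_end_s": [float(t) for t in series.schedule.ends],
        "units": "Bq/mL",
        "frame_of_reference": series.frame_of_reference,
    }
    with open(path.with_suffix("").with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_series(path) -> DynamicPETSeries:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D series")
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"frame-timing sidecar missing: {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    schedule = FrameSchedule(
        tuple(zip(sidecar["frame_start_s"], sidecar["frame_end_s"]))
    )
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DynamicPETSeries(
        data, schedule, voxel_size, sidecar.get("frame_of_reference", "native")
    )


def write_mask(mask: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size))
    nib.save(img, path)


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj) > 0


def write_curve(curve: InputFunction, path) -> None:
    pd.DataFrame(
        {"t_s": curve.t, "activity_Bq_per_mL": curve.value, "kind": curve.kind}
    ).to_csv(path, index=False)


def read_curve(path) -> InputFunction:
    df = pd.read_csv(path)
    kind = str(df["kind"].iloc[0]) if "kind" in df else "plasma"
    return InputFunction(
        t=df["t_s"].to_numpy(), value=df["activity_Bq_per_mL"].to_numpy(), kind=kind
    )


def write_motion(estimates, path) -> None:
    """Motion estimates (or ground-truth vectors) to CSV."""
    rows = []
    for est in estimates:
        if isinstance(est, MotionVector):  # ground truth: plain vectors
            est = MotionEstimate(len(rows), est)
        rows.append(
            {
                "frame": est.frame,
                "tx_mm": est.vector.tx,
                "ty_mm": est.vector.ty,
                "tz_mm": est.vector.tz,
                "rx_deg": est.vector.rx,
                "ry_deg": est.vector.ry,
                "rz_deg": est.vector.rz,
                "final_mi_nats": est.final_mi,
                "converged": est.converged,
                "note": est.note,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_motion(path) -> list[MotionEstimate]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        vec = MotionVector(
            r["tx_mm"], r["ty_mm"], r["tz_mm"], r["rx_deg"], r["ry_deg"], r["rz_deg"]
        )
        out.append(
            MotionEstimate(
                int(r["frame"]), vec,
                float(r.get("final_mi_nats", float("nan"))),
                bool(r.get("converged", True)),
                str(r.get("note", "")) if not pd.isna(r.get("note", "")) else "",
            )
        )
    return out
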