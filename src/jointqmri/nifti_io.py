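"""NIfTI and tabular I/O with JSON acquisition sidecars.

Volumes travel as NIfTI files with the voxel spacing encoded in the header
(via the affine); acquisition parameters that NIfTI headers cannot carry —
repetition time, flip-angle list, echo-time list — live in a JSON sidecar
next to each image, with BIDS-flavoured key names (RepetitionTime ms,
FlipAngles deg, EchoTimes ms).  Score tables are CSV with columns
subject_id, group, time_days, variable, value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import ParameterError, RelaxometrySeries, VolumeGrid

__all__ = [
    "SidecarMeta",
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_scores",
    "write_scores",
    "ha_concentration_table",
]

SCORE_COLUMNS = ["subject_id", "group", "time_days", "variable", "value"]


@dataclass
class SidecarMeta:
    """Acquisition parameters accompanying a NIfTI volume."""

    tr_ms: Optional[float] = None
    flip_angles_deg: Optional[list[float]] = None
    echo_times_ms: Optional[list[float]] = None
    spacing_mm: Optional[tuple[float, float, float]] = None
    orientation: Optional[tuple[str, str, str]] = None
    provenance: str = ""

    def validate_for_relaxometry(self) -> None:
        if self.flip_angles_deg is None and self.echo_times_ms is None:
            raise ParameterError(
                "sidecar must provide FlipAngles (with RepetitionTime) or EchoTimes "
                "for relaxometry input"
            )
        if self.flip_angles_deg is not None and self.tr_ms is None:
            raise ParameterError("variable-flip-angle sidecar must provide RepetitionTime (ms)")

    def to_json_dict(self) -> dict:
        out: dict = {"Provenance": self.provenance}
        if self.tr_ms is not None:
            out["RepetitionTime"] = self.tr_ms
        if self.flip_angles_deg is not None:
            out["FlipAngles"] = list(map(float, self.flip_angles_deg))
        if self.echo_times_ms is not None:
            out["EchoTimes"] = list(map(float, self.echo_times_ms))
        if self.spacing_mm is not None:
            out["VoxelSpacing"] = list(map(float, self.spacing_mm))
        if self.orientation is not None:
            out["AxisOrientation"] = list(self.orientation)
        return out

    @classmethod
    def from_json_dict(cls, d: dict) -> "SidecarMeta":
        return cls(
            tr_ms=d.get("RepetitionTime"),
            flip_angles_deg=d.get("FlipAngles"),
            echo_times_ms=d.get("EchoTimes"),
            spacing_mm=tuple(d["VoxelSpacing"]) if "VoxelSpacing" in d else None,
            orientation=tuple(d["AxisOrientation"]) if "AxisOrientation" in d else None,
            provenance=d.get("Provenance", ""),
        )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(grid: VolumeGrid, path, meta: Optional[SidecarMeta] = None) -> Path:
    """Write a VolumeGrid as NIfTI (+ JSON sidecar if meta given)."""
    path = Path(path)
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    if meta is not None:
        if meta.spacing_mm is None:
            meta.spacing_mm = grid.spacing
        _sidecar_path(path).write_text(json.dumps(meta.to_json_dict(), indent=1))
    return path


def read_volume(path) -> tuple[VolumeGrid, Optional[SidecarMeta]]:
    """Read a NIfTI volume and its JSON sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as e:  # malformed header
        raise ParameterError(f"cannot read NIfTI header of {path.name}: {e}") from e
    if any(z <= 0 for z in zooms):
        raise ParameterError(f"{path.name}: header field pixdim must be positive, got {zooms}")
    meta = None
    sp = _sidecar_path(path)
    if sp.exists():
        meta = SidecarMeta.from_json_dict(json.loads(sp.read_text()))
    orientation = meta.orientation if meta is not None else None
    grid = VolumeGrid(data, tuple(float(z) for z in zooms), np.asarray(img.affine), orientation)
    return grid, meta


def write_series(series: RelaxometrySeries, path, provenance: str = "") -> Path:
    """Write a relaxometry stack as 4D NIfTI + sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(series.stack, 0, -1), series.affine)
    img.header.set_zooms((*series.spacing, 1.0))
    nib.save(img, str(path))
    meta = SidecarMeta(
        tr_ms=series.tr_ms,
        flip_angles_deg=None if series.flip_angles_deg is None else list(series.flip_angles_deg),
        echo_times_ms=None if series.echo_times_ms is None else list(series.echo_times_ms),
        spacing_mm=series.spacing,
        provenance=provenance,
    )
    _sidecar_path(path).write_text(json.dumps(meta.to_json_dict(), indent=1))
    return path


def read_series(path) -> RelaxometrySeries:
    """Read a 4D NIfTI stack; the JSON sidecar is required."""
    path = Path(path)
    sp = _sidecar_path(path)
    if not sp.exists():
        raise ParameterError(
            f"{path.name}: missing sidecar {sp.name}; relaxometry input requires "
            "RepetitionTime+FlipAngles or EchoTimes"
        )
    meta = SidecarMeta.from_json_dict(json.loads(sp.read_text()))
    meta.validate_for_relaxometry()
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ParameterError(f"{path.name}: expected a 4D stack, got shape {data.shape}")
    stack = np.moveaxis(data, -1, 0)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RelaxometrySeries(
        stack,
        spacing,
        tr_ms=meta.tr_ms,
        flip_angles_deg=meta.flip_angles_deg,
        echo_times_ms=meta.echo_times_ms,
        affine=np.asarray(img.affine),
    )


def write_scores(frame: pd.DataFrame, path) -> Path:
    missing = set(SCORE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParameterError(f"score table missing columns: {sorted(missing)}")
    path = Path(path)
    frame[SCORE_COLUMNS].to_csv(path, index=False)
    return path


def read_scores(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"{path.name}: score table missing columns: {sorted(missing)}")
    return df


def ha_concentration_table() -> pd.DataFrame:
    """Packaged fixture: synovial-fluid hyaluronic acid concentrations (ng/mL).

    Measured study data (group x sampling day), shipped for exercising the
    descriptive and robust-ANOVA operations; not recomputable.
    """
    path = Path(__file__).parent / "data" / "ha_synovial_fluid_concentration.csv"
    return pd.read_csv(path)
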