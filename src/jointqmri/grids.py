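"""Core image containers shared by every stage of the pipeline.

A :class:`VolumeGrid` is a 3D scalar image together with its voxel spacing in
millimetres and (optionally) a NIfTI-style affine and axis-orientation tags.
Voxel coordinates are 0-based array indices; world coordinates follow the
affine.  A :class:`RelaxometrySeries` stacks co-registered volumes acquired at
different flip angles (variable-flip-angle T1) or echo times (multi-echo T2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "GridMismatchError",
    "DegenerateDataError",
    "VolumeGrid",
    "RelaxometrySeries",
    "ParametricMap",
    "BoneBiomarkers",
    "ScoreRecord",
    "records_to_frame",
    "frame_to_records",
]


class ParameterError(ValueError):
    """A physical or design parameter is outside its valid domain."""


class GridMismatchError(ValueError):
    """Two volumes that must share a grid (shape + spacing) do not."""


class DegenerateDataError(ValueError):
    """Input data admit no well-defined estimate (e.g. zero variance)."""


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
    spacing : 3 floats, mm per voxel along each array axis
    affine : 4x4 voxel-to-world matrix; defaults to ``diag(spacing)``
    orientation : optional axis tags, e.g. ``("ML", "AP", "SI")`` naming the
        anatomical direction of each array axis (medial-lateral,
        anterior-posterior, superior-inferior).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None
    orientation: Optional[tuple[str, str, str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ParameterError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grid mismatch (shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing})"
            )

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different data."""
        return VolumeGrid(data, self.spacing, self.affine, self.orientation)


@dataclass
class RelaxometrySeries:
    """Co-registered signal volumes with per-volume acquisition parameters.

    Exactly one of ``flip_angles_deg`` (with ``tr_ms``) or ``echo_times_ms``
    must be given; the stack's leading axis indexes acquisitions.
    """

    stack: np.ndarray  # (n_acq, nx, ny, nz)
    spacing: tuple[float, float, float]
    tr_ms: Optional[float] = None
    flip_angles_deg: Optional[np.ndarray] = None
    echo_times_ms: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 4:
            raise ParameterError("series stack must be 4D (acquisition, x, y, z)")
        self.spacing = tuple(float(s) for s in self.spacing)
        has_fa = self.flip_angles_deg is not None
        has_te = self.echo_times_ms is not None
        if has_fa == has_te:
            raise ParameterError("exactly one of flip_angles_deg or echo_times_ms required")
        if has_fa:
            self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
            if len(self.flip_angles_deg) != self.stack.shape[0]:
                raise ParameterError("one flip angle per volume required")
            if self.tr_ms is None or self.tr_ms <= 0:
                raise ParameterError("variable-flip-angle series requires a positive TR (ms)")
            if np.any(self.flip_angles_deg <= 0) or np.any(self.flip_angles_deg > 90):
                raise ParameterError("flip angles must lie in (0, 90] degrees")
        else:
            self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
            if len(self.echo_times_ms) != self.stack.shape[0]:
                raise ParameterError("one echo time per volume required")
            if np.any(self.echo_times_ms <= 0):
                raise ParameterError("echo times must be positive (ms)")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def n_acquisitions(self) -> int:
        return self.stack.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.stack.shape[1:]  # type: ignore[return-value]

    def volume(self, i: int) -> VolumeGrid:
        return VolumeGrid(self.stack[i], self.spacing, self.affine)


@dataclass
class ParametricMap:
    """Voxel-wise relaxation-time map (ms) with amplitude and validity mask.

    ``values`` holds T1 or T2 in ms and ``amplitude`` the fitted M0/S0.  Both
    are defined only where ``valid_mask`` is true; flagged voxels may hold
    NaN or an implausible estimate that failed the plausibility screen.
    """

    values: VolumeGrid
    amplitude: VolumeGrid
    valid_mask: VolumeGrid
    kind: str  # "T1" or "T2"

    def __post_init__(self) -> None:
        if self.kind not in ("T1", "T2"):
            raise ParameterError(f"kind must be 'T1' or 'T2', got {self.kind!r}")
        self.values.require_same_grid(self.amplitude, "parametric map")
        self.values.require_same_grid(self.valid_mask, "parametric map")
        self.valid_mask.data = self.valid_mask.data.astype(bool)


@dataclass(frozen=True)
class BoneBiomarkers:
    """Trabecular morphometry for one volume of interest.

    bvtv is the bone volume fraction (unitless), tb_th/tb_sp mean trabecular
    thickness/spacing in mm, tb_n = bvtv / tb_th in 1/mm, and d2d/d3d the 2D
    (per-slice mean) and 3D box-counting fractal dimensions.
    """

    bvtv: float
    tb_th_mm: float
    tb_sp_mm: float
    tb_n_per_mm: float
    d2d: float
    d3d: float
    voi_label: str = "medial"


@dataclass(frozen=True)
class ScoreRecord:
    """One observation of one variable on one joint."""

    subject_id: str
    group: str
    time_days: int
    variable: str
    value: float


def records_to_frame(records: Sequence[ScoreRecord]):
    """ScoreRecords -> tidy DataFrame (subject_id, group, time_days, variable, value)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "time_days": [r.time_days for r in records],
            "variable": [r.variable for r in records],
            "value": [r.value for r in records],
        }
    )


def frame_to_records(frame) -> list[ScoreRecord]:
    required = {"subject_id", "group", "time_days", "variable", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ParameterError(f"score table missing columns: {sorted(missing)}")
    return [
        ScoreRecord(str(r.subject_id), str(r.group), int(r.time_days), str(r.variable), float(r.value))
        for r in frame.itertuples(index=False)
    ]
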