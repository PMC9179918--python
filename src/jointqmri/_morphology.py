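"""Shared distance-transform morphology helpers.

Thickness of a binary phase is measured as twice the Euclidean distance
transform sampled on the phase's medial surface.  The medial surface is the
ridge of the distance transform: voxels whose EDT equals the maximum over
their 3x3(x3) neighbourhood.  Unlike topological thinning (which produces
curve skeletons in 3D and collapses plate-like structures to their rims),
the ridge keeps the full medial sheet of plates and the axis of rods, so a
parallel-plate lattice of thickness t yields exactly t * spacing.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = ["distance_ridge", "phase_thickness", "resample_to_isotropic"]


def distance_ridge(phase: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance transform of ``phase`` and its medial-surface ridge.

    Returns ``(edt, ridge)`` where ``edt`` is in mm (anisotropic spacing
    respected) and ``ridge`` is a boolean mask of local-maximum voxels.
    """
    phase = np.asarray(phase, dtype=bool)
    edt = ndimage.distance_transform_edt(phase, sampling=spacing)
    local_max = ndimage.grey_dilation(edt, size=(3,) * phase.ndim)
    ridge = phase & (edt >= local_max - 1e-9) & (edt > 0)
    return edt, ridge


def phase_thickness(
    phase: np.ndarray,
    spacing,
    sample_mask: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Mean thickness (mm) of a binary phase and the voxel-wise 2*EDT map.

    Thickness is ``2 * EDT`` averaged over medial-surface voxels, optionally
    restricted to ``sample_mask`` (e.g. a volume of interest, to avoid
    sampling structures truncated by the volume faces).
    """
    phase = np.asarray(phase, dtype=bool)
    if phase.all():
        raise ValueError(
            "phase fills the entire volume; thickness is undefined without background"
        )
    edt, ridge = distance_ridge(phase, spacing)
    if sample_mask is not None:
        ridge = ridge & np.asarray(sample_mask, dtype=bool)
    if not ridge.any():
        raise ValueError("phase has no medial-surface voxels to sample")
    return float(2.0 * edt[ridge].mean()), 2.0 * edt


def resample_to_isotropic(
    binary: np.ndarray, spacing, tol: float = 1e-6
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Nearest-neighbour resample of a binary volume to the finest spacing.

    Distance transforms on anisotropic grids bias thickness estimates, so
    morphometry resamples first.  Isotropic inputs pass through unchanged.
    """
    spacing = tuple(float(s) for s in spacing)
    s_min = min(spacing)
    if max(spacing) - s_min <= tol:
        return np.asarray(binary, dtype=bool), spacing
    zoom = [s / s_min for s in spacing]
    out = ndimage.zoom(np.asarray(binary, dtype=np.uint8), zoom, order=0) > 0
    return out, (s_min, s_min, s_min)
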