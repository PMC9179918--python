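"""Synthetic phantoms with known ground truth for every pipeline stage.

Three generators are provided:

* cartilage phantoms — spoiled-gradient-echo (SPGR) signal stacks across flip
  angles and mono-exponential multi-echo stacks across echo times, rendered
  from closed-form signal equations with per-region T1/T2/M0 truth;
* trabecular phantoms — binary lattices (parallel plates, orthogonal rods, or
  a thresholded Gaussian random field) with analytically known morphometry,
  plus a blurred/noised grayscale rendering;
* ordinal score datasets — balanced two-factor designs (treatment group x
  survival time) with planted location shifts, optionally discretized to
  ordinal stages.

Magnitude MRI noise is Rician by default (the magnitude of a complex Gaussian
perturbation); Gaussian noise is available for linear-fit unit tests.  All
randomness flows from a single integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import ndimage

from .grids import (
    ParameterError,
    ParametricMap,
    RelaxometrySeries,
    ScoreRecord,
    VolumeGrid,
)

__all__ = [
    "CartilagePhantomSpec",
    "TrabecularPhantomSpec",
    "ScoreSimSpec",
    "TrabecularTruth",
    "simulate_spgr_signal",
    "simulate_multiecho_signal",
    "add_noise",
    "make_cartilage_phantom",
    "make_trabecular_phantom",
    "make_ordinal_score_dataset",
    "DEFAULT_FLIP_ANGLES_DEG",
    "DEFAULT_ECHO_TIMES_MS",
    "FWHM_TO_SIGMA",
]

#: The six excitation flip angles used for variable-flip-angle T1 mapping.
DEFAULT_FLIP_ANGLES_DEG = (2.0, 5.0, 10.0, 15.0, 25.0, 45.0)

#: The sixteen echo times (ms) used for multi-echo T2 mapping.
DEFAULT_ECHO_TIMES_MS = (
    2.7, 4.1, 5.5, 6.9, 8.3, 9.7, 11.1, 12.5,
    13.9, 15.3, 16.7, 18.1, 19.5, 20.9, 22.3, 23.7,
)

#: Gaussian sigma per unit FWHM: 1 / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / 2.3548


# --------------------------------------------------------------------------
# signal equations
# --------------------------------------------------------------------------

def simulate_spgr_signal(m0: float, t1_ms: float, tr_ms: float, flip_angles_deg) -> np.ndarray:
    """Steady-state SPGR signal at each flip angle.

    S(a) = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),  E1 = exp(-TR/T1).
    """
    if t1_ms <= 0:
        raise ParameterError(f"T1 must be positive, got {t1_ms}")
    if tr_ms <= 0:
        raise ParameterError(f"TR must be positive, got {tr_ms}")
    if m0 < 0:
        raise ParameterError(f"M0 must be non-negative, got {m0}")
    fa = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))
    e1 = math.exp(-tr_ms / t1_ms)
    return m0 * np.sin(fa) * (1.0 - e1) / (1.0 - e1 * np.cos(fa))


def simulate_multiecho_signal(s0: float, t2_ms: float, echo_times_ms) -> np.ndarray:
    """Mono-exponential decay S(TE) = S0 exp(-TE/T2)."""
    if t2_ms <= 0:
        raise ParameterError(f"T2 must be positive, got {t2_ms}")
    if s0 < 0:
        raise ParameterError(f"S0 must be non-negative, got {s0}")
    te = np.asarray(echo_times_ms, dtype=float)
    return s0 * np.exp(-te / t2_ms)


def add_noise(
    signal: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    model: str = "rician",
) -> np.ndarray:
    """Corrupt a noiseless signal with Gaussian or Rician (magnitude) noise."""
    if sigma < 0:
        raise ParameterError("noise sigma must be non-negative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    signal = np.asarray(signal, dtype=float)
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    if model == "rician":
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        return np.hypot(re, im)
    raise ParameterError(f"unknown noise model {model!r}")


# --------------------------------------------------------------------------
# cartilage phantom
# --------------------------------------------------------------------------

@dataclass
class CartilagePhantomSpec:
    """Geometry, tissue parameters and acquisition settings for a phantom.

    ``regions`` is a list of ``(label, t1_ms, t2_ms, m0)`` tuples; regions are
    laid out as equal-thickness slabs stacked along the last (z) axis, inside
    a signal-free background margin of ``background_margin`` voxels at the z
    faces (so the cartilage mask has a boundary, as real cartilage does).
    """

    shape: tuple[int, int, int] = (16, 16, 16)
    spacing: tuple[float, float, float] = (0.25, 0.25, 0.25)
    regions: Sequence[tuple[int, float, float, float]] = ((1, 1000.0, 30.0, 1000.0),)
    background_margin: int = 2
    tr_ms: float = 15.0
    flip_angles_deg: Sequence[float] = DEFAULT_FLIP_ANGLES_DEG
    echo_times_ms: Sequence[float] = DEFAULT_ECHO_TIMES_MS
    noise_sigma: float = 0.0
    noise_model: str = "rician"
    seed: int = 0

    def validate(self) -> None:
        if len(self.regions) == 0:
            raise ParameterError("at least one region is required")
        for label, t1, t2, m0 in self.regions:
            if t1 <= 0 or t2 <= 0:
                raise ParameterError(f"region {label}: T1 and T2 must be positive")
            if m0 < 0:
                raise ParameterError(f"region {label}: M0 must be non-negative")
        if self.tr_ms <= 0:
            raise ParameterError("TR must be positive")
        fa = np.asarray(self.flip_angles_deg, dtype=float)
        if np.any(fa <= 0) or np.any(fa > 90):
            raise ParameterError("flip angles must lie in (0, 90] degrees")
        te = np.asarray(self.echo_times_ms, dtype=float)
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ParameterError("echo times must be positive and strictly increasing")
        if self.noise_model not in ("gaussian", "rician"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")


class CartilagePhantom(NamedTuple):
    vfa: RelaxometrySeries
    multiecho: RelaxometrySeries
    truth_t1: ParametricMap
    truth_t2: ParametricMap
    labelmap: VolumeGrid


def make_cartilage_phantom(spec: CartilagePhantomSpec) -> CartilagePhantom:
    """Render VFA and multi-echo stacks with voxel-wise closed-form signals.

    Before noise, every voxel's signal equals :func:`simulate_spgr_signal`
    (resp. :func:`simulate_multiecho_signal`) of its region's parameters.
    Truth maps carry the generating T1/T2/M0 per voxel.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    labels = np.zeros(spec.shape, dtype=np.int32)
    t1_map = np.zeros(spec.shape)
    t2_map = np.zeros(spec.shape)
    m0_map = np.zeros(spec.shape)
    nz = spec.shape[2]
    margin = int(spec.background_margin)
    if nz - 2 * margin < len(spec.regions):
        raise ParameterError("volume too thin for the requested regions and margin")
    n_reg = len(spec.regions)
    bounds = np.linspace(margin, nz - margin, n_reg + 1).round().astype(int)
    for i, (label, t1, t2, m0) in enumerate(spec.regions):
        sl = slice(bounds[i], bounds[i + 1])
        labels[:, :, sl] = label
        t1_map[:, :, sl] = t1
        t2_map[:, :, sl] = t2
        m0_map[:, :, sl] = m0

    fa = np.asarray(spec.flip_angles_deg, dtype=float)
    te = np.asarray(spec.echo_times_ms, dtype=float)

    vfa_stack = np.zeros((len(fa), *spec.shape))
    me_stack = np.zeros((len(te), *spec.shape))
    for label, t1, t2, m0 in spec.regions:
        region = labels == label
        vfa_stack[:, region] = simulate_spgr_signal(m0, t1, spec.tr_ms, fa)[:, None]
        me_stack[:, region] = simulate_multiecho_signal(m0, t2, te)[:, None]

    vfa_stack = add_noise(vfa_stack, spec.noise_sigma, rng, spec.noise_model)
    me_stack = add_noise(me_stack, spec.noise_sigma, rng, spec.noise_model)

    grid = VolumeGrid(labels, spec.spacing)
    valid = grid.like(labels > 0)
    truth_t1 = ParametricMap(grid.like(t1_map), grid.like(m0_map), valid, "T1")
    truth_t2 = ParametricMap(grid.like(t2_map), grid.like(m0_map), grid.like(labels > 0), "T2")
    vfa = RelaxometrySeries(vfa_stack, spec.spacing, tr_ms=spec.tr_ms, flip_angles_deg=fa)
    me = RelaxometrySeries(me_stack, spec.spacing, echo_times_ms=te)
    return CartilagePhantom(vfa, me, truth_t1, truth_t2, grid)


# --------------------------------------------------------------------------
# trabecular phantom
# --------------------------------------------------------------------------

@dataclass
class TrabecularPhantomSpec:
    """Trabecular lattice geometry and rendering parameters.

    For ``parallel_plates`` the analytic truth is
    BV/TV = thickness/period, Tb.Th = thickness * spacing,
    Tb.Sp = (period - thickness) * spacing, TbN = 1/(period * spacing).
    Plates are normal to the z axis, inset from the volume faces so that the
    volume of interest contains only whole, face-free periods.
    """

    shape: tuple[int, int, int] = (32, 32, 66)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    lattice: str = "parallel_plates"
    thickness: int = 2  # plate/rod thickness, voxels
    period: int = 10  # lattice period, voxels
    blur_fwhm_mm: float = 0.0
    noise_sigma: float = 0.0
    fill_fraction: float = 0.3  # thresholded_random_field only
    seed: int = 0

    def validate(self) -> None:
        if self.lattice not in ("parallel_plates", "orthogonal_rods", "thresholded_random_field"):
            raise ParameterError(f"unknown lattice {self.lattice!r}")
        if self.lattice != "thresholded_random_field":
            if not 0 < self.thickness < self.period:
                raise ParameterError(
                    f"need 0 < thickness < period, got {self.thickness}, {self.period}"
                )
        if not 0 < self.fill_fraction < 1:
            raise ParameterError("fill_fraction must lie in (0, 1)")
        if self.blur_fwhm_mm < 0 or self.noise_sigma < 0:
            raise ParameterError("blur and noise must be non-negative")


class TrabecularTruth(NamedTuple):
    """Analytic morphometry of a generated lattice (NaN where undefined)."""

    bvtv: float
    tb_th_mm: float
    tb_sp_mm: float
    tb_n_per_mm: float


class TrabecularPhantom(NamedTuple):
    gray: VolumeGrid
    truth_binary: VolumeGrid
    voi: VolumeGrid
    truth: TrabecularTruth


def _plate_lattice(spec: TrabecularPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    th, per = spec.thickness, spec.period
    offset = (per - th) // 2  # keep plates away from the z faces
    nz = spec.shape[2]
    z = np.arange(nz)
    plate = (z >= offset) & (((z - offset) % per) < th)
    binary = np.broadcast_to(plate[None, None, :], spec.shape).copy()
    n_full = (nz - offset - th) // per
    if n_full < 1:
        raise ParameterError("volume too short for one full lattice period")
    voi = np.zeros(spec.shape, dtype=bool)
    voi[:, :, offset : offset + n_full * per] = True
    return binary, voi


def _rod_lattice(spec: TrabecularPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    # square-section rods along z on a periodic xy grid
    th, per = spec.thickness, spec.period
    offset = (per - th) // 2
    ix = np.arange(spec.shape[0])
    iy = np.arange(spec.shape[1])
    in_x = (ix >= offset) & (((ix - offset) % per) < th)
    in_y = (iy >= offset) & (((iy - offset) % per) < th)
    binary = np.zeros(spec.shape, dtype=bool)
    binary[np.ix_(in_x.nonzero()[0], in_y.nonzero()[0], np.arange(spec.shape[2]))] = True
    nx_full = (spec.shape[0] - offset - th) // per
    ny_full = (spec.shape[1] - offset - th) // per
    if nx_full < 1 or ny_full < 1:
        raise ParameterError("volume too small for one full lattice period")
    voi = np.zeros(spec.shape, dtype=bool)
    voi[offset : offset + nx_full * per, offset : offset + ny_full * per, :] = True
    return binary, voi


def _random_field(spec: TrabecularPhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    field_ = rng.normal(size=spec.shape)
    field_ = ndimage.gaussian_filter(field_, sigma=max(spec.period / 4.0, 1.0))
    thr = np.quantile(field_, 1.0 - spec.fill_fraction)
    return field_ > thr, np.ones(spec.shape, dtype=bool)


def make_trabecular_phantom(spec: TrabecularPhantomSpec) -> TrabecularPhantom:
    """Binary lattice + grayscale rendering + analytic truth biomarkers.

    The grayscale volume is the binary truth blurred by an isotropic Gaussian
    (sigma = FWHM/2.3548, a point-spread-function proxy) with additive
    Gaussian noise.  Analytic Tb.Th/Tb.Sp are defined for plates; rods carry
    an analytic thickness only; the random field carries its fill fraction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sx = float(spec.spacing[0])

    if spec.lattice == "parallel_plates":
        binary, voi = _plate_lattice(spec)
        bvtv = spec.thickness / spec.period
        tb_th = spec.thickness * sx
        tb_sp = (spec.period - spec.thickness) * sx
        truth = TrabecularTruth(bvtv, tb_th, tb_sp, bvtv / tb_th)
    elif spec.lattice == "orthogonal_rods":
        binary, voi = _rod_lattice(spec)
        bvtv = (spec.thickness / spec.period) ** 2
        tb_th = spec.thickness * sx
        truth = TrabecularTruth(bvtv, tb_th, float("nan"), bvtv / tb_th)
    else:
        binary, voi = _random_field(spec, rng)
        truth = TrabecularTruth(spec.fill_fraction, float("nan"), float("nan"), float("nan"))

    gray = binary.astype(float)
    if spec.blur_fwhm_mm > 0:
        sigma_vox = [spec.blur_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
        gray = ndimage.gaussian_filter(gray, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0.0, spec.noise_sigma, gray.shape)

    return TrabecularPhantom(
        VolumeGrid(gray, spec.spacing),
        VolumeGrid(binary, spec.spacing),
        VolumeGrid(voi, spec.spacing),
        truth,
    )


# --------------------------------------------------------------------------
# ordinal score datasets
# --------------------------------------------------------------------------

@dataclass
class ScoreSimSpec:
    """Balanced factorial design with planted cell effects.

    ``cell_effects`` maps ``(group_level, time_level)`` to a location shift
    of the latent response; noise is standard normal.  With
    ``noise='ordinalized'`` the latent value is rounded and clipped to stages
    ``0..n_stages-1``, emulating ordinal severity scores.
    """

    levels_a: Sequence[str] = ("CTR", "CGH", "CGH-NC")
    levels_b: Sequence[int] = (24, 56, 84)
    n_per_cell: int = 6
    cell_effects: dict = field(default_factory=dict)
    noise: str = "normal"
    n_stages: int = 5
    variable: str = "score"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise ParameterError("n_per_cell must be >= 2")
        if self.noise not in ("normal", "ordinalized"):
            raise ParameterError(f"unknown noise kind {self.noise!r}")
        if self.n_stages < 2:
            raise ParameterError("need at least 2 ordinal stages")
        if len(self.levels_a) < 1 or len(self.levels_b) < 1:
            raise ParameterError("both factors need at least one level")


def make_ordinal_score_dataset(spec: ScoreSimSpec) -> list[ScoreRecord]:
    """Simulate a balanced group x time score dataset.

    Returns ``n_per_cell`` records per cell; identical seeds give identical
    records.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[ScoreRecord] = []
    subject = 0
    for a in spec.levels_a:
        for b in spec.levels_b:
            shift = float(spec.cell_effects.get((a, b), 0.0))
            latent = shift + rng.normal(size=spec.n_per_cell)
            if spec.noise == "ordinalized":
                values = np.clip(np.round(latent), 0, spec.n_stages - 1)
            else:
                values = latent
            for v in values:
                records.append(
                    ScoreRecord(f"S{subject:03d}", str(a), int(b), spec.variable, float(v))
                )
                subject += 1
    return records
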