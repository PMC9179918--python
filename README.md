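# jointqmri

Quantitative MRI biomarkers of joint health for small-animal osteoarthritis
studies: voxel-wise T1/T2 relaxometry of articular cartilage, six-segment
cartilage morphometry, subchondral trabecular bone morphometry (BV/TV,
Tb.Th, Tb.Sp, TbN, 2D/3D box-counting fractal dimensions), and the robust
trimmed-means factorial statistics used to compare treatment groups over
survival time — all driven by a synthetic phantom generator with analytic
ground truth, so the whole pipeline is testable without scan data.

The intended user is an imaging scientist analysing co-registered NIfTI
stacks from a knee/stifle protocol (e.g. a rabbit cruciate-ligament
transection model of osteoarthritis), or anyone who needs a reproducible,
phantom-validated implementation of these biomarkers.

## The quantities computed

**Cartilage relaxometry.** T1 from spoiled-gradient-echo signals at several
excitation flip angles, using the classic linearization of the SPGR
steady-state equation

    S(α) = M0 sin α (1 − E1) / (1 − E1 cos α),   E1 = exp(−TR/T1):

with y = S/sin α and x = S/tan α this is a line with slope E1, so
T1 = −TR/ln(slope) per voxel. T2 from a multi-echo stack by weighted
log-linear least squares of ln S(TE) = ln S0 − TE/T2 (weights S², which
approximates nonlinear least squares under additive noise). Fits are
strictly voxel-independent; implausible or unidentifiable voxels are
flagged, not silently kept.

**Cartilage morphometry.** Six-segment parcellation of each articular
surface (medial/lateral × anterior/central/posterior: TM, TL, CM, CL, PM,
PL), per-segment volume (voxel count × voxel volume), and thickness as
2 × the Euclidean distance transform sampled on the mask's medial surface.

**Bone morphometry.** Laplacian-sharpened Otsu binarization within a volume
of interest, then BV/TV (bone voxels / VOI voxels), Tb.Th and Tb.Sp (2×EDT
on the medial surface of the bone and marrow phases), TbN = BV/TV / Tb.Th,
and box-counting fractal dimensions D2D (per-slice average) and D3D.

**Statistics.** Wilcox's heteroscedastic two-way ANOVA for 20%-trimmed
means with interaction (Johansen-type Q statistics from cell trimmed means
and winsorized variances; p-values by exact inversion of the adjusted
chi-square critical value), two-sample t-test power analysis on the
noncentral t distribution and its inverse (effect size for a target power),
median/min/max/IQR descriptives, and ordinal stage-frequency tables for
severity heat maps.

## Worked example

Everything below is computed, not transcribed. The demo pipeline simulates
a two-region cartilage phantom and a parallel-plate trabecular phantom,
fits the maps, and runs the statistics:

```python
from jointqmri.pipeline import run_pipeline
report = run_pipeline(seed=7)
print(report["bone"])
```

prints (plate lattice: thickness 2 voxels, period 10, 0.1 mm voxels)

```
{'bvtv': 0.2, 'tb_th_mm': 0.19999999999999998, 'tb_sp_mm': 0.7999999999999999,
 'tb_n_per_mm': 1.0000000000000002, 'd2d': 1.1917..., 'd3d': 2.1380..., 'voi_label': 'medial'}
```

i.e. the analytic lattice truths BV/TV = 2/10 = 0.2, Tb.Th = 2 × 0.1 mm,
Tb.Sp = 8 × 0.1 mm and TbN = BV/TV / Tb.Th = 1.0 mm⁻¹ are recovered from
the blurred, noisy grayscale rendering; the fractal dimensions of a plate
lattice sit between those of a line/plane and of a filled slice/volume, as
they should.

The study-design power calculation (12 subjects per group, α = 0.05,
two-sided, target power 0.8):

```sh
$ jointqmri stats power --n 12
{"n_per_group": 12, "alpha": 0.05, "power": 0.8,
 "effect_size_d": 1.1968119137532305, "power_check": 0.8}
```

— a standardized effect size d ≈ 1.2: with 12 subjects per group, only
effects larger than about 1.2 pooled standard deviations are detectable at
80% power.

The same CLI exposes the other stages (`jointqmri simulate cartilage|bone|scores`,
`fit-t1`, `fit-t2`, `cartilage`, `bone`, `stats anova|describe|stages`, `run`).

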