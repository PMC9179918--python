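# Methods

This note documents the models and numerical conventions implemented in
`jointqmri`, the parameters that matter, what the synthetic phantoms do and
do not emulate, and the design choices made where several conventions were
defensible.

## Signal models and relaxometry fits

**SPGR / variable flip angle (T1).** The spoiled-gradient-echo steady state
is S(α) = M0 sin α (1 − E1)/(1 − E1 cos α) with E1 = exp(−TR/T1). The fit
linearizes: y = S/sin α against x = S/tan α is a line with slope E1 and
intercept M0(1 − E1); ordinary least squares per voxel, then
T1 = −TR/ln(slope), M0 = intercept/(1 − slope). A voxel is valid only when
the slope lies in (0, 1) (otherwise E1 is unphysical) and the resulting T1
falls in the plausibility window [50, 10000] ms. Default flip angles for
the phantom generator are 2, 5, 10, 15, 25, 45°; TR is a required input —
it is never assumed.

**Multi-echo decay (T2).** S(TE) = S0 exp(−TE/T2), fitted by log-linear
least squares of ln S on TE with weights S². The weights undo the
heteroscedasticity introduced by the log transform: for additive noise,
var(ln S) ≈ σ²/S², so weighting by S² recovers (to first order) the
nonlinear least-squares solution. Echoes with non-positive signal are
dropped per voxel; at least 3 usable echoes are required. Non-decaying
voxels are invalid; T2 plausibility window [1, 1000] ms. The default echo
ladder is the 16 times 2.7–23.7 ms in 1.4 ms steps; echo times are in ms
throughout.

Both fits are strictly voxel-wise: no spatial regularization, no B1
correction, no multi-component decay. Spatial registration of the
acquisitions is a precondition — inputs must already share a grid — since
registration is well served by dedicated external tools.

## Thickness by distance-transform ridge

Thickness of a binary phase (cartilage mask, bone phase, marrow phase) is
2 × the Euclidean distance transform (EDT), averaged over the phase's
medial surface. The medial surface is computed as the *ridge* of the EDT:
voxels whose EDT equals the maximum over their 3×3×3 neighbourhood.

The ridge is used instead of topological thinning deliberately: 3D thinning
produces curve skeletons, which collapse plate-like structures to their
rims — a 2-voxel-thick plate thins to (almost) nothing and its sampled
thickness is undefined. The EDT ridge retains the medial sheet of plates
and the axis of rods, so the parallel-plate lattice recovers its analytic
thickness exactly (plate of t voxels at spacing s → Tb.Th = t·s).

Anisotropic spacing is respected by the EDT directly for cartilage; for
bone morphometry the volume is first resampled (nearest-neighbour) to the
finest spacing, because the ridge/EDT combination on strongly anisotropic
grids biases Tb.Th. EDT distances are measured to the nearest background
*voxel centre*, so a slab of t voxels reads (t + 1)·s at the ridge; this
half-voxel-per-side overshoot is within the half-voxel tolerance quoted
for all thickness results and is not corrected, to keep the plate-lattice
truths exact.

A mask that fills its entire volume has no background and no defined
thickness; this raises an error rather than returning an arbitrary number.

## Cartilage parcellation

Six segments per articular surface: medial/lateral crossed with
anterior/central/posterior (TM, TL, CM, CL, PM, PL; T = anterior,
C = central, P = posterior, M/L = medial/lateral). The medial–lateral
boundary sits at the mask centroid along the ML axis by default; an
`ml_split="midline"` option uses the image midline instead, which is
preferable when disease has removed cartilage from one side (the centroid
of a one-sided mask lies inside it, which would re-split the remnant).
The anterior/central/posterior cuts are equal thirds of the mask's
bounding extent along the AP axis — a declared convention; no anatomical
boundary rule is imposed. Axes are identified by orientation tags
("ML", "AP", "SI"), voxel coordinates are 0-based indices, and world
coordinates follow the NIfTI affine. Every mask voxel receives exactly one
label; empty segments are reported, not errors.

## Bone binarization and morphometry

Binarization sharpens with the kernel-normalized discrete Laplacian,
`sharp = gray − λ·∇²gray/(2·ndim)` (λ default 1.0), then thresholds by
Otsu's criterion within the VOI. Normalizing the Laplacian keeps the
overshoot at edges bounded so the sharpened histogram stays bimodal; the
un-normalized operator at λ = 1 creates overshoot rings strong enough to
form a third histogram mode and destabilize the threshold. The Otsu
threshold itself is computed exactly over the distinct sample values
(between-class variance via prefix sums) rather than on a binned
histogram: synthetic volumes concentrate large point masses on single
values, and a point mass on a bin edge can be misassigned by binned
implementations. An `inverted` flag handles acquisitions where bone is
dark.

BV/TV is the voxel-count ratio bone/VOI. Tb.Th and Tb.Sp are the
ridge-sampled 2×EDT of the bone and marrow phases (marrow sampled within
the VOI, so gaps truncated by the volume faces are not sampled), and
TbN = BV/TV / Tb.Th by definition, so TbN·Tb.Th = BV/TV holds identically.

## Box-counting fractal dimensions

Box edges are powers of three (1, 3, 9, …) capped at ⌊min dim/3⌋; when
more than three scales are available the coarsest is dropped; at least
three scales must remain or the fit is refused as under-determined. The
dimension is minus the OLS slope of log N(ε) on log ε, where N counts boxes
containing structure voxels ("area" mode, the default for trabecular
architecture) or structure-boundary voxels ("boundary" mode). The triadic
ladder is exact on grid-aligned self-similar sets: a filled 81³ cube gives
3.000, the 5-iteration Sierpiński carpet gives log 8/log 3 = 1.8928, the
3-iteration Menger sponge log 20/log 3 = 2.7268. A dyadic ladder was
evaluated and rejected: its lattice misalignment with triadic structure
under-reads the carpet by ≈0.12 and the sponge by ≈0.4, errors inherent to
the grid mismatch (offset-minimizing counts do not repair them). The
coarsest scale is excluded because at box edges comparable to the
structure extent corner-merging dominates (a square's perimeter reads
≈1.11 with the coarsest scale, ≈1.03 without). D2D is the mean over slices
(perpendicular to a chosen axis) that contain structure; D3D uses 3D
boxes. Whether a per-slice average or a projection is "the" 2D dimension
is a convention; the per-slice average is used here.

## Robust factorial statistics

For a J×K design with trim fraction γ (default 0.2, the convention of the
robust-statistics literature), each cell contributes its trimmed mean
(discard ⌊γn⌋ order statistics per tail), its winsorized variance (clamp
the same order statistics), and h = n − 2⌊γn⌋. The squared standard error
of a cell trimmed mean is v = (n−1)s²_w / (h(h−1)). Main effects and the
interaction are tested with Johansen-type quadratic forms
Q = (Cm)'(C V C')⁻¹(Cm) using difference-contrast matrices (Kronecker
products of adjacent-difference and averaging vectors). The critical value
is the chi-square quantile q adjusted as c = q + q/(2k)·A·(1 + 3q/(k+2)),
A = Σ R_jj²/(h_j−1), R = V C'(C V C')⁻¹C; since c is quadratic in q the
p-value is obtained by exact inversion rather than grid search. With
γ = 0 the procedure reduces exactly to the classical heteroscedastic
(Welch–Johansen) factorial ANOVA — verified against an independently coded
oracle. An optional seeded percentile bootstrap (cells centred at their
trimmed means) provides a second route to p-values.

Calibration, measured by simulation (3×3 design, n = 6/cell, normal null):
empirical type-I error at α = 0.05 is 0.035–0.061 across seeds at 2000
replicates for all three effects. The adjusted-critical-value
approximation leaves a small systematic deviation from p-value uniformity
(Kolmogorov–Smirnov statistic ≈ 0.013 at 10⁴ replicates for these small
cells); it is below the KS detection threshold at 2000 replicates, where
uniformity is asserted on the pooled effects. Degenerate inputs (a
single-level factor, an empty cell, all-zero winsorized variances) raise
errors naming the offending cell rather than returning a meaningless
statistic.

**Power / effect size.** Two-sample t-test power is
P(reject | t' ~ noncentral t(df = 2n−2, ncp = d√(n/2))) for the stated
sidedness; the inverse (effect size achieving a target power) is solved by
monotone root finding (Brent) with inverse consistency to 10⁻⁶. At
n = 12/group, α = 0.05, power = 0.8 (two-sided), d = 1.1968 ≈ 1.2; the
target power of 0.8 corresponds to a type-II error β = 0.2. Agreement with
R's `power.t.test` was confirmed at build time to 5 decimals. Pre-tests of
normality and homoscedasticity (Shapiro–Wilk, Levene) are delegated to
scipy and merely reported.

**Descriptives and stage tables.** Summaries are median, min, max and IQR
(linear-interpolation quantiles), matching the reporting style for ordinal
severity data. Stage-frequency tables count each ordinal stage per
(group, time) cell (counts conserve n exactly; optional row-normalized
frequencies), the tabular form behind severity heat maps. A packaged CSV
of measured synovial-fluid hyaluronic-acid concentrations (ng/mL, per
group and sampling day) ships as a small real-data fixture for these
operations.

## Synthetic phantoms: what they emulate, what they do not

The cartilage phantom renders the two closed-form signal equations
region-by-region (slab regions along z inside a signal-free margin), with
per-voxel ground-truth T1/T2/M0 maps. Noise is Rician by default — the
magnitude of a complex Gaussian perturbation, the correct model for
magnitude MRI, with its positive bias at low SNR — with a Gaussian option
for linear-fit unit tests. There is no k-space simulation, no B1
inhomogeneity, no slice profile, no partial-volume mixing at region
boundaries: passing tests demonstrate estimator correctness under the
stated signal + noise model, not robustness to acquisition artefacts.

The trabecular phantom builds parallel plates (normal to z, inset from the
volume faces so the analytic VOI contains only whole, face-free periods),
orthogonal square-section rods, or a thresholded smoothed Gaussian random
field at a target fill fraction. Plate truths are exact by construction:
BV/TV = thickness/period, Tb.Th = thickness·spacing,
Tb.Sp = (period−thickness)·spacing, TbN = 1/(period·spacing). The
grayscale rendering is the binary truth blurred by an isotropic Gaussian
point-spread proxy (σ = FWHM/2.3548) plus additive noise. Real trabecular
bone is neither periodic nor plate-pure; the phantom validates the
measurement chain, not biological realism.

The score simulator produces balanced group × time designs (defaults: 3
treatment groups × 3 survival times × 6 per cell, the canonical layout of
a small-animal intervention study) from a latent normal with planted
per-cell location shifts, optionally discretized to ordinal stages by
rounding and clipping. All generators are deterministic given their seed.

## Problem sizes and numerical conventions

Simulation-backed tests use: 1024 voxels for noisy relaxometry recovery
(150-voxel nonlinear least-squares cross-check), 2000 replicates for ANOVA
null calibration, 100 random masks for parcellation conservation, 10⁵
replicates for the Monte-Carlo power oracle — sizes chosen so each claim's
tolerance is resolvable by its Monte-Carlo error. Quantiles use linear
interpolation; trimming counts are ⌊γn⌋ per tail; ties in Otsu's criterion
resolve to the first maximizing cut; the parcellation's medial side is the
low-index side of the ML axis. NIfTI I/O preserves data bit-exactly and
spacing to 10⁻⁶ mm; acquisition parameters travel in JSON sidecars
(RepetitionTime, FlipAngles, EchoTimes) because NIfTI headers cannot carry
them.

## Known limitations

- T1 estimation ignores B1 (flip-angle) miscalibration, a dominant error
  source at high field in vivo.
- Mono-exponential T2 underfits cartilage's multi-compartment decay.
- The Rician-noise T2 fit inherits the magnitude-noise floor bias at low
  SNR; the weighted log-linear fit mitigates but does not remove it.
- Thickness via EDT ridge overshoots by up to half a voxel per side by
  construction.
- Box-counting dimensions are grid-convention-dependent; values are
  comparable within this package's convention, not across packages.
- The trimmed-means ANOVA p-values rest on an asymptotic adjustment whose
  small-sample deviation, while measured and small, is nonzero (see
  calibration above); the bootstrap mode is the fallback when exactness
  matters.
- The patented single-score trabecular quality index is not computed (no
  public formula).
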