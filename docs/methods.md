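# Methods

## Signal model

The control-minus-label difference at an arterial voxel is modelled as a
two-piece saturation curve of the label duration `t`: zero before the
leading edge of the label bolus arrives, then a hyperbolic rise toward a
plateau. The breakpoint `b` is interpreted as the macrovascular arterial
transit time; `m` is the plateau (saturation) level in signal units; `h`
is the half-rise time in ms. Two branch forms are implemented:

- **literal**: `f(t) = m·t/(h+t)` for `t > b`. The saturating branch does
  not depend on `b`, so the model is discontinuous at the breakpoint and
  `b` is identifiable only up to the interval between adjacent sample
  times: every `b` in `(t_k, t_{k+1}]` produces identical residuals. Ties
  are broken toward the smallest `b` (earliest arrival), which makes the
  fit deterministic and conservative.
- **continuous**: `f(t) = m·(t−b)/(h+(t−b))` for `t > b`. The saturation
  origin shifts with the breakpoint, residuals vary smoothly in `b`
  between sample times, and noiseless curves are recovered exactly. This
  branch is translation-equivariant: shifting all times and `b` jointly
  leaves residuals unchanged.

The literal form is the package default for single-curve fits; the
synthetic studies and the pipeline default use the continuous form because
only it supports sub-sample breakpoint recovery. Both are exposed
everywhere via `variant=`.

## Fitting algorithm

Per curve, the sum of squared residuals is profiled on a breakpoint grid
(default step 10 ms) over `[0, b_max]`; for each candidate `(b, h)` pair
the amplitude is linear with closed form `m = Σy·g / Σg²` (clipped at 0),
so the whole grid reduces to one matrix product per batch of curves. The
half-rise grid is geometric (80 points over `[1, 2·10⁴]` ms). The best
candidate of the winning inter-sample interval — and of its two
neighbours, because a coarse `h` grid can misrank adjacent intervals when
a sample sits barely above the true breakpoint — is then polished by
bounded trust-region least squares with an analytic Jacobian, each polish
confined to its interval so the active sample set stays fixed. The best
polished solution wins; residual ties go to the smallest breakpoint.

`b_max` defaults to the last sample time plus the final inter-sample gap
(2800 ms for the 100–2200 ms schedule), admitting arrival later than the
last label duration. Fits are unweighted. A curve whose maximum is below
the noise floor — default 2 × 1.4826·MAD of the first-time-point
difference signal over non-vessel brain voxels, i.e. twice the robust
noise sd where no signal can yet have arrived — is flagged `below_noise`
and excluded from maps. `r2 = 1 − SSE/SStot` is clipped to `[0, 1]`.

With the 8-point schedule, information about the breakpoint is limited by
the 400–600 ms inter-sample gaps: on raw single curves at SNR 10 even an
exhaustive 1 ms-grid search attains an RMSE of ~180 ms. Reliable per-voxel
recovery therefore depends on the edge-preserving smoothing stage, which
averages each vessel voxel's curve with its same-class neighbours and
brings the RMSE to ~50–70 ms at SNR 10.

## Vessel isolation

The cascade follows: subtraction → brain masking → temporal-maximum image
→ slice-wise 2D Frangi vesselness in the XY, YZ and ZX planes →
binarization of each directional response at 0.05 × its own maximum →
voxel-wise AND → area opening → guided bilateral smoothing.

Vesselness uses Gaussian-derivative Hessians normalised by σ² so responses
are comparable across scales (a Gaussian ridge of sd `t` then peaks at
σ = √2·t, the standard γ=2 ridge-selection result). With `|λ1| ≤ |λ2|`,
vesselness is 0 where `λ2 ≥ 0` and otherwise
`exp(−R_B²/2β²)·(1−exp(−S²/2c²))`, `R_B = λ1/λ2`, `S = √(λ1²+λ2²)`.
Defaults: scales {1, 1.5, 2, 3} px, β = 0.5, and `c` set per slice to half
the maximum Hessian norm across all scales. The temporal-maximum image
feeds the filter because it maximises distal-vessel contrast.

Area opening removes connected components below `min_size` (library
default 50 voxels, 26-connectivity). The parameter is meant to be tuned
per dataset: on the 64³ demo phantom the vessel tree forms a single
component of ~8–14 k voxels while blob and noise clusters stay below
~500, so the demo configuration uses 1000 — separation holds with a wide
margin across seeds.

Smoothing is a joint bilateral filter per time point: spatial Gaussian
with sd = FWHM/(2√(2 ln 2)) per axis (default FWHM 5×5×4 voxels, chosen to
approximate large intracranial vessel diameters), range Gaussian on the
*guide* image — the binary vessel mask — so values do not mix across the
vessel/background boundary; weights are renormalised per voxel, making the
filter exact identity on constants and free of over/undershoot. For a
binary guide the filter reduces to two separable blurs blended per class,
which is the fast path; arbitrary grayscale guides use a direct windowed
evaluation.

## Atlas projection and statistics

Regional projection assigns the unweighted mean of the defined arterial
voxels inside each label to the entire region; regions with fewer than
`min_voxels` (default 5) defined voxels stay undefined. The
voxel-count-weighted mean of the regional means equals the global defined
mean exactly, and projecting a filled map is idempotent — both are tested
identities. Pre/post difference tables use the post − pre convention
(vasodilation → negative Δ). The common-mask correction restricts both
maps to voxels defined in both scans and in the pre-scan vessel mask, so
deltas are not inflated by distal vessels that only become visible after
vasodilation.

Slice profiles average defined voxels per slice (or per group of slices;
group means of a linear profile leave the regression slope unchanged, so
both conventions are supported). Distance is measured from the centre of
the most caudal slice. The distance regression is ordinary least squares
on the slice means with `adj R² = 1 − (1−R²)(n−1)/(n−2)`; an optional
distance window can censor oscillatory segments (e.g. near the carotid
siphon), and voxel-count weighting is available behind a flag. ROI
correlation uses pairwise-complete regions, Pearson r, and a two-sided p
from the t distribution with n−2 df; no multiple-testing correction is
applied.

## Synthetic data

The generator emulates the statistical structure the estimator relies on,
not MR physics. Walkers grow a branching tree from the most caudal slice
with persistent direction, gentle curvature, cranial drift, and inward
steering near the brain-ellipsoid boundary; a tube of tapering calibre
(~3 voxels across proximally, ~1 distally) is painted around each
centreline. The true breakpoint is `b0 + gradient × path_distance` (mm of
arc length), so arrival is monotone along every path; defaults `b0 = 650`
ms, `gradient = 7.7` ms/mm, 8 label durations 100–2200 ms, voxel pitch
0.6×0.6×0.8 mm, 64³ volume. Amplitude tapers from `m0 = 10` toward
`m_min = 3` with distance (distal vessels are fainter); `h = 400` ms;
noise is additive Gaussian on the difference signal inside the brain with
`noise_sigma = 1` (SNR ≡ m/noise_sigma = 10 proximally). Ellipsoidal blob
artifacts (~8–90 voxels) are placed within the 8 most caudal slices to
exercise area opening. A straight-tube variant (`generate_tube_phantom`)
provides an unambiguous geometry for filter-retention measurements.
Because `gradient` is per mm of path length while the slice regression
measures ms per axial mm, the phantom's true axial slope is
`gradient × mean(∂path/∂z)` (≈1.2 × gradient for the default tree);
recovery is therefore always judged against the truth's own axial
slice-profile slope.

What the phantom does not model: label T1 decay, labelling efficiency,
keyhole/view-sharing reconstruction artifacts, flow velocity profiles,
motion, and real vascular anatomy. Passing recovery tests therefore shows
the estimator chain is correct and noise-robust under the stated SNR and
geometry, not that clinical accuracy matches any in-vivo figure.

Reported synthetic conditions for the headline checks: 64³ volumes at SNR
10 with uniform amplitude (`m_taper = 0`, so the stated SNR holds along
the whole tree), path gradients 7.7 and 6.6 ms/mm, breakpoint fits on the
smoothed series, 500–800-voxel fitting subsets where only the fitter is
under test. These sizes keep the full suite and the acceptance script
within a few minutes on one CPU while leaving tolerances comfortably
non-trivial.

## Numerical choices and edge cases

- FWHM ↔ sd conversion fixed at `FWHM = 2√(2 ln 2)·sd`; kernel extents in
  mm are the element-wise product of voxel FWHM and stated voxel pitch
  (no hidden reconstructed-pitch corrections).
- Voxel indices are 0-based; slice 0 is the most caudal slice; mm
  distances are measured from its centre.
- Label durations live in the pipeline configuration, not NIfTI headers;
  arrival-time input maps with all finite values below 20 are interpreted
  as seconds and converted to ms (logged, overridable).
- Degenerate fits: constant curves and sub-noise-floor curves are
  `below_noise`; optimiser failure is `fail`; maps are NaN outside ok
  voxels and all-NaN inputs raise.
- `matt_total` is the maximum over defined voxels, with an optional
  percentile for robustness against isolated outliers.
- Brain-mask editing (e.g. eye-region artifact removal) is accepted as
  user input rather than automated; a simple intensity-threshold fallback
  builds a mask when none is supplied.

## Known limitations

- The printed form of the saturation model is ambiguous about whether the
  saturating branch is shifted by the breakpoint; both readings are
  implemented and neither is asserted as canonical.
- Atlas registration is out of scope: region labels must already be on the
  acquisition grid (an identity-transform path).
- Regional means weight through-passing and terminating vessels equally.
- With the literal branch, breakpoints are interval-censored by the sample
  schedule; densifying late sample times is the only remedy.
- The area-opening size is dataset-dependent by design; defaults are
  calibrated for the bundled phantoms only.
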