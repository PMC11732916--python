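# Methods

## Model and measurement equation

The package analyses dynamic FDG data under the two-tissue compartment
model with plasma input Cp(t), free/transported pool C₁ and trapped
(phosphorylated) pool C₂:

    dC₁/dt = K₁·Cp − (k₂+k₃)·C₁ + k₄·C₂
    dC₂/dt = k₃·C₁ − k₄·C₂
    C_T(t) = (1−v_B)·(C₁+C₂) + v_B·Cp(t)

Units: K₁ in mL/ccm/min, k₂–k₄ in 1/min, v_B unitless; all activities
in SUV, assumed decay-corrected. k₄ = 0 by default (irreversible
trapping), which is the regime in which the Patlak comparison is
meaningful; a k₄-free mode exists but is not the default. The derived
net influx is K_i = K₁·k₃/(k₂+k₃).

Two exact consequences of the measurement equation shape everything
downstream and are worth stating explicitly. Integrating the C₁
equation gives C₁+C₂ = K_i·∫Cp + (k₂/(k₂+k₃))·C₁, hence

    C_T/Cp = (1−v_B)·K_i·x + (1−v_B)·(k₂/β)·(C₁/Cp) + v_B,   β = k₂+k₃.

(1) The Patlak slope of the *measured* TAC converges to **(1−v_B)·K_i**,
not K_i — the blood-volume fraction scales the tissue signal and cannot
be removed without a compartment fit. (2) The plot is linear only once
C₁/Cp is constant, i.e. after the transient e^(−βt) has died *and* the
input tail is effectively mono-exponential. Windows that include early
frames therefore acquire a bias for slow tissues whose sign depends on
the interplay of the early deficit and the mid-time overshoot of C₁/Cp.
The long 59.25-min window starts at 45 s by construction, so this bias
is part of what the STI/LTI comparison measures; the package reports
slopes as-is and never "corrects" them.

## Forward solution and fitting

For piecewise-linear Cp the compartment responses are exponentials
convolved with the input, and on a uniform grid the per-step update has
a closed form (stable `expm1` kernels, with series limits at β→0, and a
two-exponential combination when k₄>0). The only discretisation error
is the piecewise-linear representation of Cp itself: at the default
0.5-s step, frame averages of a bolus-shaped input are accurate to
~1e-7 relative; the test suite verifies ≤1e-6 agreement with an
independent stiff LSODA integration across the whole tissue library at
a 0.02-s step. Frame values are interval averages of the continuous
curve (how scanners bin counts); mid-point sampling is an option.
Sampled input curves are interpolated linearly through the (0,0)
injection anchor and frame mid-times and held flat beyond the last mid.

The VOI fit (`TwoTissueModel`) is weighted nonlinear least squares
(Levenberg–Marquardt) under a "first fit" convention: one descent from
fixed initial values v_B=0.05, K₁=0.1, k₂=0.1, k₃=0.01, stopped by
whichever comes first of 200 iterations or a 1e-6 relative chi-square
change, with no parameter restrictions in the default mode (a
nonnegative bounded mode exists for production use). A non-finite
objective raises a fit error carrying the last finite iterate rather
than returning garbage. Standard errors come from the Gauss–Newton
covariance at the optimum. Weights are uniform by default;
frame-duration weighting is available (a crude count-statistics
surrogate). Delay/dispersion between input and tissue is not fitted.
Voxel-wise compartment maps are deliberately not produced; the
compartment analysis is VOI-level, with the Patlak maps carrying the
voxel-wise burden.

The Patlak fit (`PatlakModel`) is weighted linear least squares on the
transformed coordinates, with frames excluded when Cp ≤ 1e-6 SUV
(guard, not regularisation); fewer than three usable frames is an error
at VOI level and NaN at voxel level, so a bad window never aborts a
volume. Negative slopes are reported as-is — clamping would bias the
contrast comparisons. Window presets select frames by count, exactly
as acquired: STI = last six frames, LTI = all but the first three; a
generic t* option maps a minute value to the first frame whose mid-time
reaches it. Voxel-wise maps evaluate the same weighted line in closed
form across the grid at once (the plasma guard is frame-level, so all
voxels share the usable-frame set).

## Input function

The image-derived input is the plain per-frame voxel mean of the
blood-pool VOI, used as plasma directly — no plasma/whole-blood ratio,
no metabolite correction, no delay correction. The running plasma
integral (the Patlak abscissa numerator) is the trapezoid through the
(0,0) anchor and the frame mid-time points; finer intra-frame
reconstruction would be false precision. On the default synthetic
bolus this trapezoid is ~0.7% low around 5 min (the peak-area deficit
of the 15-s frames), decaying below 0.5% past ~10 min as the running
integral grows; the bias is common to every tissue fitted against the
same input.

## Synthetic phantoms

`synthetic` generates the data the analysis assumes. The arterial
input is a Feng-type tri-exponential with linear rise,
Cp(t) = (A₁t−A₂−A₃)e^(−λ₁t) + A₂e^(−λ₂t) + A₃e^(−λ₃t), with defaults
A = (57.6, 4.46, 13.68) SUV, λ = (1.5, 0.008, 0.95) /min: a single
bolus peak of ~19 SUV at ~45 s and a 60-min tail at ~14% of peak. The
middle exponential is deliberately fast (gone by ~8 min) so the late
tail is mono-exponential — the condition under which late-window Patlak
slopes converge cleanly to the apparent influx; it also gives liver a
small negative LTI bias, which is the mechanism behind the long
window's improved tumor-to-liver contrast.

Tissue ground truth is a library of population-mean rate constants for
liver, kidney, spleen, lung, muscle, bone and a typical tumor lesion
(k₄=0); inter-subject variability can be drawn as mean-preserving
log-normal jitter on the rates (population SD/mean as coefficient of
variation) with v_B jittered additively and clipped to [0,1]. The
default phantom voxelises axis-aligned ellipsoids on a 48×48×96 grid of
1.65-mm voxels — an aorta cylinder, six organs and six tumor spheres —
small enough that voxel-wise mapping runs in seconds while every region
still holds enough voxels for stable means. Noise is zero-mean
Gaussian with variance scale·max(v, floor)/Δt_min (scale 0.3 SUV·min,
floor 0.01 SUV), i.e. growing with activity and shrinking with frame
duration — the leading-order behaviour of count-limited reconstruction
noise, chosen to make the short-window maps visibly noisier than the
long-window ones (~7–17% per voxel on late frames). What the phantom
does *not* emulate: anatomical texture, partial-volume and spill-over,
scanner PSF/TOF effects, attenuation/scatter residuals, motion, or
correlated reconstruction noise. Passing recovery tests therefore
demonstrates the correctness of the estimators under their own
statistical assumptions, not clinical performance.

## Numerical and design choices

- Masks must share the image grid exactly; no resampling anywhere.
- NaN marks failed voxels in parametric maps; inputs must be finite.
- Wilcoxon signed-rank drops zero differences before ranking; exact
  null for n ≤ 25 without ties, otherwise normal approximation with tie
  correction. Spearman uses tie-corrected ranks. The tumor-vs-organ
  comparison defaults to Welch's unequal-variance t-test (a pooled
  option exists). No multiple-testing correction is applied.
- For VOI-level compartment parameters only TBR_mean is defined (a
  single fitted value has no max or SD); the background SD in CNR is
  the liver VOI's voxel SD in the same image type.
- Protocol presets are built-in: the window names "sti"/"lti" and the
  FitSettings defaults constitute the replication configuration; phantom
  and run specs serialise to YAML/JSON for custom studies.
- Pipeline runs are deterministic under a fixed seed; the manifest
  records the config hash, seed and per-stage timings.

## Known limitations

- The Patlak slope estimates (1−v_B)·K_i; comparisons against the
  compartment K_i must account for the blood-volume factor, and the
  long window adds a transient bias of up to ~15% for tissues whose
  equilibration is slow relative to their influx signal (kidney,
  spleen, muscle in the library). This is a property of the protocol,
  faithfully reproduced, not an implementation artifact.
- The unrestricted "first fit" convention can return negative rate
  constants on pathological TACs; that is the convention's point, and
  the bounded mode exists when it is not wanted.
- The IDIF is taken at face value: no partial-volume recovery, no
  dispersion model. On the phantom the aorta region is noise-free in
  expectation, which flatters the input relative to clinical data.
- Problem sizes in the test suite are scaled to the phantom defaults
  (48×48×96 voxel maps, 100-replicate noise studies, 50-region
  correlation phantoms); all statistical tolerances were derived from
  oracle studies at those sizes.
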