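# dynpet

Kinetic analysis of whole-body dynamic [¹⁸F]FDG PET on long-axial-FOV
protocols: indirect Patlak parametric imaging over short and long
late-time windows, irreversible two-tissue-compartment (2TCM) fitting
with an image-derived input function, and tumor-to-background contrast
reporting — together with a synthetic dynamic-phantom generator so that
every stage can be validated by parameter recovery against known ground
truth.

## The problem

A 60-min dynamic acquisition (33 frames: 10×15 s, 5×30 s, 5×60 s,
5×120 s, 8×300 s) yields a time-activity curve (TAC) per voxel or VOI.
With the descending-aorta blood pool as the input function Cp(t), two
quantitative readouts compete with the conventional late static image
(*sumSUV*, the mean of the 50–60 min frames):

**Patlak graphical analysis.** For an irreversible tracer, plotting
y = C_T(t)/Cp(t) against x = ∫₀ᵗCp/Cp(t) becomes linear after the
reversible pools equilibrate; the slope is the net influx constant K_i
(mL/ccm/min) and the intercept the distribution volume DV. Two window
presets mirror common practice: **STI** (the last six 300-s frames,
30 min of data) and **LTI** (all frames except the first three,
59.25 min). Because the measured TAC contains a blood fraction,
C_T = (1−v_B)(C₁+C₂) + v_B·Cp, the slope converges to (1−v_B)·K_i;
and the LTI window deliberately includes early, non-equilibrated
frames, which shifts the slope for slowly equilibrating tissue — that
window sensitivity is a feature of the protocol comparison, not a bug.

**Two-tissue compartment model.** C₁ (free/transported FDG) and C₂
(phosphorylated FDG) follow

    dC₁/dt = K₁·Cp − (k₂+k₃)·C₁ + k₄·C₂,   dC₂/dt = k₃·C₁ − k₄·C₂,

with k₄ fixed to 0 by default, fitted per VOI by weighted nonlinear
least squares under a "first fit" convention (single descent from fixed
initial values, stopped by an iteration cap or a chi-square tolerance,
no parameter restrictions).  The derived influx is
K_i = K₁·k₃/(k₂+k₃).

Image types are compared lesion-by-lesion against the liver-parenchyma
background via TBR_mean = mean(L)/mean(B), TBR_max = max(L)/mean(B),
CNR_mean = (mean(L)−mean(B))/SD(B), CNR_max = (max(L)−mean(B))/SD(B),
with Wilcoxon matched-pairs signed-rank tests, Spearman rank
correlations of K_i across methods, and Welch t-tests of tumor vs
normal-organ parameters.

## Worked example

```python
import dynpet as dp

spec = dp.default_phantom_spec(noise_scale=0.3, seed=1)   # 48×48×96 grid
image, vois, truth = dp.build_phantom(spec)
input_fn = dp.InputFunction(dp.extract_idif(image, vois, "aorta"))

tac = dp.TimeActivityCurve(
    image.voxels[vois.mask("tumor_1")].mean(axis=0), image.schedule)

print(dp.PatlakModel(tac, input_fn, window="lti").fit().summary())
print(dp.TwoTissueModel(tac, input_fn).fit().summary())
```

```
Patlak graphical analysis
============================================
window                         LTI
frames used                     30
weights                    uniform
RSS                       0.048219
--------------------------------------------
param         estimate       std err
Ki            0.053352      0.000329
DV             0.26063        0.0107

Two-tissue compartment model fit
============================================
frames                          33
k4 mode                 fixed-zero
bounds                unrestricted
chi-square                 0.21475
function evals                  13
termination              tolerance
--------------------------------------------
param         estimate       std err
vB            0.052017       0.00581
K1             0.27983        0.0148
k2             0.87783        0.0636
k3              0.2221         0.005
--------------------------------------------
Ki = K1*k3/(k2+k3)        0.056505
```

The phantom's tumor regions are generated with v_B = 0.057, K₁ = 0.267,
k₂ = 0.863, k₃ = 0.234, so the true influx is K_i = 0.0570.  The
compartment fit on the noisy lesion TAC recovers 0.0565 (−0.8%); the
long-window Patlak slope, 0.0534, sits at (1−v_B)·K_i as theory says it
must.  Voxel-wise maps and the full report bundle come from the
pipeline:

```sh
dynpet run-all --seed 1 --out run1      # or: dynpet simulate / patlak / tcm-fit
```

which writes `ki_sti.nii.gz`, `ki_lti.nii.gz`, `sumsuv.nii.gz`, the
IDIF CSV and four report tables (contrast, Wilcoxon, parameters,
correlations) plus a manifest with the seed and config hash.  On the
default phantom the mean tumor TBR_mean ordering is
LTI K_i > STI K_i > sumSUV (≈13.2 / 13.1 / 3.8 at seed 1), and the
voxel-wise K_i variance in liver is lower for LTI than STI — the
long-window influx image separates lesions from background best, at the
lowest parametric noise.

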