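# Methods

## Scope and model

The package studies one question: can a translational patient setup
error be detected, and its direction identified, from the change it
induces in an integrated transmission fluence map recorded during an
arc delivery?  The chain is: simulate fluence maps with injected
shifts → quantify the change against a baseline (DD and SSIM maps) →
classify the shift (radiomics + classical ML, and a four-branch CNN).

## The synthetic cohort

No measured phantom data ship with the package, so a synthetic-data
module generates cohorts with the geometry that makes the problem
interesting.

**Phantom.** Each "patient" is an analytic phantom: an ellipsoidal
head-like body (semi-axes ≈ 60/70/70 mm along LR/AP/SI, jittered per
patient) of water-like MV attenuation (μ ≈ 0.005 mm⁻¹) containing 3–6
ellipsoidal heterogeneities (bone-like or air-like contrast, positions
and sizes drawn per patient seed).  Because every component is an
ellipsoid, the attenuation line integral of any ray has a closed form
(μ × chord length), so projections are exact and fast and a rigid
phantom shift corresponds to an exact sub-pixel displacement of the
projection — no voxelization or interpolation error enters the forward
model.  A rasterized attenuation grid is available for inspection
(`PhantomModel.attenuation_grid`).

**Delivery.** Two partial arcs, 240°→120° clockwise through gantry zero
and the reverse, sampled at a 5° control-point spacing (a desk-scale
stand-in for a continuous arc — coarse enough to be fast, fine enough
that in-plane shift cancellation over the arc is well resolved).  The
under-couch sector 120°–240° is never visited.  At each angle the beam
is shaped by a smoothly modulated rectangular aperture with a sigmoid
penumbra (≈1.5 mm), whose centre and size follow low-order Fourier
series in gantry angle drawn from the plan seed — a stand-in for
VMAT-like aperture motion; real MLC sequences are out of scope.

**Projection geometry.** Parallel beam, imager orthogonal to the beam
at every angle, geometric magnification configurable (default 1.0: one
mm of couch shift displaces the imager-plane projection by one mm).
Rows of the image run along SI, columns along the in-plane axis.  A
shift `(lr, si, ap)` displaces the projection at gantry angle θ by
`du = M·(lr·cosθ − ap·sinθ)` in-plane and `dz = M·si` along SI.  Summed
over the arc this makes SI shifts coherent and LR/AP shifts partially
self-cancelling — the package's directional-detectability ordering
(SI easiest, LR hardest) is a geometric consequence, not an assumption.

**Dose scale and noise.** The open-field integrated map is normalised
to 200 cGy (the fraction dose); transmission through the phantom leaves
of order 100 cGy at the centre.  Detector noise is additive Gaussian
with σ = 0.5 % of the map maximum (configurable; the acquisition
electronics of a real panel are not modelled).  Zero-noise cohorts are
used where exact identities are asserted.

**Cohort layout.** Per patient: one baseline acquisition plus the 27
error positions of {0,2,4}³ mm, including a re-acquisition of the
unshifted position with a fresh noise seed.  Everything derives from a
single master seed through `numpy` seed sequences; cohorts are
bit-reproducible.

**What the generator does not emulate.** Scatter, beam hardening,
panel calibration drift, MLC sequencing, rotational errors, anatomy
change.  Passing tests therefore demonstrate that the pipeline recovers
translational-shift signal from arc-integrated transmission images
under controlled conditions — not clinical performance on measured
data.

## Comparison maps

`DD = |V_x − V_y|` pixelwise.  The SSIM decomposition uses a uniform
(unweighted) 11×11 window; local means, standard deviations and the
covariance come from uniform filters with reflective border handling
(configurable to valid-only cropping).  Stabilising constants
`C1 = (K1·L)²`, `C2 = (K2·L)²`, `C3 = C2/2` with `K1 = 0.01`,
`K2 = 0.03`, `L = 200` cGy; exponents α = β = γ = 1 by default.  The
contrast term uses `C2` in numerator and denominator.  All comparison
arithmetic runs in double precision so that the self-comparison
identities (`DD ≡ 0`, `SSIM ≡ 1`) hold to rounding.

Maps are computed on the full image and cropped to the 512×512 centre
afterwards (crop offset `floor((H−512)/2)`), so window statistics near
the crop edge use real neighbours.

## Labels

Isocenter error = Euclidean norm of the shift.  The 3 mm boundary is
strict: exactly 3.00 mm counts as "no error" (the {0,2,4} mm design
never lands on the boundary; the printed norms 2.83 and 3.46 mm pin the
threshold to the open interval between them).  Type 3 encodes the three
per-axis flags into classes 1–8 (1 none, 2 LR, 3 AP, 4 SI, 5 LR+AP,
6 LR+SI, 7 SI+AP, 8 all).

## Radiomics features

94 features per map: first order (19), GLCM (24), GLDM (14), GLRLM
(16), GLSZM (16), NGTDM (5), following the IBSI-aligned formulations of
the standard extraction libraries; shape families are excluded because
every analysed map shares one rectangular support.  Texture families
run on a discretized copy: GLCM and GLRLM use the four 2D distance-1
directions, symmetric counting, feature values averaged over
directions; GLSZM zones and GLDM dependencies use 8-connectivity
(dependence size = dependent neighbours + 1, α = 0).  Degenerate inputs
take their defined limits (constant map → GLCM contrast 0, correlation
1, NGTDM coarseness capped at 10⁶), never NaN.

Discretization defaults: the standalone extractor uses a fixed bin
width of 25 map units anchored at the map minimum (the conventional CT
default; it makes difference-based features shift-invariant).  The
cohort pipeline instead uses a fixed bin count of 32 for every source
map, because the SSIM component maps occupy a data-dependent sliver of
[−1, 1] and any fixed width is either degenerate for them or absurd for
DD maps.  Both schemes are configurable.

## Classification

One sample per (patient, error position): 27 rows per patient; the
baseline enters only through the comparison maps.  ML1 uses the 94 DD
features, ML2 the 282 luminance+contrast+structure features, ML3 all
376.  The pipeline is leakage-free: the patient-level 80/20 split comes
first, the Pearson filter (default |r| ≥ 0.1 against the task's label
coding, zero-variance columns always dropped) is fitted on training
patients only, and hyperparameters are tuned by leave-one-patient-out
cross-validation on the training set (unit = patient, not sample, to
avoid within-patient leakage).  Grids: KNN neighbours 1–10; SVM linear
and RBF kernels with C ∈ {0.01, 0.1, 1, 10} and RBF γ ∈ {0.001, 0.01,
0.1, 1}; LDC solver ∈ {svd, lsqr, eigen}; XGBoost depth 3–10 with
10–100 rounds (step 10) for the binary tasks and 100–250 for type 3.
Features are standardized inside each fold.  Ties in the grid go to the
first-listed point.  No class-imbalance correction is applied.

A note on the linear discriminant: without shrinkage its covariance
estimate needs clearly more training rows than features.  The package's
recovery checks therefore run on cohorts large enough that the
post-filter feature count stays below the training row count (24
synthetic patients ≈ 513 training rows against ≈ 300 kept features);
at smaller cohort sizes the kernel and tree models recover the signal
first.  The per-axis LR task is the weakest for every model — expected,
since LR displacements lie in the rotation plane and partially cancel.

## The CNN

Four branches (DD, luminance, contrast, structure), each a VGG-style
stack: conv blocks of {2,2,3,3,3} 3×3 same-padding convolutions with
ReLU, a 2×2 max pool after each of the first four blocks (halving the
spatial side, doubling the channel width: 8→16→32→64→128 from a default
initial width of 8), and a global average pool reducing each channel to
its mean.  The four 128-vectors are concatenated and passed through two
fully connected layers (hidden 64) to n class scores; prediction is the
arg-max of the softmax.  A reduced variant for desk-scale runs keeps
the construction at 128×128 inputs with blocks {2,2,3}, two max pools
and initial width 4.

Training: Adam (lr 10⁻³ default), softmax cross-entropy, explicit
seeding of initialisation and batch order (bit-reproducible on a fixed
BLAS); non-finite loss aborts with a diagnostic.  The engine is a small
NumPy layer stack (im2col convolution via one GEMM, mask-based pool
backward) — adequate for the reduced problem sizes the package targets;
no GPU path.

**Input normalization.** Each branch map is standardized per sample
(zero mean, unit variance over its own pixels, clipped at ±8σ) after
optional block-average downsampling.  A fixed affine mapping of each
map type to [0, 1] was tried first and rejected: the SSIM component
maps concentrate so tightly near 1 that three of the four branches
received near-constant inputs and the network collapsed to the majority
class.  Per-sample standardization is parameter-free, uses no labels
(hence cannot leak), and gives every branch O(1) contrast at any noise
level.

## Evaluation

Accuracy = correct/total.  Precision, recall and F1 are one-vs-rest per
class with the zero-denominator → 0 convention.  ROC/AUC (binary tasks
only, positive class = label 2 "error present") uses the trapezoidal
rule over all score thresholds and equals the Mann–Whitney concordance
probability; the suite cross-checks this against exhaustive pair
counting.  Confusion matrices are true×predicted counts with an
optional row-normalized view.

## Numerical and I/O conventions

16-bit TIFF storage at 0.01 cGy per integer step with a JSON metadata
tag (scale, pitch, provenance); DICOM RT Image read-only with
RescaleSlope/Intercept and ImagePlanePixelSpacing; CSV manifests with
exactly one baseline row per patient.  Image origin top-left,
row-major, SI along rows.  Simulated maps are float32 (dose values of
order 100 cGy; the 10⁻⁵ relative rounding is far below the 0.5 % noise
floor); comparison maps and feature accumulations are float64.

## Problem sizes used by the shipped checks

The test suite and the reproduction script run everything at desk
scale, chosen so each check still exercises the property it is about:
recovery and CNN checks use a 24-patient zero-noise cohort at 600×600
pixels (512×512 analysis crop); the directional-ordering check uses
three independent 6-patient cohorts at the default noise level; cohort
counting uses 40 patients at reduced image size; the CNN runs in its
reduced 128×128 mode.  The full 1190×1190 panel size and the
full-scale network remain available through configuration.

## Known limitations

- The forward model is parallel-beam and scatter-free; absolute dose
  realism is not attempted beyond the 200 cGy open-field scale.
- The imager is assumed orthogonal to the beam at every gantry angle
  (it rides the gantry); panel sag or rotation is not modelled.
- Aperture motion is a random smooth surrogate, not an optimised plan;
  cross-patient variability of the synthetic cohorts is therefore
  plan-seed-driven rather than anatomy-driven.
- The type-3 Pearson filter correlates features against the integer
  class codes 1–8, which imposes an arbitrary ordering on an unordered
  class set; it is kept because the search space of alternatives is out
  of scope, and the downstream classifiers see all surviving features.
- Softmax probabilities are assumed for the CNN's score vector; raw
  uncalibrated scores would change AUC not at all and accuracy not at
  the arg-max.
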