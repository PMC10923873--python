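# Methods

## Hierarchical zonal labels and loss

Let 𝕃, 𝕋, ℙ be the sets of lesion, transition-zone (TZ) and
peripheral-zone (PZ) voxels of a case. Every voxel receives a label
vector m = [m₀, m₁] ∈ {0,1}²:

| voxel            | m      | reading                                   |
|------------------|--------|-------------------------------------------|
| v ∈ 𝕃 ∩ 𝕋      | [1, 1] | diffusion evidence + T2 evidence           |
| v ∈ 𝕃 ∩ ℙ      | [1, 0] | diffusion evidence alone suffices          |
| otherwise        | [0, 0] | background                                 |

Channel 0 is the diffusion-common "lesion anywhere" signal; channel 1 is
the additional T2 evidence PI-RADS demands for TZ lesions. The pattern
[0, 1] (T2 evidence without diffusion evidence) carries no diagnostic
meaning and is never emitted; m₁ ≤ m₀ is an invariant checked by tests.
Lesion voxels that fall outside both zonal masks — zonal masks come from
an upstream segmentation and can be imperfect — are labeled [1, 0] and
counted in a warning: the diffusion-common channel applies to every
lesion, whereas T2 evidence is specifically the TZ addition. This
fallback is our choice for an under-specified corner case.

The model emits p = [p₀, p₁] ∈ [0,1]² per voxel. Because [0, 1] is
undefined, predictions with p₁ > p₀ are internally inconsistent; before
the cross-entropy the probabilities are replaced by

    p₀' = p₀               if m₀ = 1,    max(p₀, p₁) if m₀ = 0
    p₁' = min(p₀, p₁)      if m₁ = 1,    p₁          if m₁ = 0

which routes extra gradient against the inconsistent channel (on
background voxels the loss in p₁ has double the marginal slope above p₀;
on TZ-lesion voxels an over-confident p₁ is capped by p₀). The zonal
loss is the focal form of this constrained cross-entropy,

    L(P, M) = Σᵥ −m·(1−p')^γ·log p' − (1−m)·p'^γ·log(1−p'),

summed over both channels. γ defaults to 2.0, the canonical focal-loss
exponent, since the appropriate value is otherwise unspecified; γ = 0
reduces exactly to the constrained cross-entropy, which tests assert.
Probabilities are clamped to [ε, 1−ε], ε = 1e−7, so saturated outputs
keep the loss finite. Reduction defaults to the plain voxel sum; a
mean-over-voxels option exists for batch-size-independent learning
rates (Adam's per-parameter normalization makes the two nearly
equivalent in practice). Ties p₀ = p₁ inside max/min route their
gradient to channel 0, a fixed precedence that keeps training
deterministic.

Two implementations exist on purpose: vectorized NumPy functions (the
public evaluation API) and autodiff-graph versions used in training.
The suite checks both against an independently written per-voxel scalar
loop, and the autodiff gradient against finite differences away from
the max/min tie points.

## Symmetric-aware network

A 3-level 3-D encoder–decoder. Input is the 5-channel stack (T2, ADC,
high-b DWI, TZ mask, PZ mask); the same stack mirrored about the width
axis feeds a second path through the *same* encoder instance, so weight
sharing holds by construction (asserted on object identity, not value).
Each convolution block is a 3×3×3 convolution → LeakyReLU (slope 0.01)
→ instance normalization with affine parameters. Levels below the top
open with a stride-2 convolution; upsampling uses kernel-2/stride-2
transposed convolutions (a standard U-Net convention; the choice of
down/up-sampling operator was otherwise open). At every level above the
bottleneck the original- and mirrored-path features are concatenated and
fused by a BridgeBlock of two convolution blocks; the decoder
concatenates each bridge output with the upsampled features from below.
Only the original-path bottleneck enters the decoder by default — the
literal reading of fusing "at each level other than the bottom" — with a
`fuse_bottom` flag for the alternative. The head is a zero-initialized
1×1×1 convolution with an independent sigmoid per channel: labels are
hierarchical multi-label ([1,1] is legal), which softmax cannot
represent, and zero initialization makes an untrained model output 0.5
everywhere. For mirror-symmetric input the two encoder paths receive
identical arrays and produce identical features, a collapse property the
tests assert.

The engine underneath (`symzone.nn`) is a compact reverse-mode autodiff
on float32 NumPy arrays. 3-D convolution lowers to an offset-major
im2col and a batched GEMM; its input gradient uses the zero-dilation /
full-correlation identity, avoiding scatter-adds. Every primitive's
vector-Jacobian product is verified against finite differences, and the
convolution forward against `scipy.ndimage.correlate`.

## Phantoms

Each case is a centered prostate ellipsoid (semi-axes 0.38/0.32/0.32 of
the volume extent) split into an inner TZ ellipsoid (0.58 scale) and the
surrounding PZ shell, on zone-wise constant base intensities with a mild
radial T2 gradient, plus i.i.d. Gaussian noise (σ = 0.02 by default, on
the [0,1] normalized scale). Focal structure is additive ellipsoidal
offsets with mildly anisotropic radii drawn from 4–8 mm:

* TZ lesions: (−0.25, −0.30, +0.30) on (T2, ADC, high-b) — dark T2,
  dark ADC, bright high-b;
* PZ lesions: (−0.08, −0.35, +0.35) — strong diffusion contrast, weak T2;
* mimic pairs: (−0.22, −0.30, +0.30), lesion-like but placed as a blob
  plus its exact width-flip, and excluded from the lesion mask.

The clinical literature does not quantify these contrasts; the values
are fixed defaults chosen to preserve the qualitative channel relations
(cancer and its benign mimics dark on ADC/T2 and bright on high-b) and
are configurable in `PhantomSpec`. Deterministic structure is built from
arithmetic that commutes with the width flip, so a noiseless mimic-only
phantom equals its mirror bit-for-bit; lesion centers are kept ≥ 2
voxels off-midline so lesions are genuinely asymmetric. Lesions are
redrawn if the gland boundary would amputate more than 10 % of the
ellipsoid (keeping discretized volumes within ~15 % of analytic) or if
they would touch previously placed structure (each lesion stays its own
connected component); a bounded number of attempts converts an
over-crowded specification into an error. One RNG stream derived from
`PhantomSpec.seed` drives all randomness, so generation is reproducible
bit-for-bit.

Default geometry is a (16, 128, 128) volume at (3.0, 0.625, 0.625) mm —
the crop size and resolution of clinical prostate T2 acquisitions — so
the 5 mm matching radius and FROC behave realistically. What the
phantoms deliberately omit: MR physics (bias fields, coil profiles,
partial volume), inter-sequence misregistration, anatomical texture, and
DCE imaging. Passing tests therefore demonstrate correctness of the
machinery and the *direction* of the symmetry/zonal effects under
controlled conditions, not clinical performance.

## Preprocessing

Rotation about the in-plane volume center by the single global angle
atan2(Δw, Δh) between the whole-gland and TZ centroids (projected
in-plane), verticalizing the centroid line; images interpolate linearly,
masks nearest-neighbour (zone overlaps created by rounding are resolved
in favour of TZ, and lesion voxels are re-clipped to the gland). Center
crop about the in-plane center (128×128 default). T2 and high-b are
min–max scaled to [0, 1] per patient; ADC is quantitative across
patients, so it is clipped at a patient-independent value and divided by
it — default 3000 (units 10⁻⁶ mm²/s) for raw maps, 1.0 for phantoms
already on the normalized scale; the clip constant is recorded in the
JSON provenance sidecar. Bias-field correction and DWI→T2 registration
are upstream responsibilities; phantoms are generated pre-aligned.

## Detection and evaluation

Detection points are the local maxima (26-neighbourhood) of the p₀
channel — p₀ encodes "lesion anywhere" in the hierarchy, while p₁ only
adds TZ evidence; the scored channel is configurable. A trained model
saturates to constant plateaus (sigmoid = 1.0 in float32), which have no
*strict* maxima, so extraction is plateau-aware: a connected component
of candidate voxels strictly above its entire border counts as one
detection at the voxel nearest the component centroid; an equal-valued
border voxel marks a shoulder (rejected), and a plateau covering the
whole volume (a constant map) has no surroundings to dominate and yields
nothing. Peaks below `min_score` (default 0.1) are dropped and greedy
non-maximum suppression enforces `min_separation_mm` (default 5) in
world space.

A point is a true positive when its world-space distance to the nearest
lesion *voxel center* is ≤ 5 mm — the shape-aware (and more
conservative) reading of "within 5 mm of the lesion", tolerant of the
imaging-to-histopathology mismatch that motivates the radius. A lesion
is detected when ≥ 1 true positive maps to it; extra hits on a detected
lesion never count as false positives. The FROC sweeps thresholds over
the union of detection scores; operating-point sensitivities use the
right-continuous step convention (sensitivity at the largest achieved
FP/patient not exceeding the operating point), making reported numbers
bit-reproducible. Patient score is the maximum of p₀; AUC is the
rank-based Mann–Whitney statistic (tested against brute-force pair
enumeration and scikit-learn); confidence intervals are percentile
bootstrap over patients (1000 resamples, 95 % by default; resamples that
leave a metric undefined are skipped). The k-fold splitter partitions
randomly with fold sizes differing by at most one — 652 ids give
131/131/130/130/130.

## Training and the scaled experiment

Adam (lr 1e−3 default — unspecified upstream — batch size 2), a fixed
epoch budget with early stopping after `patience` consecutive epochs
without *training*-loss improvement (validation-based stopping is a
config option; the reference protocol is 60 epochs / patience 30, which
are the config defaults). The best-loss weights are restored at the
end. Non-finite loss aborts with a diagnostic. Weight initialization
and data order are seeded separately, so identical seeds reproduce loss
histories exactly (single-threaded).

The ablation driver crosses {symmetric, single-path} × {zonal,
focal-binary} on identical cases and seeds. The single-path arm feeds
the original stack to both encoder inputs, removing the mirrored view
while preserving the parameter count (the alternative — deleting the
second path — would confound symmetry with capacity).

The scaled experiment runs this grid at phantom scale on one CPU:
(8, 24, 24) voxels at (3.0, 2.5, 2.5) mm — the same physical gland at
coarser resolution — encoder widths (8, 16, 32), two blocks per level,
10 epochs, cohorts of 40 training and 10 test phantoms with 60 %
lesion-positive cases and a symmetric mimic pair in every case. These
sizes are the package's chosen operating point for desk-scale
experimentation; the full-width (64, 128, 256) configuration is
constructible but sized for accelerator memory, not for the NumPy
engine. The headline comparison is the mean FP/patient needed to reach
0.8 lesion sensitivity, symmetric + zonal arm versus single-path focal
baseline, over five fixed seeds; the acceptance test asserts the
symmetric arm is no worse in a majority of seeds. On such small cohorts
the zonal loss alone can be noisy (it splits supervision over two
channels); the symmetry-aware architecture is the dominant
false-positive reducer, consistent with the mimic design of the
phantoms.

## Known limitations

* The autodiff engine is single-threaded NumPy; wide configurations are
  memory- and compute-bound (no chunked convolution).
* Phantom realism is deliberately limited (see above); absolute metric
  values on phantoms do not transfer to clinical data.
* The 5 mm adjudication uses voxel-center distances; sub-voxel lesion
  boundaries are not modelled.
* Bootstrap CIs resample patients only; they ignore lesion-level
  clustering within a patient.
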