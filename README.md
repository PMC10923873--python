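# symzone

Symmetry-aware, zone-aware detection of clinically significant prostate
cancer (csPCa) on multi-parametric MRI (mpMRI), exercisable end to end on
synthetic anatomical phantoms.

## The problem

Radiologists reading prostate mpMRI use two anatomical priors that generic
voxelwise detectors ignore:

1. **Zonal appearance rules.** Under PI-RADS, a peripheral-zone (PZ) lesion
   is called primarily on diffusion evidence (dark ADC, bright high-b DWI),
   while a transition-zone (TZ) lesion additionally needs T2-weighted
   evidence. Binary cross-entropy treats all lesion voxels identically and
   discards this structure.
2. **Left–right symmetry.** Benign tissue that looks like cancer channel-
   wise — benign prostatic hyperplasia (BPH) nodules, central-zone wings —
   tends to appear *symmetrically* about the gland midline, whereas cancer
   is asymmetric. Symmetry-blind models turn these mimics into false
   positives.

This package implements both priors:

* a **hierarchical zonal loss**: each voxel gets a label vector
  m = [m₀, m₁] with [1,1] for TZ lesions, [1,0] for PZ lesions and
  [0,0] otherwise ([0,1] is undefined). The model predicts p = [p₀, p₁]
  per voxel, constrained before the cross-entropy by

      p₀' = p₀ if m₀=1 else max(p₀, p₁)
      p₁' = min(p₀, p₁) if m₁=1 else p₁

  so any prediction with p₁ > p₀ is penalized, and the focal form

      L = Σᵥ −m·(1−p')^γ·log p' − (1−m)·p'^γ·log(1−p')

  handles the extreme lesion/background class imbalance (γ = 0 recovers
  the constrained cross-entropy);
* a **symmetric-aware dual-path 3-D encoder–decoder**: one shared-weight
  encoder consumes both the original stack (T2, ADC, high-b DWI, TZ mask,
  PZ mask) and its mirror about the width axis; at each level the two
  feature maps are fused by a BridgeBlock of two convolution blocks before
  decoding, letting the network compare a suspicious focus with its
  contralateral counterpart;
* the **evaluation protocol** used in lesion-detection studies: local-maxima
  detection points, true positives within 5 mm of any ground-truth lesion
  voxel, FROC sensitivity at 0.5/1/1.5/2/2.5 FP/patient, patient-level ROC
  from the maximum of the probability map, k-fold splits and bootstrap
  confidence intervals;
* a **phantom generator** producing co-registered synthetic mpMRI cases —
  a prostate ellipsoid split into TZ and a PZ shell, asymmetric TZ/PZ
  lesions with the channel contrasts above, and exactly mirror-placed
  benign mimic pairs that bait symmetry-blind models into false positives —
  so every stage is testable without clinical data.

The network and training run on a compact NumPy reverse-mode autodiff
engine (`symzone.nn`) with 3-D convolution, transposed convolution,
instance normalization and Adam; no GPU framework is required.

## Worked example

Train the symmetry-aware model with the zonal loss on a small phantom
cohort and evaluate it on held-out cases:

```python
from symzone.experiments import make_cohort
from symzone.sym_net import ModelConfig, build_model
from symzone.training import TrainConfig, prepare_case, train, evaluate_model

train_cases = make_cohort(12, seed=0)          # generated + preprocessed
test_cases = make_cohort(6, seed=999)
model = build_model(ModelConfig(encoder_channels=(8, 16, 32),
                                decoder_channels=(32, 16, 8),
                                blocks_per_level=2, seed=0))
model, history = train(model,
                       [prepare_case(c, "zonal") for c in train_cases],
                       TrainConfig(epochs=6, early_stop_patience=6, seed=0))
metrics = evaluate_model(model, test_cases)
print(f"train loss: {history[0]:.1f} -> {history[-1]:.1f}")
print(f"sensitivity @ 0.5 FP/patient: {metrics['sens_at_0.5_fp']:.3f}")
print(f"sensitivity @ 2.5 FP/patient: {metrics['sens_at_2.5_fp']:.3f}")
print(f"patient-level AUC: {metrics['patient_auc']:.3f}")
```

prints

```
train loss: 3181.4 -> 3004.9
sensitivity @ 0.5 FP/patient: 0.625
sensitivity @ 2.5 FP/patient: 1.000
patient-level AUC: 1.000
```

i.e. after six epochs on twelve phantoms the model already separates
patients with lesions from lesion-free ones perfectly (AUC 1.0), finds
every lesion when allowed 2.5 false positives per patient, and 62.5 % of
lesions at the strictest 0.5 FP/patient budget. Longer training (the
ablation driver uses 40 cases and 10 epochs) tightens the low-FP end.

A CLI mirrors the library: `symzone simulate | preprocess | train |
evaluate | ablate` (see `symzone --help`).

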