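# ctexture

Windowed texture features, attenuation-pattern classification and
region-of-interest search for CT bowel-abnormality screening.

Radiologists read bowel pathology on CT through a small vocabulary of
bowel-wall *attenuation patterns* — white (enhancing thickened wall), gray
(thickened wall with limited enhancement), water-halo and fat-halo signs
(stratified walls with a water- or fat-density middle layer) and black
(intramural air, the ischemia indicator). `ctexture` automates that reading:
it reduces each rectangular image window to six texture descriptors,
classifies windows against trained patterns, and scans whole slices for
regions worth a clinician's attention — without requiring a segmentation of
the intestines. It is aimed at researchers prototyping computer-aided
detection of intestinal ischemia and related bowel-wall abnormalities.

## The method

Each window yields the feature vector

**f** = ( m, σ², g₁, g₂, H, d_B )

- m, σ² — gray-level mean and population variance,
- g₁ = (1/N) Σ((xᵢ−m)/σ)³ — skewness; g₂ = (1/N) Σ((xᵢ−m)/σ)⁴ − 3 — excess
  kurtosis (a normal histogram scores 0 for both),
- H = −Σ a_pq ln a_pq — entropy of the gray-level co-occurrence matrix at
  displacement (+1, +1) over L = 32 quantized levels,
- d_B — box-counting fractal dimension of the mean-thresholded window,
  minus the slope of log n(r) vs log r over dyadic box sizes.

Features are z-scored on the training set (f* = (f − μ_f)/σ_f). A test
window is assigned by a k-NN majority vote (k = 3, Euclidean distance);
whole groups of windows are assigned to the class minimizing the
Bhattacharyya distance D_B = ⅛ Δmᵀ[(Cᵢ+Cⱼ)/2]⁻¹Δm +
½ ln(|(Cᵢ+Cⱼ)/2|/√(|Cᵢ||Cⱼ|)) between Gaussian class models. The forward
ROI search slides a window of the average trained-pattern size across the
slice, keeps any window whose mean per-feature relative error
|a−b|/max(|a|,|b|)·100 against some trained pattern is within a threshold
(default 20%), and expands around every hit to its right/below/diagonal
neighbors. Evaluation reproduces confusion matrices over the eight
reporting classes plus the diseased-vs-non-diseased sensitivity and
specificity aggregation. Details and design rationale: `docs/methods.md`.

Because no public dataset of labeled attenuation-pattern windows exists,
the package ships a seeded synthetic texture generator (nine class presets:
moments, spatial correlation, halo banding) so every stage is testable
end-to-end; the packaged reference confusion matrices `t1`–`t7` anchor the
evaluation arithmetic.

## Worked example

```python
import ctexture as ct

# 20 seeded synthetic windows per pattern class, with within-class spread
data = ct.generate_training_set(20, seed=11, mean_jitter=10.0, logvar_jitter=0.5)

cm, summary = ct.run_experiment(
    data, ct.SplitSpec(train_fraction=0.5, seed=1), ct.KnnConfig(k=3)
)
print(cm.to_frame().round(2))
print({k: summary[k] for k in ("n_test", "accuracy", "sensitivity", "specificity")})
```

```
            white  gray  water_halo  fat_halo  black  ischemia  benign  control
white         1.0   0.0         0.0       0.0    0.0       0.0    0.00     0.00
gray          0.0   0.8         0.0       0.0    0.0       0.0    0.00     0.20
water_halo    0.0   0.0         0.5       0.4    0.0       0.0    0.10     0.00
fat_halo      0.0   0.0         0.1       0.9    0.0       0.0    0.00     0.00
black         0.0   0.0         0.0       0.0    0.8       0.2    0.00     0.00
ischemia      0.0   0.0         0.0       0.0    0.0       1.0    0.00     0.00
benign        0.0   0.1         0.0       0.0    0.0       0.0    0.75     0.15
control       0.0   0.4         0.0       0.0    0.0       0.0    0.10     0.50
{'n_test': 90, 'accuracy': 0.777..., 'sensitivity': 95, 'specificity': 75}
```

Each row is a true class, each column the k-NN assignment, as row
proportions over the 90-window test half (the two benign sub-patterns
report merged). The two halo signs — both stratified walls — confuse each other;
benign and control windows mix with gray; sensitivity (the mean diseased-row
mass staying in diseased columns, 95%) exceeds specificity (75%), the
expected regime for this screening problem. Searching a slice:

```python
classes, sizes, background, _ = ct.load_presets()
scene = ct.generate_phantom(background, [("ischemia", (100, 110))], seed=42,
                            class_params=classes)
dets = ct.forward_search(scene.image, data, ct.SearchConfig(threshold=20.0),
                         pattern_sizes=list(sizes.values()))
print(scene.truth[0])
print(dets[0].window, dets[0].matched_class, round(dets[0].score, 1))
```

```
(Window(row=171, col=159, height=100, width=110), 'ischemia')
Window(row=200, col=165, height=50, width=55) ischemia 3.2
```

The planted 100×110 ischemia patch is localized by a 50×55 scan window
fully inside it, matched to the correct class at a 3.2% relative error.

The same pipeline is scriptable from a shell — `ctexture extract | train |
classify | search | evaluate`; every command writes a provenance block
(config, seed, version) beside its outputs.

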