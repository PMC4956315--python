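# vesselseg

Unsupervised segmentation of the blood-vessel tree in color fundus
photographs, for researchers working with the DRIVE/STARE family of
retinal image databases and anyone who needs a fast, training-free
vessel map (e.g. as a preprocessing step for diabetic-retinopathy
screening pipelines).

## Method

The pipeline runs entirely on the green channel `I` of the fundus image,
where vessels show the strongest contrast against the background:

1. **CLAHE** — contrast-limited adaptive histogram equalization: per-tile
   histogram equalization with each tile histogram clipped at
   `clip_limit × (tile pixel count)` (clip limit in `[0, 0.01]`, 8×8
   tiles) and the excess redistributed uniformly; tile mappings are
   blended bilinearly.
2. **Modified top-hat** — background removal around the estimate
   `B = (I · S_c) ∘ S_o` (closing then opening, disk structuring elements
   of radius 8 px, covering vessel widths of 1–8 px).  Vessels are dark,
   so the enhanced (inverse) image is the positive part of `B − I`,
   rescaled to `[0, 1]`: vessels become bright ridges on a dark field.
3. **Hessian eigenvalue vesselness** at two scales.  At each pixel the
   scale-normalized Hessian `σ²H` has eigenvalues `λ₁ ≤ λ₂`, and the
   vesselness is the bare difference

   `V = λ₂ − λ₁ = √((h₁₁ − h₂₂)² + 4 h₁₂²) ≥ 0`,

   computed at `σ = 1` (thin vessels) and `σ = 2.5` (wide vessels) — no
   Frangi-style ratio or structureness terms.
4. **Fused global/region-based Otsu thresholding.**  A global Otsu
   threshold `t*` (the exhaustive maximizer of the between-class variance
   `σ²_B(t) = ω₀(μ₀−μ_T)² + ω₁(μ₁−μ_T)²`) binarizes the wide-vessel map;
   the resulting wide-vessel mask is fused into the thin-vessel map by
   saturating its pixels to 1.0.  A second Otsu split of the fused image
   gives the base for a two-valued region threshold map: base + δ inside
   a dilated neighborhood of the wide vessels (suppressing noise beside
   strong vessels), base − δ elsewhere (recovering faint thin vessels).
5. **Area filter** — every 8-connected component of ≤ 30 px is removed
   as noise.

Evaluation uses the standard pixel metrics inside the field of view:
accuracy, sensitivity `Sn = TP/(TP+FN)`, specificity `Sp = TN/(TN+FP)`,
and the single-operating-point summary `AUC = (Sn + Sp)/2`.

A synthetic fundus generator (random vessel trees with Gaussian
cross-sections, dark-on-bright polarity, radial illumination gradient,
sensor noise, circular aperture, exact ground truth) makes every stage
testable without downloading the external databases; the pipeline runs
on real DRIVE/STARE files if you supply them.

## Worked example

```python
from vesselseg import (default_spec, render, segment, confusion_counts,
                       compute_metrics, round_metric)

sample = render(default_spec(seed=1))          # 256x256 synthetic fundus
mask, _ = segment(sample.image, fov=sample.fov)
rec = compute_metrics(confusion_counts(mask, sample.truth, fov=sample.fov),
                      image_id="synthetic-01", eval_region="fov")
print(int(mask.sum()))                         # 12654 vessel pixels found
for name in ("acc", "sn", "sp", "auc"):
    print(name, round_metric(getattr(rec, name)))
```

prints

```
12654
acc 0.83
sn 0.848
sp 0.826
auc 0.837
```

i.e. on this synthetic sample the pipeline recovers 84.8% of the true
vessel pixels (sensitivity) while keeping 82.6% of the background clean
(specificity), for a (Sn+Sp)/2 summary of 0.837.  See
`docs/methods.md` for what synthetic samples do and do not say about
performance on real photographs.

The same flow is available from the shell:

```bash
vesselseg synth --n 1 --seed 7 --out-dir demo
vesselseg segment demo/synth_default_007_rgb.png \
    --fov demo/synth_default_007_fov.png --out demo/mask.png
vesselseg evaluate demo/mask.png demo/synth_default_007_truth.png \
    --fov demo/synth_default_007_fov.png
vesselseg batch my_images/ --truth-dir my_truths/ --out-dir out/   # DRIVE/STARE layout
```

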