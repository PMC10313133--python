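# duvmargin

Slide-level malignant/benign classification of deep-ultraviolet (DUV)
fluorescence whole-surface images, built for intra-operative margin
assessment workflows:

1. **Tiling** — each slide is resized to the nearest dimensions divisible by
   the 400×400 patch size and split into a non-overlapping grid; patches with
   at least 20 % foreground (grayscale luma ≥ 5) are kept.
2. **Features** — a frozen backbone turns each valid patch into a feature
   vector.  A deterministic mock backbone (channel means + seeded random
   projection) runs everywhere; a pretrained torchvision ResNet50 (2048-D)
   is available when torch is installed.
3. **Patch classification** — a gradient-boosted tree ensemble at library
   defaults, trained on features of flip/rotation-augmented patches, predicts
   each patch as malignant (+1) or benign (−1).
4. **Regional importance** — Grad-CAM++ on a differentiable model: pixel-wise
   α coefficients from second/third derivatives of the class score, rectified
   gradient channel weights, and a rectified weighted activation map,
   upsampled to the slide and min–max normalized to [0, 1].  Higher-order
   derivatives come either from truncated-Taylor forward mode (exact for
   smooth networks) or the exponential-score closed form for
   piecewise-linear heads.
5. **Decision fusion** — per patch, the mean map importance r is thresholded
   at 0.25 into a weight w; the count H of patches with w·y > 0 is compared
   with q·M (default q = 0) to call the slide.  A majority-voting baseline is
   included.
6. **Evaluation** — patient-grouped stratified k-fold cross-validation,
   accuracy/sensitivity/specificity, and trapezoidal ROC/AUC on the fused
   slide score H/M.

Because real DUV cohorts are not generally available, the package ships a
**phantom generator**: synthetic slides with a near-black background, green
benign tissue, pink/yellow malignant foci with higher bright-spot density,
plus pixel masks and per-patch ground-truth labels, so the entire pipeline
can run and be scored end to end.

## CLI

```bash
# full cross-validated run on a phantom cohort (24 benign / 36 malignant)
duv-margin run-all --out results/run1 --seed 1

# staged surface on a shared work directory
duv-margin simulate --out work --benign 4 --malignant 6 --seed 1
duv-margin tile --workdir work
duv-margin featurize --workdir work
duv-margin train --workdir work
duv-margin explain --workdir work --class-index 1
duv-margin fuse --workdir work --q 0.0
duv-margin evaluate --workdir work
duv-margin render --workdir work --slide-id S000
```

`run-all` performs grouped 5-fold cross-validation; the staged commands run
each stage once over all slides (no CV loop) and exist to inspect
intermediates.  Exit codes: 0 ok, 1 validation error, 2 runtime error.
Configuration can be given as YAML (`--config`) with CLI overrides.

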