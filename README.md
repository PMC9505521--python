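# rfilm — residual plastic-film pollution evaluation for pre-sowing cotton fields

Residual polyethylene mulch ("white pollution") accumulates in film-mulched
cotton fields and, after autumn straw crushing and ploughing, surfaces as
bright, fragmented pieces scattered over the soil before spring sowing.
`rfilm` evaluates this pollution from low-altitude UAV RGB imagery:

1. **Segmentation** — a slimmed U-shaped encoder–decoder whose
   down-sampling stages use multiscale *inception blocks* (parallel 1×1
   and 1×1→3×3 branches, concatenated and 1×1-reduced) labels each pixel
   film or background. The default model has ≈3.5 M trainable parameters,
   roughly 1/9 of a classic U-Net, and is implemented in NumPy with
   explicit forward/backward passes (Adam, per-pixel cross-entropy).
2. **Per-pixel metrics** — accuracy, precision, recall, F1, and the mean
   of the film- and background-class Jaccard indices
   IOU = ½·(TP/(TP+FP+FN) + TN/(TN+FN+FP)), aggregated per image or
   pooled (MIOU).
3. **Pollution index** — the film coverage rate
   L = 100·(film pixels)/(M·N) per image, with regression validation of
   predicted (L1) vs. true (L2) coverage:
   R² = 1 − Σ(L2−L1)²/Σ(L2−L̄2)², RMSE, and MRE = mean(|L1−L2|/L2)·100%.

Because imagery of this kind is not publicly deposited, the package
includes a synthetic scene generator (`rfilm.synthgen`) producing
cotton-field-like scenes — textured soil with straw and clod confusers,
bright irregular film fragments, sunny-day specular highlights, and
blur/scale degradation increasing with flight height from 5 to 9 m — with
pixel-exact ground-truth masks, so the entire pipeline is testable end to
end. It is intended for agricultural remote-sensing researchers and for
anyone needing a dependency-light, fully reproducible binary-segmentation
pipeline with exact coverage statistics.

## Worked example

```sh
# 1. simulate a small survey: 80 scenes, balanced over weather x height
rfilm simulate --n 80 --out data --seed 7 --size 256

# 2. train a reduced-width model for 15 epochs
cat > smoke.yaml <<EOF
model: {encoder_channels: [8, 16, 32], bottleneck_channels: 64}
train: {epochs: 15}
augment: {crop_width: 192, crop_height: 192}
EOF
rfilm train --data data --out run --config smoke.yaml --seed 1

# 3. stratified segmentation metrics on the held-out test split
rfilm evaluate --data data --checkpoint run/best_model.npz --out metrics.csv
```

The same experiment through the library (as run by the test suite):

```python
from rfilm.dataio import load_manifest_pairs
from rfilm.model import load_checkpoint, predict_mask
from rfilm.pollution import coverage_rate, regression_eval

model = load_checkpoint("run/best_model.npz")
test = load_manifest_pairs("data", {"test"})
l1 = [coverage_rate(predict_mask(model, img)).l_pct for img, _ in test]
l2 = [coverage_rate(msk).l_pct for _, msk in test]
print(regression_eval(l1, l2))
```

prints (seed-for-seed reproducible):

```
RegressionReport(n=8, r_squared=0.997, rmse=0.154, mre_pct=3.78,
                 slope=0.984, intercept=0.005, n_excluded_zero_truth=0)
```

i.e. predicted coverage tracks true coverage with R² ≈ 0.997 and a mean
relative error under 4% on the eight test scenes, while the stratified
metrics table shows mean per-image MIOU ≈ 94% overall, higher at 5 m than
at 9 m (blur and shrinking fragments) and higher on cloudy than sunny
scenes (specular-highlight false positives) — the qualitative signatures
the pipeline is designed to expose.

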