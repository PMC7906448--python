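# pigmorph

Top-view RGB-D morphometry and body-weight forecasting for growing pigs.

A ceiling-mounted RGB-D camera (2.25 m above the floor, 848×480 px, 6 frames/s)
records short top-view videos of individual pigs. From each video the package
extracts three body descriptors — body length and width in pixels from the RGB
stream, and standing height in metres from the depth stream — and uses them in
a linear mixed-effects model to predict body weight one to four days ahead.
Because real recordings cannot be redistributed, the package ships a synthetic
scene generator that emulates the recording geometry (animal silhouette, depth
rendering, sitting postures, border-touching and motion-blurred frames, depth
sensor noise) with known ground truth, so every stage of the pipeline can be
validated end to end.

## What the pipeline does

1. **RGB morphometry** (`pigmorph.rgb_morphometry`). Each frame is converted to
   grayscale, thresholded (Otsu by default), and the largest 8-connected
   component is kept. A morphological opening removes thin protrusions such as
   the tail. The component contour's minimum-area rotated bounding box gives
   body length (longer side) and width (shorter side). Frames where the animal
   touches the image border or has an implausible area are rejected; the
   per-video descriptor is the median over accepted frames.
2. **Depth morphometry** (`pigmorph.depth_morphometry`). The median depth in a
   small window around the segmented animal's centroid, subtracted from the
   camera height, gives per-frame animal height. Per video, 2-means clustering
   splits frames into standing and sitting postures; the median of the standing
   (higher) cluster is the video height.
3. **Descriptor assembly** (`pigmorph.descriptor_assembly`). Per-video
   descriptors are joined with reference weights into one row per animal-day,
   plus a derived volume proxy (length × width × height) and a Pearson
   correlation matrix.
4. **Weight forecasting** (`pigmorph.weight_forecasting`). A random-intercept
   linear mixed model, `weight ~ length + width + height + (1 | animal)`, is
   fitted by REML on a sliding 14-day training window and evaluated 1–4 days
   ahead. `LMM1` predicts from fixed effects only; `LMM2` adds each animal's
   estimated random intercept (BLUP). Volume is excluded from the model because
   it is nearly collinear with its factors. Accuracy is reported as the squared
   Pearson correlation between predicted and observed weights (R²) and as mean
   absolute error in kg.

## Worked example

Measure one synthetic 60-frame video of a pig with true length 180 px, width
70 px, and standing height 0.48 m, contaminated with 20% border-touching, 10%
motion-blurred, and 30% sitting frames:

```python
from pigmorph.config import PipelineConfig
from pigmorph.synthetic_scene import SceneConfig, simulate_video
from pigmorph.rgb_morphometry import measure_frame, aggregate_length_width
from pigmorph.depth_morphometry import video_height

cfg = PipelineConfig()
scene = SceneConfig(pig_length=180.0, pig_width=70.0, pig_height=0.48,
                    border_fraction=0.2, blur_fraction=0.1, standing_fraction=0.7)
frames, truths = simulate_video(scene, 60, seed=11)

measurements = [measure_frame(f, cfg) for f in frames]
length, width, n_ok = aggregate_length_width(measurements)
height, clustering, merged = video_height(frames, cfg, seed=11)
print(f"length={length:.2f} px  width={width:.2f} px  "
      f"height={height:.4f} m  accepted={n_ok}/60")
```

Output:

```
length=180.68 px  width=70.66 px  height=0.4800 m  accepted=40/60
```

Quality control rejects 20 of 60 frames (border-touching plus out-of-range
areas); the medians over the remaining frames land within 0.7 px of the true
length and width, and the posture clustering recovers the standing height to
four decimal places despite 5 mm depth noise and 40% sitting frames.

Forecast weights for a simulated herd of 8 animals followed over 38 days:

```python
from pigmorph.synthetic_scene import GrowthConfig, simulate_growth
from pigmorph.weight_forecasting import make_scenarios, run_cv, results_frame

table, truth = simulate_growth(GrowthConfig(n_animals=8, n_days=38, rng_seed=5))
results = run_cv(table, make_scenarios(table["day"].unique(), horizons=(1, 2, 3, 4)))
df = results_frame(results)
print(df.groupby(["model", "horizon"])
        .agg(median_r2=("r2", "median"), median_mae_kg=("mae_kg", "median"),
             slides=("start_day", "count")))
```

Output:

```
               median_r2  median_mae_kg  slides
model horizon
LMM1  1            0.469          4.388      24
      2            0.474          4.379      23
      3            0.476          4.393      22
      4            0.473          4.384      21
LMM2  1            0.987          0.803      24
      2            0.987          0.777      23
      3            0.986          0.741      22
      4            0.986          0.712      21
```

With a 14-day window over 38 days there are 24/23/22/21 slides at horizons
1–4. Adding the per-animal random intercept (LMM2) raises median R² from about
0.47 to about 0.99 and cuts the median absolute error from ~4.4 kg to under
1 kg, because most weight variation in a herd of similar-sized growing pigs is
between animals rather than along each animal's short-term trajectory.

## Command-line interface

```bash
pigmorph simulate --out data/ --seed 3 --animals 8 --days 38 --frames 60
pigmorph run --root data/ --out results/ --seed 3
pigmorph forecast --table table.csv --horizons 1,2,3,4 --out forecast/
```

`pigmorph run` writes `measurements.csv`, `descriptors.csv`, `table.csv`,
`correlations.csv`, `forecast_slides.csv`, `forecast_summary.json`, and a
`manifest.json` recording the seed, configuration hash, and library versions.
Runs with the same seed and inputs byte-match. See `pigmorph --help` for the
full surface; configuration files (YAML or TOML) are validated and unknown
keys rejected (exit code 2).

## Layout

- `src/pigmorph/` — library code (scene synthesis, RGB/depth morphometry,
  descriptor assembly, forecasting, pipeline, CLI).
- `tests/` — unit, property, and acceptance tests, including the independent
  oracles (exhaustive 2-partition, rotating-calipers brute force, closed-form
  correlations, and an lme4 REML cross-check run through `Rscript`).
- `scripts/acceptance.py` — standalone reproduction script.
- `docs/methods.md` — models, parameter choices, and known limitations.
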