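# Methods

This note documents the models, parameter choices, and numerical conventions
implemented in `pigmorph`, and the limitations of the synthetic validation
data. All quantitative statements here are computed by the package's test
suite or by `scripts/acceptance.py`.

## Synthetic scene model

Each frame pair consists of an 8-bit RGB image and a 16-bit depth image in
millimetres, by default 848×480 px with the camera 2.25 m above the floor.

- **Silhouette.** The animal body is a filled rotated ellipse (default
  200×80 px semantics: `pig_length` and `pig_width` are the full axis
  lengths). A thin rectangle (5 px wide, 25 px long) attached to one end
  models the tail; the RGB measurement stage is expected to remove it.
- **Intensities.** Floor 60, body 200 (grayscale-equivalent constants), so
  either polarity of a global threshold separates them cleanly.
- **Depth profile.** Inside the body mask the depth is
  `floor_depth − 1000 · h · profile(r)`, where `profile` is 1.0 inside a flat
  core (`CORE_RADIUS = 0.15` of the normalized elliptical radius) and tapers
  linearly to `EDGE_PROFILE = 0.7` at the silhouette edge. The flat core
  exists so the centroid-window depth sample reads the true back height
  exactly rather than a taper-dependent value; the taper keeps the edges
  lower than the spine, as a rounded animal back is. Depth values are
  computed in float32 and quantized to uint16 mm.
- **Postures.** A frame is "sitting" with probability `1 − standing_fraction`
  (default 0.3). Sitting frames are rendered with height
  `SITTING_HEIGHT_FACTOR = 0.55` times the standing height — low enough that
  a 2-cluster split of per-frame heights is well separated, high enough that
  a sitting animal is still clearly above the floor.
- **Contamination.** A configurable fraction of frames is placed so the
  silhouette touches the image border (`border_fraction`, drawn mutually
  exclusively with blur), and another fraction is motion-blurred with a 21 px
  directional line kernel (`blur_fraction`). Depth noise is zero-mean
  Gaussian (default σ = 5 mm) truncated at ±4σ so a single extreme draw
  cannot corrupt a median window.
- **Growth model.** For herd simulations, per-animal descriptor trajectories
  grow linearly from randomized starting sizes, and weights follow
  `w = β₀ + β_L·length + β_W·width + β_H·height + b_animal + ε` with
  `b_animal ~ N(0, σ²_animal)` and `ε ~ N(0, σ²_resid)` — exactly the
  random-intercept model the forecasting stage assumes, so model-recovery
  tests have a known truth. Defaults: β = (−35, 0.22, 0.18, 40),
  σ²_animal = 25, σ²_resid = 1.
- **Determinism.** All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning, so datasets, measurements, and
  pipeline outputs byte-match across runs with the same seed.

## RGB morphometry

- **Grayscale**: ITU-R BT.601 luma weights.
- **Threshold**: Otsu by default (`threshold_method="fixed"` with an explicit
  value is available). Foreground polarity is decided by a border-majority
  rule: the threshold class that holds at least half of the image-border
  pixels is taken as background. This handles both light-animal-on-dark-floor
  and dark-animal-on-light-floor scenes, and keeps the area QC meaningful
  even when the animal fills more than half the frame.
- **Component selection**: largest 8-connected component; ties broken by
  scan order.
- **Opening**: isotropic (disk) opening with diameter `opening_diameter_px`
  (default 15 px) removes the tail before contour extraction. The kernel must
  be wider than the tail but narrower than the body's tightest curvature:
  for an elliptical body the snout curvature radius is roughly
  `width²/(2·length)` px, so quarter-scale scenes use a 7 px kernel (tests
  and small pipeline runs) — still wider than the 5 px tail. The opening is
  computed on a cropped bounding window of the component for speed; the
  result is identical to operating on the full frame.
- **Rotated box**: the component contour's minimum-area rotated rectangle
  (exact convex-hull-edge algorithm via `shapely`). Length is the longer
  side, width the shorter.
- **Quality control**, in order: no object found → `NO_OBJECT`; any rectangle
  corner within `border_margin_px` (default 2 px) of the frame edge →
  `BORDER_ATTACHED`; component area outside
  [`min_area_frac`, `max_area_frac`] (defaults 1%–40%) of the frame →
  `AREA_OUT_OF_RANGE`. Per-video length and width are medians over frames
  with status `OK`; a video with no accepted frames raises an error rather
  than returning a silent NaN.

## Depth morphometry

- Per-frame height = `camera_height_m` − median depth (in m) in a
  `(2·centroid_window_px+1)²` window (default 5×5) around the segmented
  mask's centroid (rounded half-up to a pixel). Zero depth values are treated
  as invalid and excluded from the median; an all-invalid window raises
  `InvalidDepthError`.
- Per video, standing/sitting separation uses k-means with k = 2
  (`kmeans_restarts = 10` restarts, seeded). The cluster with the higher
  median is standing and its median is the video height. If the two cluster
  means differ by less than `merge_tol_m = 0.05` m — about half the
  standing/sitting gap of a mid-size pig, and well above the 5 mm noise
  scale — the clusters are merged and the overall median is used, so a
  video with a single posture is not split by noise.
- Optionally (`estimate_floor_per_video`), the floor depth is estimated as
  the median depth outside the animal mask instead of trusting the configured
  camera height.

## Descriptor assembly

Per-video medians are inner-joined with reference weights on
`(pig_id, day)`; duplicate keys raise, unmatched rows are logged. Volume is
the product length × width × height (px·px·m; a relative proxy, not a
physical volume). The correlation matrix is the Pearson matrix over
`weight_kg, length_px, width_px, height_m, volume`, with constant columns
yielding NaN plus a warning.

## Weight forecasting

- Model: `weight ~ 1 + length_px + width_px + height_m + (1 | animal)`,
  fitted by REML (`statsmodels` MixedLM; cross-checked against lme4 in the
  test suite). Volume is deliberately excluded: it is a deterministic product
  of the three fixed effects and nearly collinear with them.
- `LMM1` predicts with fixed effects only; `LMM2` adds the training-window
  BLUP of the animal's random intercept. An animal absent from the training
  window gets a zero BLUP (logged).
- Evaluation: sliding window of `window_days = 14` consecutive training days,
  tested `h` days after the window end for horizons 1–4. With 38 study days
  this yields 24, 23, 22, and 21 slides. Slides with fewer than two test
  animals are skipped and logged.
- R² is the squared Pearson correlation between predictions and observations
  (`r2_definition = "squared_correlation"`); the alternative `1 − SSE/SST` is
  available by configuration. The two differ when predictions are biased:
  squared correlation ignores a constant offset, `1 − SSE/SST` penalizes it
  and can be negative. MAE is reported in kg alongside R² for an
  offset-sensitive error measure.

## Acceptance problem sizes

`scripts/acceptance.py` validates descriptor recovery on 50 synthetic videos
of 60 frames (morphometry) and 5 videos of 80 frames (height), rather than
full 1,080-frame videos: per-video medians stabilize well below 60 frames, so
longer videos add runtime without adding information about correctness. The
pass criteria themselves (3 px, 0.01 m, oracle agreement, 3·SE parameter
coverage) are independent of video length. The frame-count arithmetic
(1,080 frames/video, 216,000 frames per 200-video corpus) is checked
separately as arithmetic.

## Limitations

- The synthetic silhouette is a tailed ellipse; real pigs have legs, ears,
  and non-elliptical outlines, and real segmentation contends with occlusion,
  multiple animals, shadows, and reflective wet floors. The generator
  validates the measurement chain, not a segmentation model for real footage.
- Depth noise is i.i.d. truncated Gaussian; real time-of-flight/stereo depth
  has structured artifacts (edge bleeding, dropouts, distance-dependent
  noise) only partially represented by the zero-invalid-pixel convention.
- The growth model is linear with a random intercept only; real growth curves
  are nonlinear and animals differ in slope as well as level. The forecasting
  results on synthetic herds therefore show the behavior of the estimator
  under its own assumptions, not expected field accuracy.
- Length and width are reported in pixels; converting to metres requires the
  camera model and the animal's height plane, which is out of scope here.
- The posture model is binary (standing/sitting); intermediate postures
  or lying-flat frames would need k > 2 or a different separation rule.
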