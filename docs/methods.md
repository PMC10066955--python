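# Methods

## Problem setting

A low-altitude UAV survey of a wild *Lamiophlomis rotata* (LR) stand yields
an RGB orthomosaic of 10⁸–10⁹ pixels at a ground-sample distance (GSD) of a
few millimetres.  The analysis goal is a plant-level census: how many
individual rosettes are present, where they are, how much leaf area each
carries, and — through allometry — what the stand's harvestable dry-weight
yield is.  The package decomposes this into tiling, per-tile instance
segmentation, cross-tile census, yield estimation and evaluation; every
stage is specified against exact synthetic ground truth.

## Tiling

Tiles are non-overlapping `T x T` squares (default 512) in row-major order;
0-based (row, col) coordinates and half-open intervals are used throughout.
Non-overlap is what makes pixel totals and plant counts additive across
tiles.  Remainder tiles at the right/bottom edges are zero-padded to full
size with the valid region recorded; padding keeps the detector input shape
uniform while the valid-region bookkeeping keeps the tile→mosaic coordinate
map bijective (reassembling valid regions reproduces the source raster
bit-exactly, a tested invariant).  The train/test tile split uses
round-half-away-from-zero on `n x fraction`, which reproduces a 6:4 split of
5,700 tiles as 3,420/2,280.

## Synthetic scenes

The generator emulates the statistical structure of degraded alpine meadow
rather than its photometry:

* **Background** — lightish yellow-green base with Gaussian-smoothed noise
  (grass texture), brown elliptical bare-soil patches covering a configured
  area fraction, and elongated green tufts as weed distractors whose colour
  band overlaps the plants' but whose shape does not.
* **Plants** — a Thomas-style cluster process: a configurable fraction of
  plants arrives in 2–3 member clumps scattered as a Gaussian (default
  σ = 0.12 m) around a common parent, the rest uniform; the total count is a
  single Poisson draw with mean `density x area`, so scene counts are
  Poisson by construction (verified across 100 seeds).  Clump members may
  touch; their labels stay distinct, producing the merged-patch failure mode
  that makes rosette separation hard.
* **Rosette geometry** — silhouette `r(ψ) = R(0.92 + 0.08 cos 4(ψ−φ))` with
  random phase φ, the four opposite-paired leaves expressed as interior
  shading.  A strongly four-lobed outline was rejected deliberately: its
  axis-aligned bounding box shrinks to ~0.75 of the nominal diameter at 45°
  rotation, which would decouple the configured size distribution from what
  masks measure.  With the scalloped disk the bounding-box long side stays
  within ~8 % of the nominal diameter at any rotation (tested: a 10 cm plant
  at 5 mm GSD always spans 18–22 px).
* **Occlusion** — later-drawn plants overwrite earlier ones; each label is
  then reduced to its largest 4-connected component so the label raster,
  instance table and pixel counts remain mutually exact.
* **Allometry** — each plant's true dry weight is `slope x mask_area +
  intercept` (default slope 700 g/m², intercept 0, noise 0).  The emitted
  table stores length = bounding-box long side and width = mask_area/length,
  so length x width equals mask leaf area exactly.  This is a deliberate
  design choice: it makes the chain "fit allometry on field-style rows →
  apply to census leaf areas" exactly invertible, so the oracle-backend
  yield-recovery invariant (< 0.1 % error) isolates census defects instead
  of conflating them with the bbox-vs-area shape factor (~1.2 for these
  outlines).  The standalone `generate_allometry` adds Gaussian noise
  truncated at zero weight.

Scene parameters the field does not constrain — plant density (default
1.5 m⁻²), weed density (0.5 m⁻²), bare-patch fraction (0.08) — are free
parameters chosen once as a moderately dense stand, not a reproduction of
any particular site; published LR surveys do not report per-m² densities.

What passing on synthetic scenes does *not* show: robustness to real
radiometry (shadows, exposure gradients, atmospheric effects), to
photogrammetric stitching artefacts, or to vegetation whose colour *and*
shape both match LR; the colour bands of plants and background are cleanly
parameterised here, so the classical segmenter's synthetic accuracy is an
upper bound, not a field estimate.

## Classical reference segmenter

Deterministic and seed-free: HSV threshold (hue 0.25–0.45, saturation
≥ 0.25, value ≤ 0.52 — dark foliage against brighter grass), morphological
opening (disk radius 1), hole filling, then marker-based watershed on the
Euclidean distance transform with markers from distance-peak maxima at a
minimum separation of 7 px; components under 9 px are dropped.  The
confidence score is an explicit shape prior, `roundness x relative
greenness` with roundness `4πA/P²` clipped to 1 and greenness
`mean(G − (R+B)/2)/128` clipped to [0, 1]: compact dark rosettes score
≈ 0.4–0.8, elongated tufts lower, which is what makes score-threshold
filtering meaningful.  Watershed splitting is the package's answer to
touching rosettes; disabling it reproduces the characteristic undercount on
clumped stands (a tested, directional behaviour).  The score threshold
applied at inference is configuration, not a constant — no single value is
canonical.

## Census

Within a tile, duplicate masks are removed by greedy mask-IoU NMS (default
IoU 0.5, matching the evaluation threshold; highest score wins, input order
breaks ties).  Surviving masks are lifted to mosaic coordinates, where
masks from *different* tiles that are 8-connected across a shared border
merge into one record — the minimal policy that makes counts invariant to
where the tile grid falls (tested across tile sizes 256/512/1024).
`merge="none"` preserves the literal split-tolerant alternative.  Pixels are
counted from the final painted raster, so overlapping detections never
double-count a pixel (conservation is a tested invariant).  Touching plants
*within* a tile are deliberately not merged: they are distinct detections,
and separating them is the segmenter's job.  Records carry centroid, pixel
count, leaf area `pixels x GSD²` and mean member score; exports are CSV,
GeoJSON points (the distribution-map product) and a summary JSON.

## Yield

`fit_allometry` is ordinary least squares of dry weight on length x width
with R² computed explicitly as `1 − SS_res/SS_tot`; fitting requires ≥ 3
rows and a non-degenerate predictor.  At inference the line is applied to
mask leaf area.  The intercept's treatment at inference is genuinely
underdetermined when the fit is applied per plant versus in aggregate; both
modes are provided, defaulting to per-plant application with negative
predictions clamped at zero (with a zero intercept and no clamping the two
modes coincide exactly, a tested identity).  The count-based estimator is
`count x mean dry weight / 1000` kg.  Reports round to 2 decimals only at
the reporting boundary; internal quantities keep full precision.  Rounding
is half-away-from-zero via the shortest decimal representation, which is
what reproduces printed survey-table averages (banker's rounding does not).

## Evaluation

Instance matching is greedy in score-descending order: each prediction
claims the highest-IoU unmatched truth at or above the threshold, ties
going to the lower truth id.  Greedy matching is not globally optimal on
arbitrary overlap structures — a high-scoring prediction can claim the only
truth reachable by a neighbour — so the equality-with-exhaustive-assignment
property is asserted on fixtures where each prediction overlaps at most one
truth above threshold (where greedy is provably optimal), and as an
inequality (`greedy ≤ optimal`) elsewhere.  AP@50 follows the COCO
101-point interpolation; AR averages matched recall over IoU 0.50:0.05:0.95.

Counting metrics follow the printed equations exactly, with one stated
policy: images with a zero truth count are excluded from the Acc sum (their
relative-error term is undefined) but kept in MAE/RMSE/R².  When every image
has zero truth, Acc is reported as undefined (NaN) rather than a number.
The matched-pair count regression reports the OLS slope/intercept of
automatic on manual counts but computes R²/RMSE against the identity line —
the same formulas as the counting metrics, a tested consistency — plus the
fraction of points above y = x as an over-counting flag.

The cross-validation harness assigns tiles randomly to k folds (default 4),
scores each held-out fold, repeats the assignment (default 5 times), and
averages fold values arithmetically; cross-site summaries are arithmetic
means of per-site values, the same aggregation that produces published
survey averages.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through named
`numpy.random.Generator` instances; no global state.  Identical scene spec →
bit-identical raster; identical pipeline config → bit-identical numeric
outputs (tested at file level), and every output file carries the SHA-256
hash (truncated) of the resolved config that produced it, excluding only
the output path.  Degenerate inputs fail loudly: empty rasters, zero-area
masks, zero-variance predictors, k > n folds and out-of-range scores all
raise `ValueError`/`KeyError` rather than propagating NaNs silently.

Problem sizes in the shipped tests and acceptance script (512–1024 px
scenes, 10–20 scenes per property, n = 86 allometry samples) were chosen as
the smallest sizes at which every property is meaningfully exercised —
Poisson count bands need ~100 seeds, slope recovery needs the field-sample
n, border merging needs multi-tile scenes — keeping a full run in the
seconds-to-minutes range on one CPU.

## Known limitations

* The classical segmenter is a reference implementation for contract and
  census testing, not a competitor to a trained CNN on real imagery; weeds
  matching LR in both colour and compactness defeat its score prior.
* Census-level merging cannot split genuinely connected clumps; that error
  mode is inherited from the segmenter.
* Leaf area uses one global GSD; on sloped terrain the true per-plant GSD
  varies and area-based yield inherits that bias (terrain-corrected GSD is
  out of scope).
* The allometric law is linear by design; saturating growth forms would
  need a different functional form.
* AR is reported over IoU 0.50–0.95 while AP is reported at IoU 0.50; the
  two are not directly comparable and are labelled accordingly.
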