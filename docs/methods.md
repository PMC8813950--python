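# Methods

## The estimation problem

Cloud cover over a landscape is dominated by synoptic meteorology; the
land-surface contribution of a forest is a small residual on top of it. The
space-for-time design removes the shared meteorological signal by
differencing coexisting surface states inside a small window: unchanged
forest versus unchanged non-forest for the *potential* effect
(ΔCloud = Cloud_forest − Cloud_nonforest), and forest-loss pixels versus
unchanged forest for the *actual* effect
(ΔCloud_loss = Cloud_loss − Cloud_forest). Because both classes in a window
sit under the same weather, systematic ΔCloud indicates a surface-driven
preference: enhancement when forests trigger moist convection (higher
sensible heat, deeper boundary layer), inhibition when the thermal contrast
between a cool, moist forest and warmer surroundings drives a mesoscale
circulation that subsides over the forest.

## Pipeline and parameters

1. **Land-state classification.** From baseline tree cover, yearly loss,
   gain and a categorical land-cover map:
   - unchanged forest: tree cover > `forest_threshold` (0.5) and change
     < `change_threshold` (0.05);
   - unchanged non-forest: tree cover ≤ 0.5, change < 0.05, land-cover class
     not water/wetland/snow-ice (these classes would contaminate the
     non-forest reference);
   - forest loss: net loss > `loss_threshold` (0.15) — a deliberately strong
     signal so the loss response is detectable against cloud variability;
   - everything else: changed-other; nodata: masked.

   "Change" for the unchanged test defaults to gross turnover (loss + gain):
   a pixel that lost and regained 0.2 of its cover is genuinely disturbed
   even though its signed net change is zero. The signed reading
   (|gain − loss|) is available via `ClassifierConfig.change_metric`; the
   loss test always uses the signed net loss. Tree cover exactly at the
   threshold counts as non-forest (forest requires strictly greater).

2. **Window search.** Windows (default `size` 9 px = 0.45°, centers `step`
   5 px apart, i.e. half-overlapping) are fully interior — partial edge
   windows would bias class counts — and retained only where at least one
   pixel exceeds the change trigger, keeping the comparison local to real
   transitions. Water pixels and their 8-neighbor buffer are excluded from
   both classes (coastal cloud suppression would alias into ΔCloud). A
   window needs at least `min_count_forest` = `min_count_nonforest` =
   `min_count_loss` = 3 pixels per class — a floor chosen for mean
   stability; the sources this emulates do not state one — and is rejected
   whole when the standard deviation of elevation across it exceeds
   `elev_sd_max` = 100 m, removing mountainous windows where orographic
   clouds would swamp the vegetation signal. Rejections are typed outcomes
   (`min_count_*`, `elevation_sd`, …) and are counted, so
   placed = retained + rejected is checkable.

3. **Display aggregation.** Window samples are binned by center coordinate
   (half-open cells) to a `display_resolution` (0.5°) grid of unweighted
   means. Sign splits, latitudinal profiles and all reported percentages are
   computed over display cells. Zero deltas count as enhancement in sign
   splits (configurable; zeros have measure zero for continuous fields).

4. **Attribution.** Per window, OLS of cloud on (tree, elevation, 1) gives
   sensitivities S_tree (cloud fraction per tree fraction) and S_ele (per
   meter). The regression needs ≥ 4 unmasked pixels (one more than the
   parameter count), a nonzero tree cover, and a full-rank design (constant
   elevation is rejected with a reason code). Sensitivities and the window
   differences ΔTree, ΔEle are averaged to the display grid *before*
   multiplying into components ΔCloud_tree = S_tree·ΔTree and
   ΔCloud_ele = S_ele·ΔEle. A cell's class is the component that shares
   ΔCloud's sign with the larger magnitude (Tree± / Orography±); if neither
   shares the sign, or ΔCloud is exactly zero, the cell is Other; exact
   magnitude ties go to tree cover, the driver of interest. "Explained" is
   the coefficient of determination (squared Pearson correlation) of
   original against reconstructed ΔCloud across cells; an absolute-ratio
   variant (Σ|rec|/Σ|orig|) sits behind a flag since either reading is
   defensible.

   The tree field fed to the regression should be the cover that actually
   co-varies with the cloud average — the multiyear mean cover
   (`SyntheticScene.tree_multiyear_mean`), not the baseline year — because
   in loss pixels the cloud record reflects the declining cover.

5. **Cloud types.** The ISCCP 3 × 3 grid of cloud-top pressure (boundaries
   440 / 680 hPa) by optical depth (3.6 / 23) yields codes 1–9 (cirrus …
   stratus); boundary values fall into the higher-altitude / thinner bin.
   Codes follow the standard altitude ordering (1–3 high, 7–9 low); the
   convective set is {3, 7, 8}, shallow convective {7, 8}. Per-type
   fractional covers are required to sum to the total cloud fraction pixel
   by pixel (averaging daily type-indicator maps guarantees this), so the
   per-type window effects sum to the total effect exactly — asserted to
   1e-10. A cell's dominant type is the type sharing the total effect's
   sign with the largest magnitude, ties to the smallest code, none when no
   type qualifies.

6. **Trends.** For a hotspot region, each year's mean cloud field is run
   through the loss estimator and averaged over display cells with loss
   fraction > 0.05. The companion tree-cover deficit is
   ΔTree_year = (Tree2000_loss − Tree2000_forest) − Σ₂₀₀₁^year
   (Treeloss_loss − Treeloss_forest): the accumulated excess loss in loss
   pixels is *subtracted*, so ΔTree declines as clearing progresses — the
   only sign convention consistent with a deficit that deepens over time.
   Trends are OLS of the series (× 100, %) on year with a two-tailed
   t-test; the total change is slope × inclusive year count (2002–2018 →
   17), the convention that reproduces all four published slope→total pairs
   (0.046→0.78, 0.070→1.19, 0.005→0.09, −0.012→−0.20). Degenerate constant
   series get slope 0 and an undefined (NaN) p.

7. **Scale dependency.** The scene is block-aggregated to 0.1–1° (mean for
   continuous fields, majority with smallest-code tie-break for land
   cover), the classifier and estimator re-run with two window settings per
   resolution, and the enhancement/inhibition shares tabulated. Because
   mesoscale inhibition lives at sub-window scales, its spatial coverage
   can only shrink as resolution coarsens.

8. **Sensible-heat linkage.** Each window's dominant (modal) land-cover
   pair — forest class, non-forest class, ties to the smallest code — keys
   a ΔH lookup (W/m²) in a conversion table per 1° cell; a missing key is a
   typed missing value, never zero. Daytime flux means cover local hours
   8–16 inclusive (9 values; the endpoint convention is ours). Paired-site
   records are matched to the 1° effect map at the midpoint of the two
   sites, built without the elevation filter and water buffer to maximize
   coverage; pairs are excluded — values untouched — when the midpoint cell
   is nodata or |ΔH| > 200 W/m². The ΔH–ΔCloud relationship is summarized
   with geometric-mean (reduced major axis) regression,
   slope = sign(r)·sd(y)/sd(x) (both variables carry error), and Spearman
   rank correlation via `scipy.stats.spearmanr` (the tests check it against
   an explicit rank-then-Pearson computation).

## The synthetic-data generator

Scenes are a pure function of a `SceneConfig` (same seed → bit-identical).
Cloud cover in year *y* is

    cloud_y = clip(b0 + S_tree·tree_y + S_ele·elevation
                   + spatial_noise + interannual_y, 0, 1)

with `tree_y` the baseline cover minus accumulated loss. Defaults emulate a
0.05° study domain: b0 = 0.45 (typical mean cloud fraction), S_tree = 0.05
(so a full forest/non-forest contrast of ~0.85 yields ΔCloud ≈ 0.04, the
order of the strongest observed effects), S_ele = 1e-4 /m (positive:
orographic lifting), spatial noise sd 0.02 with a 3-cell correlation length,
interannual noise sd 0.01 applied as one scalar per year scene-wide (it then
cancels exactly in every within-window difference, as the real estimator's
differencing is designed to achieve). Tree cover is a squashed (tanh)
correlated field giving crisp forest (~0.95) and non-forest (~0.05) with
transition zones; loss patches are contiguous blobs BFS-grown from random
forest seeds, losing `loss_rate_per_year` (0.03) per pixel per year, capped
so cover never goes negative. Water is a correlated-field quantile
threshold; snow flags follow a latitude-band × month table and set monthly
cloud values to nodata. The coupling sign can vary by longitude bands
(`s_tree_regions`) or as small blobs of one sign in a background of the
other (`s_tree_patch`) — the latter is what makes the scale experiment
meaningful, since the blobs are resolved by 0.05° windows but averaged away
inside 1° pixels.

Optional extras: per-type cloud covers split the total into a
tree-coupled shallow-convective (stratocumulus) part, an orographic cirrus
part and a baseline stratus part — constant shifts keep covers nonnegative
without touching any forest/non-forest difference, and a proportional
rescale preserves the exact sum identity under clipping; representative
cloud-top-pressure and optical-depth fields are consistent with the
locally dominant type. The sensible-heat table assigns each 1° cell
ΔH = 1000 W/m² per unit S_tree of its local coupling plus N(0, 5 W/m²)
jitter, so ΔH ≈ 50 W/m² where S_tree = 0.05, the order of observed
forest/non-forest flux contrasts, with the table's sign tracking the
coupling sign by construction.

What the generator does *not* emulate: radiative transfer, diurnal
convection physics, orographic flow, wind-direction asymmetries, spatially
structured interannual variability, and sensor artifacts. Passing tests
therefore demonstrate that the estimator recovers known ground truth under
the model's own assumptions (linear coupling, additive stationary noise) —
not that the real-world magnitudes are reproduced, which would require the
multi-year satellite record.

## Numerical choices and statistics

- Grids are cell-centered, axes strictly evenly spaced (tolerance 1e-9°),
  extent half-open [south, north) × [west, east); all window indexing is
  0-based. Aggregation ignores nodata and yields nodata only for all-nodata
  blocks; majority ties break to the smallest category code (deterministic,
  order-independent).
- Cloud quantities are fractions in [0, 1] internally; reporting layers
  multiply by 100.
- GeoTIFF files carry georeferencing in the standard ModelPixelScale /
  ModelTiepoint tags and nodata in GDAL_NODATA (sentinel −9999); stacks go
  through CF-style NetCDF (scipy backend, NetCDF3 classic). Round-trips are
  bit-exact for float64.
- The per-window OLS uses `numpy.linalg.lstsq` after a column-scaled rank
  check (tolerance 1e-10) so that meter-scale elevation values do not mask
  genuine rank deficiency.
- Tie-breaks are always deterministic and documented: earliest month/hour
  for timing maxima, smallest code for categories and cloud types, tree
  cover for attribution magnitude ties.
- **Standard errors under spatial correlation.** Overlapping windows sharing
  one correlated noise field are not independent samples; a naive
  sd/√n_windows standard error is too small and the whole-scene mean ΔCloud
  wobbles with the realized forest–noise covariance. The null-calibration
  check therefore computes the standard error across 1° display cells,
  which are wide relative to the noise correlation length (3 cells = 0.15°)
  and approximately independent, and uses a domain large enough (512², ≈
  1,800 windows, ≈ 480 cells) for the ±2 SE and sign-split bounds to have
  power. Similarly, mean-sensitivity recovery is assessed on a 192² domain
  (≈ 550 windows) where the window-mean estimator's sampling noise is small
  relative to the 10% tolerance; on smaller domains the check is
  variance-limited, not biased.

## Test-suite problem sizes

The default suite runs in a few seconds: most tests use a 64 × 64, 5-year
fixture scene; calibration and recovery properties use 128²–512² scenes as
noted above; the scale experiment uses a 320² scene with 0.6°-scale
inhibition blobs. `scripts/acceptance.py` regenerates all of these from the
`--seed` argument and completes in well under a minute.

## Known limitations

- Geographic lat/lon grids only; no reprojection, no out-of-core tiling.
- OLS sensitivities carry no spatial-autocorrelation correction; per-window
  estimates in low-contrast windows are noisy (by design they are averaged,
  and the displays aggregate further).
- The window trigger, thresholds and filters are faithful to the emulated
  design but all exposed in configs; changing them changes the estimand.
- The conversion table is a plain keyed input; the package does not compute
  energy-balance residuals or land-model tile fluxes that would generate a
  real table, and it follows the convention of labeling the combined
  sensible + ground heat flux simply "H".
- Gain rasters are treated as plain inputs with no date semantics.
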