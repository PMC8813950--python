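# forestcloud

Space-for-time estimation of forest effects on cloud cover from gridded
rasters.

Whether a forest enhances or suppresses the clouds above it is hard to
measure directly: cloud cover responds to synoptic weather far more strongly
than to the land surface. `forestcloud` implements the observational
work-around — a **space-for-time substitution**: inside a small moving window
(default 9 × 9 cells of a 0.05° grid), coexisting unchanged forest and nearby
unchanged non-forest share the same meteorology, so the difference of their
multiyear mean cloud-cover fractions

```
ΔCloud = Cloud_forest − Cloud_nonforest            (potential effect)
```

isolates the land-surface contribution. Positive ΔCloud is cloud enhancement
over forest, negative is inhibition (the signature of a thermally driven
mesoscale circulation whose subsiding branch sits over the forest). The same
machinery compares pixels that lost forest against nearby intact forest,

```
ΔCloud_loss = Cloud_loss − Cloud_forest            (actual effect)
```

quantifying what deforestation has already done to local cloudiness.

Around this core the package provides, as importable modules and as pipeline
stages:

| module | what it does |
| --- | --- |
| `grid` | raster data model (`GridField`/`GridStack`), block mean/majority aggregation, GeoTIFF + NetCDF IO |
| `synth` | synthetic-scene generator with known ground truth (linear cloud model, patchy loss, water/snow masks, cloud-type and sensible-heat extras) |
| `surface` | land-state classification: unchanged forest (tree cover > 0.5, net change < 0.05), unchanged non-forest, forest loss (net loss > 0.15), water buffering, snow masking |
| `windows` | window placement at change locations, class means, elevation-s.d. filter (> 100 m rejected), 0.5° display aggregation, sign/latitude/season/diurnal summaries |
| `attribution` | per-window OLS of cloud on (tree, elevation); splits ΔCloud into `S_tree·ΔTree` + `S_ele·ΔEle` and classifies cells into Tree±, Orography±, Other |
| `cloudtypes` | nine-type ISCCP classification from cloud-top pressure × optical depth; per-type ΔCloud with an exact sum identity; convective dominance shares |
| `trends` | annual ΔCloud_loss series over loss hotspots, progressive ΔTree bookkeeping, OLS trends in %/yr with totals over the inclusive year span, multi-resolution rescale experiment |
| `heatlink` | dominant land-cover pairs, ΔH conversion-table lookup, daytime means, paired-site matching, geometric-mean regression, Spearman rank correlation |
| `cli` | `forestcloud` command: simulate → classify → effects → attribute → cloudtypes → trends → scale → heatlink → report |

## Worked example

A synthetic scene with two coupling regimes — clouds inhibited over forest in
the western half (S_tree = −0.05), enhanced in the eastern half (+0.05) — and
intensive forest-loss patches:

```yaml
# config.yaml
scene:
  n_lat: 96
  n_lon: 96
  years: [2002, 2018]
  seed: 7
  s_tree_regions: [-0.05, 0.05]
  loss_patch_count: 14
  loss_patch_size: 60
  include_cloud_types: true
window: {size: 9, step: 5}
display_resolution: 0.5
```

```
forestcloud run --config config.yaml --outdir out --seed 7 \
    --stages classify,effects,attribute,cloudtypes,trends,heatlink,report
cat out/report.txt
```

prints

```
[effects]
 percent_enhancement  percent_inhibition  n_samples  n_rejected
           61.290323           38.709677         58          63

[attribution]
       class   percent
       Tree+ 58.064516
       Tree- 29.032258
  Orography+  3.225806
  Orography-  9.677419
       Other  0.000000
explained_r2  0.902345

[cloud types]
 percent_convective  percent_shallow_convective  n_cells
          80.645161                   80.645161       31

[trends]
region  slope_pct_per_year      p_value  total_change_pct  n_years
 scene            0.025123 3.086091e-55          0.427095     17

[heat link]
 gm_slope  gm_intercept  spearman_rho      p_value  n_windows
 0.000768       -0.0012      0.781859 4.337613e-13         58
```

Reading the numbers: 61% of 0.5° display cells show cloud enhancement and
39% inhibition, matching the two injected coupling regimes; the attribution
step assigns 87% of cells to tree cover (58% Tree+, 29% Tree−) with the
reconstruction explaining R² = 0.90 of ΔCloud; where effects exist they are
carried by the shallow-convective (stratocumulus) cover the generator couples
to tree cover; the annual loss-effect trend of +0.025 %/yr accumulates to
+0.43% over the 17-year span (loss in the inhibition regime raises cloud
cover); and window ΔCloud rank-correlates at ρ = 0.78 with the sensible-heat
difference ΔH of the dominant land-conversion pair, the mechanism that sets
the sign of the effect.

Library use mirrors the stages:

```python
import forestcloud as fc

scene = fc.generate_scene(fc.SceneConfig(seed=7))
cmap = fc.classify_scene(scene)
samples, rejected = fc.potential_effects(
    cmap, scene.cloud_yearly.mean(), scene.elevation, scene.water_mask)
effect_map = fc.aggregate_to_display(samples, 0.5)
print(fc.sign_fractions(effect_map))
```

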