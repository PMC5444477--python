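# anisocell

Organ-centric 3D cell-shape analysis for cylindrical plant tissues.

During seed germination the embryonic axis elongates purely by cell
expansion, and the expansion is strongly non-uniform: cells near the
radicle grow more than cells higher up the hypocotyl, and concentric
cortical cell layers of different starting sizes grow at different
relative rates. Quantifying this requires (i) segmenting every cell of a
membrane-stained confocal stack in 3D, (ii) measuring each cell in an
*organ-aligned* coordinate frame — longitudinal (along the organ axis),
radial (toward/away from the axis), circumferential (around it) — and
(iii) comparing per-layer, per-position distributions of cell volume and
directional lengths between time points. `anisocell` implements the full
workflow plus a synthetic-tissue generator with closed-form ground truth,
so every stage can be validated without any imaging data.

It is aimed at plant developmental biologists and image-analysis
methodologists who want a scripted, reproducible equivalent of the
MorphoGraphX / 3DCellAtlas-style interactive workflow.

## The measurement and statistical model

**Geometry.** A Bezier curve **c**(t), t ∈ [0, 1], is fitted through the
centre of the stele (least squares on chord-length parameters with a
Levenberg–Marquardt polish). For a cell with centroid **x**, the frame is

- longitudinal **l** = ĉ′(t*), the unit tangent at the nearest axis point,
- radial **r** ∝ (**x** − **c**(t*)) orthogonalised against **l**,
- circumferential **e** = **l** × **r**,

and each directional length is the extent (max − min) of the cell's
voxels projected onto the corresponding frame vector; volume is voxel
count × voxel volume. Layers (1 = epidermis, increasing inward) are
recovered by 1-D clustering of radial distances; axial positions H1
(nearer the radicle, t < 0.5) and H2 are windows of t.

**Statistics.** For each layer × position × metric, growth between the
two time points is the ratio of sample means computed on the log scale,

```
ratio = exp(ln x̄ − ln ȳ)          (≡ x̄ / ȳ)
interval = t_{level, nx+ny−2} · √( S²ln(x)/nx + S²ln(y)/ny )
CI = exp( ln x̄ − ln ȳ ± interval )
```

with S²ln(·) the sample variance of the log-transformed values. Multiple
comparisons across m cell layers are Bonferroni-corrected via the level
1 − α/m (99.3% for α = 0.05, m = 7). Time-point differences use pooled
two-tailed Student's t-tests; position dependence of growth uses the
interaction term of a two-way time × position ANOVA on the log response.
Percentile bootstrap CIs (1000 resamples) are available for distribution
summaries.

## Worked example

```python
import anisocell as ac

spec = ac.OrganSpec(organ_radius=18.0, segment_length=24.0, n_layers=3,
                    per_layer_cell_dims=[(8, 4, 5), (8, 5, 6), (8, 5, 6)],
                    voxel_spacing=(0.5, 0.5, 0.5))
tissue = ac.build_tissue(spec, seed=1)            # labels + closed-form truth

growth = ac.GrowthSpec(                            # H1 grows more than H2
    ratios={(l, p, m): r
            for l in (1, 2, 3)
            for p, rs in (("H1", {"long": 1.5, "rad": 1.2, "circ": 1.05}),
                          ("H2", {"long": 1.2, "rad": 1.1, "circ": 1.05}))
            for m, r in rs.items()},
    sigma=0.1)
grown = ac.apply_growth(tissue, growth, seed=2)

results = ac.compare_layers(tissue.records, grown.records, m=7)
print(results.summary())
```

prints (abridged):

```
Layer-by-position growth comparison
  layers analysed: [1, 2, 3]
  positions: ['H1', 'H2']   metrics: ['volume_um3', 'len_long_um', 'len_rad_um']
  alpha = 0.05, m = 7 comparisons -> corrected level 99.3%
  ratio CIs at 99.3%

 layer position      metric  ratio  ci_low  ci_high    t_p  t_sig  anova_p  anova_sig
     1       H1  volume_um3 1.8494  1.6643   2.0552 0.0000   True   0.0000       True
     1       H1 len_long_um 1.4983  1.4146   1.5869 0.0000   True   0.0000       True
     1       H2  volume_um3 1.3800  1.2689   1.5008 0.0000   True   0.0000       True
     ...
```

Reading it: epidermal (layer 1) cell volume in H1 grew by a factor 1.85
(99.3% CI 1.66–2.06) versus 1.38 in H2 — the imposed longitudinal ratio
1.5 × radial 1.2 × circumferential 1.05 ≈ 1.89 is recovered within its
interval, the time difference is significant at the corrected threshold
(`t_sig`), and the H1-vs-H2 growth difference is flagged by the ANOVA
interaction (`anova_sig`).

The same analysis runs end to end from a shell, including rendering,
watershed segmentation and measurement of the synthetic stacks:

```
anisocell all --config cfg.yaml --seed 1 --out out/
anisocell segment --stack out/generate/rep1_membrane.tif --out seg.tif
anisocell compare --t0 a.csv --t1 b.csv --out results.csv
```

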