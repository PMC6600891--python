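# rofseg

Fully automated counting of immunofluorescently stained macrophages in
whole-slide tissue images, built on Rudin–Osher–Fatemi (ROF)
total-variation cartooning, a floating intensity threshold and
rule-based shape classification.

Counting tumor-associated macrophages (e.g. CD14⁺/CD163⁺ cells in
lymphoma sections) is hard for threshold-based tools: the cells vary
wildly in size and shape, staining intensity is inhomogeneous even
within one cell, and autofluorescent structures such as erythrocytes,
tissue folds and vessels mimic signal.  `rofseg` addresses this with a
deterministic, training-free pipeline intended for pathology image
analysts who need repeatable counts, densities and double-stain
percentages from single-channel 8-bit fluorescence scans.

## Method

For each stain channel image I⁽⁰⁾ (0.45 μm/px):

1. **Cartooning.** I⁽²⁾ = max(I⁽⁰⁾ − median₃₁ₓ₃₁(I⁽⁰⁾), 0) normalises
   background brightness; the ROF filter
   min_u ½‖u − I⁽²⁾‖² + λ·TV(u) then yields an edge-preserving cartoon
   I⁽³⁾ (Chambolle dual-projection solver).
2. **Evaluation region.** From the DAPI-channel cartoon, every pixel
   with intensity ≥ 10 seeds a centred 31×31 px white square; their
   union is the tissue mask I_eval.  The nucleus count is estimated as
   (#pixels ≥ 10)/100.  For ROI images the whole frame is evaluated.
3. **Floating threshold.** For i from round(mean I⁽³⁾) to 255, pixels
   < i are masked and the remaining connected features F are
   classified by five descriptors — size s, convex-hull size c, axis
   ratio r of the covering ellipse, perimeter p₁, equal-area-circle
   perimeter p₂:
   - s > s_max: keep for the next threshold (may split),
   - s < s_min: reject (erythrocyte-scale),
   - otherwise accept iff c/s ≥ 1 + c_min/100 (irregular, not round),
     r ≤ r_max (not elongated) and p₁/p₂ ≤ p_max (regular boundary).
   Accepted features go to the output masks I_segm/I_conv and are
   removed; every feature is counted at most once.
   Presets: ROI (140, 800, 7.5, 3, 2) and whole-sample
   (160, 1500, 7.5, 3, 2.5) for (s_min, s_max, c_min, r_max, p_max).
4. **Statistics.** A channel-A feature is *double-stained* when ≥ 20 %
   of its convex hull is covered by channel-B hulls.  Counts are
   normalised to density (cells/mm²), cell percentage (per estimated
   nucleus) and area percentage; validation against manual 3×3 px
   cross tags uses exact hull matching and Pearson correlation; tiled
   samples can be aggregated and stride-subsampled at 50 %/25 %.

A seeded synthetic-data generator (`rofseg.synthetic_data`) produces
stain/DAPI triples with ground truth — irregular blobs, ~100 px round
erythrocyte distractors, bright elongated fold artifacts, defocus blur
and background autofluorescence — for testing the whole pipeline.

## Worked example

```sh
rofseg synth --out-dir demo --seed 3 --n-macrophages 25
rofseg segment --channel-a demo/synth_A.png --channel-b demo/synth_B.png \
               --dapi demo/synth_dapi.png --out-dir demo/out
```

prints

```
segmenting channel A (600x900 px)...
channel A: count=26, initial threshold=5
segmenting channel B (600x900 px)...
channel B: count=15, initial threshold=4
double-stained: 15/26 (57.69 %)
outputs written to demo/out
```

26 macrophage-like features were accepted in channel A (25 planted;
one was split by nonuniform staining, a known failure mode of
intensity thresholding), 15 of them also stained in channel B.
`demo/out` holds the three masks per channel (`*_eval.png`,
`*_segm.png`, `*_conv.png`), a key=value logfile with per-feature
records, and `metrics.csv` with density, cell percentage and area
percentage per channel.  Validating against the generator's tag mask:

```sh
rofseg validate --tags demo/synth_tags.png \
                --conv-mask demo/out/channel_A_conv.png \
                --segm-mask demo/out/channel_A_segm.png
```

```
 n_tags  n_features  n_matched  pct_matched_of_tags  pct_matched_of_features
     25          26         25                100.0                96.153846
```

— every planted cell is attributable to a detected hull.

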