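# Methods

## Pipeline model and assumptions

`rofseg` treats macrophage detection as a segmentation problem on a
*cartoon* of each single-channel fluorescence image: a version of the
image in which slowly varying background has been subtracted and
small-scale oscillation removed while edges are preserved.  The
working assumptions are those of immunofluorescence slide scans at
0.45 μm/px: one active channel per image (so RGB renderings collapse
losslessly to greyscale via the Euclidean modulus), 8-bit intensities,
stain intensity that varies strongly between and within cells, and a
DAPI channel that is much more regular than the antibody channels.

Because no reliable shape prior exists for macrophages, detection is
rule-based rather than template- or learning-based: a connected
feature is accepted only if its size lies in [s_min, s_max], its
convex hull exceeds its area by at least c_min percent (macrophages
are irregular; round objects such as erythrocytes and nuclei are not),
its covering-ellipse axis ratio is at most r_max (folds and vessels
are elongated), and its perimeter is at most p_max times that of the
equal-area circle.  The floating threshold makes the approach robust
to staining inhomogeneity: a feature too large at a low threshold is
left alone and re-examined at higher thresholds where it may decompose
into acceptable parts; every accepted or rejected feature is removed
from the working image, so features are counted at most once and the
accepted set is pairwise disjoint by construction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| pixel size | 0.45 μm | physical pixel edge of the scans |
| median window | 31×31 px | background estimation scale; replicate-padded borders avoid dark rims at image edges |
| ROF weight λ | 10 (intensity units) | TV regularisation strength |
| ROF iterations / tol | 200 / 1e-4 | Chambolle solver stopping |
| DAPI threshold | 10 | fixed threshold on the DAPI cartoon |
| evaluation square | 31×31 px | neighbourhood credited as tissue around each bright DAPI pixel |
| px per nucleus | 100 | nominal nucleus area for the nucleus-count estimate |
| rule preset "roi" | (140, 800, 7.5, 3, 2) | (s_min, s_max, c_min, r_max, p_max) for 900×600 px ROIs |
| rule preset "whole" | (160, 1500, 7.5, 3, 2.5) | for tiled whole samples and tumor subregions |
| double-stain fraction | 0.20 | minimal hull coverage by the other channel's hulls (inclusive) |
| match proximity | 7 px (≈3 μm) | Chebyshev distance for tag-to-hull attribution |

s_min sits above the ~100 px mean area of erythrocytes so their
autofluorescence cannot be counted.  The ROF internals are not
determined by the data model; λ was calibrated once on synthetic
fixtures so that isolated single-pixel speckles of amplitude ≤ 20 are
flattened to zero after quantization, and is exposed in the API
together with the iteration budget and tolerance.

## Numerical conventions

- *Rounding.*  The RGB modulus, the cartoon quantization, the initial
  threshold (mean of the cartoon, over the full frame) and reported
  μm²/mm² values all round half-up; `ceil` is available for the
  initial threshold as an alternative.
- *Connectivity.*  Features are 8-connected on the thresholded
  cartoon (4-connectivity is a parameter).
- *Convex hull.*  c(F) is the pixel count of the filled convex hull on
  the pixel grid (scikit-image's rasterization), so c(F) and the
  I_conv area agree exactly and c ≥ s always.
- *Axis ratio.*  r(F) comes from the normalized second central moments
  of the pixel set with the +1/12 pixel-extent correction added to
  both diagonal terms — the region-properties convention of the
  toolbox the original procedure family is built on.  It keeps r
  finite for 1-px-wide features (a 1×10 bar measures exactly r = 10).
  A minimum-area enclosing ellipse would be a defensible alternative;
  the moments convention was chosen for determinism and familiarity.
- *Perimeter.*  p₁ counts unit edges between feature and background
  pixels.  Under this convention a digital disk measures
  p₁/p₂ ≈ 4/π ≈ 1.27 rather than 1; the rule thresholds p_max = 2 and
  2.5 leave ample headroom, and synthetic rule-conforming blobs
  measure p₁/p₂ ≈ 1.3–2.0.
- *Degenerate inputs.*  Weight-0 ROF returns the input; empty DAPI
  cartoons give an empty evaluation region (count 0); zero
  denominators in the normalizations are reported as missing values,
  never as silent zeros; features still above s_max at intensity 255
  are discarded uncounted.
- *Ties.*  All rule inequalities and the 20 % double-stain coverage
  are inclusive.

## Synthetic data: what it emulates and what it does not

The generator plants irregular macrophage-like blobs (dilated
random-walk polylines; target areas 240–1050 px bracketing the
~150 μm² ≈ 740 px mean macrophage size), round erythrocyte-like disks
of ~100 px in both stain channels, hyperfluorescent gently curved
bars with axis ratio > 3 (fold/vessel artifacts), a DAPI nuclei field
(disks under each cell, scattered between cells, and along artifact
paths — folds lie in nucleated tissue), defocus blur (Gaussian,
σ = 0.8 px) and smooth background autofluorescence of amplitude ≤ 5.
Defaults describe one ROI-sized field (900×600 px) with 25
macrophages, 50 erythrocytes, 3 artifacts and a 55 % double-stain
rate, matching the conditions the method is designed for.

In the *easy regime*, every planted blob individually passes all
whole-preset rules on its noiseless mask, and — because blur and ROF
smoothing feather outlines by a pixel or two, filling concavities —
also after a 2-px dilation with a 30 % solidity margin; blobs are
placed without overlap (12 px safety margin).  A `stratified`
placement mode jitters cells on a grid for spatially homogeneous
fixtures; the tiling experiments use 144 cells on a 12×12 grid over
1600×1600 px so that each 400 px tile receives 9 grid boxes exactly.

Passing tests on these fixtures therefore demonstrate the loop's
bookkeeping, rule arithmetic, colocalization and normalization logic
under realistic intensity variation and distractors — they do not
demonstrate performance on real tissue, where touching cells lump,
nonuniform staining splits cells, features cross tile borders, and
staining artifacts are larger and messier than the generator's.
Tile-border splitting is inherent to independent per-tile processing
and is a documented limitation of the tiled mode.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use one ROI-sized field per
seed (10 seeds for recovery), 30–100 random 128×128 cartoons for the
loop-equivalence check, a 16-tile 1600×1600 px fixture for
subsampling, and a 1300×1300 px field with 200 cells for double-stain
recovery — sizes chosen so a full run completes in a few minutes on a
single core while keeping the statistics meaningful (binomial 95 %
band at n = 200; ≥ 95 % recall/precision over 250 planted cells).

## Known limitations

- Deferred features whose descriptors never fall below s_max are
  silently discarded; aggregates of tightly packed cells can thus be
  missed entirely (the whole-sample preset's larger s_max mitigates
  this).
- The evaluation region is derived from DAPI alone; anucleate tissue
  (e.g. fibrin) is never evaluated.
- The tag-matching proximity rule (Chebyshev ≤ 7 px) is a
  deterministic proxy for by-eye attribution of partly covered cells;
  several tags may match one hull, mirroring cell lumping.  One-to-one
  matching is available as an option.
- The gene-expression normalization adds the pseudo count before the
  housekeeper geometric mean (numerator and divisor alike).
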