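"""Floating-threshold segmentation with rule-based feature classification.

The cartoon is thresholded at every integer intensity i from its
rounded mean up to 255.  At each threshold the surviving pixels are
labelled into connected features and each feature is classified:

  Rule 1  — s > s_max: defer; the too-large feature stays in the
            working image and is re-examined at the next threshold,
            where it may break into smaller parts;
  Rule 2  — s < s_min: reject as too small and mask it;
  Rule 3  — s_min <= s <= s_max: accept iff all of
            3a) c/s >= 1 + c_min/100   (not too round/convex),
            3b) r <= r_max             (not too elongated),
            3c) p1/p2 <= p_max         (boundary regular enough);
            accepted features are written to I_segm/I_conv and masked,
            failures are masked.

Masking sets a pixel's working-cartoon value to 0 so it fails every
later threshold; accepted features are therefore mutually disjoint and
counted exactly once.  Features still above s_max when the maximal
intensity is passed are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import IntensityImage, _round_half_up
from .preprocess import Cartoon, make_cartoon
from .evaluation_region import (EvaluationRegion, eval_mask_from_dapi,
                                full_eval_region)
from . import geometry
from .geometry import Feature, label_features, shape_descriptors

MAX_INTENSITY = 255

DECISION_DEFER = "defer"
DECISION_REJECT_SMALL = "reject_small"
DECISION_REJECT_ROUND = "reject_round"
DECISION_REJECT_ELONGATED = "reject_elongated"
DECISION_REJECT_IRREGULAR = "reject_irregular"
DECISION_ACCEPT = "accept"


@dataclass
class RuleParams:
    """Geometric rule parameters, in px and dimensionless ratios.

    ``c_min`` is the minimal area excess of the convex hull in percent;
    the ROI preset is (140, 800, 7.5, 3, 2), the whole-sample preset
    (160, 1500, 7.5, 3, 2.5).  s_min = 160 px sits above the ~100 px
    mean area of erythrocytes so their autofluorescence is not counted.
    """

    s_min: int = 160
    s_max: int = 1500
    c_min: float = 7.5
    r_max: float = 3.0
    p_max: float = 2.5

    def __post_init__(self):
        if not (0 < self.s_min <= self.s_max):
            raise ValueError("require 0 < s_min <= s_max")
        if self.c_min < 0 or self.r_max < 1 or self.p_max < 1:
            raise ValueError("require c_min >= 0, r_max >= 1, p_max >= 1")


PRESETS = {
    "roi": RuleParams(140, 800, 7.5, 3.0, 2.0),
    "whole": RuleParams(160, 1500, 7.5, 3.0, 2.5),
}


@dataclass
class SegmentationResult:
    features: list
    i_eval: np.ndarray
    i_segm: np.ndarray
    i_conv: np.ndarray
    count: int
    hull_area_px: int
    eval_area_px: int
    nuclei_estimate: float
    initial_threshold: int
    params: RuleParams
    pixel_size_um: float = 0.45
    audit_log: list = field(default_factory=list)  # (i, N(i), {decision: n})


def classify_feature(f: Feature, params: RuleParams) -> str:
    """Apply Rules 1, 2 and 3a-3c to a measured feature.

    Rule 3 requires all three criteria; on failure the first failing
    criterion (in order 3a, 3b, 3c) is reported.
    """
    if f.s > params.s_max:
        return DECISION_DEFER
    if f.s < params.s_min:
        return DECISION_REJECT_SMALL
    if not (f.c / f.s >= 1.0 + params.c_min / 100.0):
        return DECISION_REJECT_ROUND
    if not (f.r <= params.r_max):
        return DECISION_REJECT_ELONGATED
    if not (f.p1 / f.p2 <= params.p_max):
        return DECISION_REJECT_IRREGULAR
    return DECISION_ACCEPT


def initial_threshold(cartoon: Cartoon, mode: str = "half_up") -> int:
    """Starting threshold: the cartoon's mean intensity rounded to integer."""
    mean = float(np.asarray(cartoon.pixels, dtype=np.float64).mean())
    if mode == "ceil":
        return int(np.ceil(mean))
    return int(_round_half_up(mean))


def floating_threshold_segment(cartoon: Cartoon, region: EvaluationRegion,
                               params: RuleParams,
                               connectivity: int = 8) -> SegmentationResult:
    """Run the incremented-threshold loop over the cartoon.

    The working image starts as the cartoon with everything outside the
    evaluation region masked; each threshold pass labels the remaining
    pixels, classifies every feature and masks all but the deferred
    ones.  Deferred (too large) features persist unchanged into the
    next pass.
    """
    if cartoon.shape != region.mask.shape:
        raise ValueError("cartoon and evaluation region differ in shape")
    work = cartoon.pixels.astype(np.int16)
    work[~region.mask] = 0
    i0 = initial_threshold(cartoon)

    shape = cartoon.shape
    i_segm = np.zeros(shape, bool)
    i_conv = np.zeros(shape, bool)
    accepted = []
    audit = []

    for i in range(i0, MAX_INTENSITY + 1):
        if i > 0 and not (work >= i).any():
            # nothing left above any later threshold; remaining passes
            # are no-ops, so the loop may end early without effect
            break
        feats = label_features(work >= i, connectivity)
        decisions = {}
        for f in feats:
            f.s = int(f.rows.size)
            if f.s > params.s_max:
                decisions[DECISION_DEFER] = decisions.get(DECISION_DEFER, 0) + 1
                continue
            if f.s < params.s_min:
                dec = DECISION_REJECT_SMALL
            else:
                shape_descriptors(f)
                dec = classify_feature(f, params)
            decisions[dec] = decisions.get(dec, 0) + 1
            work[f.rows, f.cols] = 0      # masked: rejected or accepted
            if dec == DECISION_ACCEPT:
                f.threshold = i
                accepted.append(f)
                geometry.paint_feature(f, i_segm)
                geometry.paint_hull(f, i_conv)
        audit.append((i, len(feats), decisions))

    return SegmentationResult(
        features=accepted, i_eval=region.mask, i_segm=i_segm, i_conv=i_conv,
        count=len(accepted), hull_area_px=int(i_conv.sum()),
        eval_area_px=region.area_px, nuclei_estimate=region.nuclei_estimate,
        initial_threshold=i0, params=params,
        pixel_size_um=cartoon.pixel_size_um, audit_log=audit)


def segment_sample(channel_img: IntensityImage, dapi_img=None,
                   params: RuleParams = None, connectivity: int = 8,
                   median_window_px: int = None, rof_weight: float = None,
                   rof_n_iter: int = None, rof_tol: float = None):
    """Full single-image pipeline: cartoon, evaluation region, loop.

    With a DAPI image the evaluation region and nuclei estimate are
    derived from its cartoon; without one (ROI mode) the whole image is
    evaluated.
    """
    from . import preprocess as pp

    params = params or PRESETS["whole"]
    kw = {}
    if median_window_px is not None:
        kw["window_px"] = median_window_px
    if rof_weight is not None:
        kw["weight"] = rof_weight
    if rof_n_iter is not None:
        kw["n_iter"] = rof_n_iter
    if rof_tol is not None:
        kw["tol"] = rof_tol

    cartoon = make_cartoon(channel_img, **kw)
    if dapi_img is not None:
        if dapi_img.shape != channel_img.shape:
            raise ValueError("channel and DAPI images differ in shape")
        dapi_cartoon = make_cartoon(dapi_img, **kw)
        region = eval_mask_from_dapi(dapi_cartoon)
    else:
        region = full_eval_region(channel_img.shape, channel_img.pixel_size_um)
    return floating_threshold_segment(cartoon, region, params, connectivity)


@dataclass
class AggregateResult:
    """Sum of per-tile segmentation outputs for a tiled sample."""

    count: int
    hull_area_px: int
    eval_area_px: int
    nuclei_estimate: float
    tile_results: list


def segment_tiles(tiles, dapi_tiles=None, params: RuleParams = None,
                  **kwargs) -> AggregateResult:
    """Segment each tile independently and aggregate by summation.

    Features crossing tile borders may be split or dropped at the
    border; this matches the tiled whole-slide processing convention.
    """
    results = []
    for k, tile in enumerate(tiles):
        dapi = dapi_tiles[k] if dapi_tiles is not None else None
        results.append(segment_sample(tile, dapi, params, **kwargs))
    return AggregateResult(
        count=sum(r.count for r in results),
        hull_area_px=sum(r.hull_area_px for r in results),
        eval_area_px=sum(r.eval_area_px for r in results),
        nuclei_estimate=sum(r.nuclei_estimate for r in results),
        tile_results=results)
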