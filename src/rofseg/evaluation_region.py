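"""Tissue evaluation mask and nuclei estimate from the DAPI channel.

The evaluation subregion is the part of the image where tissue is
present.  It is derived from the cartoon of the DAPI (nuclear stain)
channel: every pixel of intensity >= 10 on the 8-bit scale seeds a
31x31 px white square centred on it, and the mask is the union of those
squares (clipped at the image border).  A fixed threshold works here
because the DAPI image is far more regular than the antibody channels.

The number of cell nuclei is estimated from the same cartoon by
counting the pixels of intensity >= 10 and dividing by 100 (the
nominal nucleus area in px at 0.45 um/px).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_INTENSITY_MIN = 10
DEFAULT_SQUARE_PX = 31
DEFAULT_PX_PER_NUCLEUS = 100.0


@dataclass
class EvaluationRegion:
    mask: np.ndarray            # boolean I_eval
    area_px: int
    area_mm2: float
    nuclei_estimate: float

    @classmethod
    def from_mask(cls, mask, pixel_size_um: float, nuclei_estimate: float = 0.0):
        mask = np.asarray(mask, bool)
        area_px = int(mask.sum())
        return cls(mask, area_px, px_area_mm2(area_px, pixel_size_um),
                   nuclei_estimate)


def px_area_mm2(area_px: float, pixel_size_um: float) -> float:
    return area_px * pixel_size_um ** 2 / 1e6


def eval_mask_from_dapi(dapi_cartoon, intensity_min: int = DEFAULT_INTENSITY_MIN,
                        square_px: int = DEFAULT_SQUARE_PX,
                        px_per_nucleus: float = DEFAULT_PX_PER_NUCLEUS) -> EvaluationRegion:
    """Build I_eval as the union of squares centred on bright DAPI pixels.

    Pixels with intensity below *intensity_min* are masked; every
    remaining pixel contributes a centred ``square_px`` x ``square_px``
    white square, clipped (not shifted) at the borders.  Implemented as
    binary dilation with a square structuring element, which is exactly
    that union.
    """
    if square_px % 2 == 0:
        raise ValueError("square_px must be odd")
    px = np.asarray(dapi_cartoon.pixels)
    bright = px >= intensity_min
    if bright.any():
        mask = ndimage.binary_dilation(
            bright, structure=np.ones((square_px, square_px), bool))
    else:
        mask = np.zeros_like(bright)
    return EvaluationRegion.from_mask(
        mask, dapi_cartoon.pixel_size_um,
        estimate_nuclei(dapi_cartoon, intensity_min, px_per_nucleus))


def full_eval_region(shape, pixel_size_um: float,
                     nuclei_estimate: float = 0.0) -> EvaluationRegion:
    """Whole-image evaluation region, used in ROI mode (no DAPI image)."""
    return EvaluationRegion.from_mask(np.ones(shape, bool), pixel_size_um,
                                      nuclei_estimate)


def estimate_nuclei(dapi_cartoon, intensity_min: int = DEFAULT_INTENSITY_MIN,
                    px_per_nucleus: float = DEFAULT_PX_PER_NUCLEUS) -> float:
    """Estimate the nucleus count: bright-pixel count / px_per_nucleus."""
    if px_per_nucleus <= 0:
        raise ValueError("px_per_nucleus must be positive")
    n_bright = int((np.asarray(dapi_cartoon.pixels) >= intensity_min).sum())
    return n_bright / px_per_nucleus
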