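"""Connected components and the five shape descriptors driving the rules.

Each candidate feature F (a connected set of above-threshold pixels) is
described by:

  s  — feature size, the pixel count;
  c  — convex-hull size, the pixel count of the filled convex hull
       (so the I_conv area and c agree exactly);
  r  — ratio of the principal axis lengths of the covering ellipse,
       taken from the normalized second central moments of the pixel
       set with the +1/12 pixel-extent correction on both axes (the
       standard region-properties convention; r >= 1 always);
  p1 — feature perimeter, counted as unit edges between feature pixels
       and background;
  p2 — perimeter of the circle with the feature's area, 2*sqrt(pi*s).

Macrophages are irregular: the solidity-type rule c/s >= 1 + c_min/100
demands non-convexity, r <= r_max excludes elongated fold/vessel
artifacts, and p1/p2 <= p_max bounds boundary raggedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

_STRUCT_8 = np.ones((3, 3), bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class Feature:
    """One connected pixel set with its shape descriptors."""

    rows: np.ndarray                    # global row coordinates
    cols: np.ndarray                    # global column coordinates
    bbox: tuple = None                  # (r0, c0, r1, c1), exclusive ends
    s: int = 0
    c: float = 0.0
    r: float = 1.0
    p1: float = 0.0
    p2: float = 0.0
    hull_local: Optional[np.ndarray] = None   # filled hull over the bbox
    double_stained: Optional[bool] = None
    threshold: Optional[int] = None     # loop threshold at acceptance

    def local_mask(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        m = np.zeros((r1 - r0, c1 - c0), bool)
        m[self.rows - r0, self.cols - c0] = True
        return m


def label_features(mask, connectivity: int = 8):
    """Partition the true pixels of a binary mask into connected features.

    Descriptors are left unfilled; call :func:`shape_descriptors`.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    lab, n = ndimage.label(np.asarray(mask, bool), structure=structure)
    feats = []
    for sl, k in zip(ndimage.find_objects(lab), range(1, n + 1)):
        rr, cc = np.nonzero(lab[sl] == k)
        r0, c0 = sl[0].start, sl[1].start
        feats.append(Feature(rows=rr + r0, cols=cc + c0,
                             bbox=(r0, c0, sl[0].stop, sl[1].stop)))
    return feats


def shape_descriptors(f: Feature) -> Feature:
    """Fill s, c, r, p1, p2 and the hull mask of a feature in place."""
    if f.rows.size == 0:
        raise ValueError("feature has no pixels")
    f.s = int(f.rows.size)
    m = f.local_mask()

    # perimeter: unit edges between feature pixels and background/outside
    h_adj = int(np.count_nonzero(m[:, 1:] & m[:, :-1]))
    v_adj = int(np.count_nonzero(m[1:, :] & m[:-1, :]))
    f.p1 = float(4 * f.s - 2 * (h_adj + v_adj))
    f.p2 = 2.0 * np.sqrt(np.pi * f.s)

    # convex hull on the pixel grid; c is its filled pixel count
    if f.s == 1:
        f.hull_local = m.copy()
    else:
        f.hull_local = convex_hull_image(m)
    f.c = float(np.count_nonzero(f.hull_local))

    # covering-ellipse axis ratio from normalized second central moments
    f.r = _axis_ratio(f.rows, f.cols)
    return f


def _axis_ratio(rows, cols) -> float:
    """Major/minor axis-length ratio of the moments ellipse.

    Normalized second central moments with the +1/12 per-axis
    pixel-extent correction; axis lengths are 4*sqrt(eigenvalue), so
    the ratio is sqrt(lambda_max / lambda_min).  The correction keeps
    the minor eigenvalue positive even for 1-px-wide features.
    """
    y = rows - rows.mean()
    x = cols - cols.mean()
    n = rows.size
    uyy = float(y @ y) / n + 1.0 / 12.0
    uxx = float(x @ x) / n + 1.0 / 12.0
    uxy = float(x @ y) / n
    common = np.sqrt((uxx - uyy) ** 2 + 4.0 * uxy ** 2)
    lam_max = (uxx + uyy + common) / 2.0
    lam_min = (uxx + uyy - common) / 2.0
    return float(np.sqrt(lam_max / lam_min))


def hull_mask(f: Feature, shape) -> np.ndarray:
    """Embed the feature's filled convex hull into a full-size mask."""
    if f.hull_local is None:
        raise ValueError("descriptors not filled; call shape_descriptors first")
    out = np.zeros(shape, bool)
    r0, c0, r1, c1 = f.bbox
    out[r0:r1, c0:c1] = f.hull_local
    return out


def paint_feature(f: Feature, canvas: np.ndarray) -> None:
    """Set the feature's pixels to True on a boolean canvas."""
    canvas[f.rows, f.cols] = True


def paint_hull(f: Feature, canvas: np.ndarray) -> None:
    """OR the feature's filled hull onto a boolean canvas."""
    r0, c0, r1, c1 = f.bbox
    canvas[r0:r1, c0:c1] |= f.hull_local
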