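"""Seeded generator of synthetic fluorescence image triples with ground truth.

Emulates the difficulties of macrophage counting in immunofluorescence
scans: irregular, variably stained macrophage-like blobs; round
autofluorescent erythrocyte-like distractors of ~100 px area (~6 um
diameter at 0.45 um/px); bright elongated fold/vessel-like artifacts;
defocus blur; a DAPI nuclei field; and low-amplitude background
autofluorescence.  Every placed cell is recorded with its center, area
and double-stain label, and a manual-count-style tag mask (3x3 px
crosses at cell centers) is produced.

Macrophage blobs are built by dilating a short random-walk polyline
with disks of varying radius, which gives direct control over area and
irregularity.  In the easy regime each planted blob, measured on its
noiseless mask, satisfies all acceptance rules of the whole-sample
parameter preset by construction (resampled until it does).

Everything is driven by one numpy Generator seeded from the config, so
identical configs give byte-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_io import IntensityImage, write_mask
from .geometry import Feature, shape_descriptors
from .segmentation import RuleParams, PRESETS, classify_feature, DECISION_ACCEPT

_PLACEMENT_MARGIN_PX = 12
_MAX_BLOB_TRIES = 200
_MAX_PLACE_TRIES = 400

#: correlation length of the background autofluorescence texture, px
_BG_SMOOTH_SIGMA = 3.0


@dataclass
class SynthConfig:
    """Generator settings; defaults describe the study conditions.

    The image is one ROI-sized field (900x600 px); blob target areas
    span 1.5*s_min .. 0.7*s_max of the whole-sample preset, bracketing
    the ~740 px (150 um^2) mean macrophage area; the double-stain rate
    defaults to the observed mean of ~55 %; erythrocyte distractors
    have ~100 px mean area.
    """

    image_size: tuple = (600, 900)           # (H, W)
    n_macrophages: int = 25
    size_range_px: tuple = (240, 1050)
    intensity_range: tuple = (60, 200)
    staining_nonuniformity: float = 0.2      # 0 = uniform interior
    double_stain_rate: float = 0.55
    n_erythrocytes: int = 50
    n_elongated_artifacts: int = 3
    blur_sigma: float = 0.8
    background_level: int = 4                # peak amplitude, <= 5
    seed: int = 0
    rule_preset: str = "whole"               # easy-regime conformance target
    placement: str = "uniform"               # or "stratified" (jittered grid)

    def __post_init__(self):
        if not (0 <= self.double_stain_rate <= 1):
            raise ValueError("double_stain_rate must be in [0, 1]")
        if not (0 <= self.staining_nonuniformity <= 1):
            raise ValueError("staining_nonuniformity must be in [0, 1]")
        if self.size_range_px[0] > self.size_range_px[1]:
            raise ValueError("invalid size_range_px")


@dataclass
class CellRecord:
    center: tuple                # (row, col)
    area_px: int
    double_stained: bool
    channels: tuple              # subset of ("A", "B")
    kind: str = "macrophage"     # or "erythrocyte", "artifact"


@dataclass
class GroundTruth:
    tag_mask: np.ndarray
    cell_records: list = field(default_factory=list)
    mac_mask_A: Optional[np.ndarray] = None      # planted macrophage pixels, channel A
    mac_mask_B: Optional[np.ndarray] = None
    distractor_mask: Optional[np.ndarray] = None  # erythrocyte pixels
    artifact_mask: Optional[np.ndarray] = None    # elongated-artifact pixels

    @property
    def n_cells(self):
        return len(self.cell_records)


@dataclass
class SynthSample:
    img_A: IntensityImage
    img_B: IntensityImage
    img_dapi: IntensityImage
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# blob construction

def _stamp_disks(points, radii, pad=4):
    """Rasterize a union of disks; returns (mask, origin_offset)."""
    pts = np.asarray(points, float)
    rad = np.asarray(radii, float)
    r0 = int(np.floor((pts[:, 0] - rad).min())) - pad
    c0 = int(np.floor((pts[:, 1] - rad).min())) - pad
    r1 = int(np.ceil((pts[:, 0] + rad).max())) + pad
    c1 = int(np.ceil((pts[:, 1] + rad).max())) + pad
    h, w = r1 - r0 + 1, c1 - c0 + 1
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), bool)
    for (py, px), r in zip(pts, rad):
        mask |= (yy - (py - r0)) ** 2 + (xx - (px - c0)) ** 2 <= r ** 2
    return mask, (r0, c0)


def _walk_disks(rng, area):
    """Disk centers/radii along a random-walk polyline sized for *area*."""
    n_nodes = int(rng.integers(4, 8))
    r_arm = float(np.sqrt(area / (np.pi * n_nodes)))
    r_arm = min(max(r_arm, 4.0), 9.0)   # keep arms thin vs the median window
    pos = np.zeros(2)
    nodes = [pos.copy()]
    for _ in range(n_nodes - 1):
        ang = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(1.6, 2.6) * r_arm
        pos = pos + step * np.array([np.sin(ang), np.cos(ang)])
        nodes.append(pos.copy())
    nodes = np.asarray(nodes)
    node_r = r_arm * rng.uniform(0.75, 1.25, size=n_nodes)
    # interpolate disks along the polyline so arms are solid
    pts, rad = [], []
    for k in range(n_nodes - 1):
        seg = np.linalg.norm(nodes[k + 1] - nodes[k])
        n_sub = max(2, int(np.ceil(seg)))
        for t in np.linspace(0, 1, n_sub, endpoint=False):
            pts.append(nodes[k] * (1 - t) + nodes[k + 1] * t)
            rad.append(node_r[k] * (1 - t) + node_r[k + 1] * t)
    pts.append(nodes[-1])
    rad.append(node_r[-1])
    return np.asarray(pts), np.asarray(rad)


def _measure(mask) -> Feature:
    rr, cc = np.nonzero(mask)
    f = Feature(rows=rr, cols=cc,
                bbox=(0, 0, mask.shape[0], mask.shape[1]))
    return shape_descriptors(f)


def synth_macrophage(rng, cfg: SynthConfig):
    """Draw one rule-conforming irregular blob.

    Returns ``(mask, intensity, offset_center)``: a local boolean mask,
    a float intensity profile over it, and the blob's centroid in local
    coordinates.  The blob's area is within +-10 % of the sampled
    target, and its noiseless mask passes all acceptance rules of the
    configured preset (resampled until both hold).
    """
    params = PRESETS[cfg.rule_preset]
    lo, hi = cfg.size_range_px
    for _ in range(_MAX_BLOB_TRIES):
        target = float(rng.uniform(lo, hi))
        pts, rad = _walk_disks(rng, target)
        mask, _ = _stamp_disks(pts, rad)
        # one multiplicative correction toward the target area
        got = mask.sum()
        if got == 0:
            continue
        scale = np.sqrt(target / got)
        if abs(scale - 1) > 0.02:
            mask, _ = _stamp_disks(pts, rad * scale)
        got = mask.sum()
        if not (0.9 * target <= got <= 1.1 * target):
            continue
        f = _measure(mask)
        if classify_feature(f, params) != DECISION_ACCEPT:
            continue
        # defocus blur and ROF smoothing feather the outline by a pixel
        # or two, which fills concavities; an easy-regime blob must stay
        # distinctly non-convex under that, so require the 2-px-dilated
        # mask to pass the rules with a solidity margin as well
        dil = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool),
                                      iterations=2)
        fd = _measure(np.pad(dil, 2))
        if classify_feature(fd, params) != DECISION_ACCEPT:
            continue
        if fd.c / fd.s < 1.0 + 1.3 * params.c_min / 100.0:
            continue
        intensity = _intensity_profile(rng, mask, cfg)
        cy, cx = ndimage.center_of_mass(mask)
        return mask, intensity, (cy, cx)
    raise RuntimeError("could not draw a rule-conforming blob; "
                       "check size_range_px against the rule preset")


def _intensity_profile(rng, mask, cfg: SynthConfig):
    base = rng.uniform(*cfg.intensity_range)
    prof = np.full(mask.shape, base, float)
    if cfg.staining_nonuniformity > 0:
        noise = rng.standard_normal(mask.shape)
        noise = ndimage.gaussian_filter(noise, 3.0)
        rng_span = noise.max() - noise.min()
        if rng_span > 0:
            noise = (noise - noise.min()) / rng_span     # [0, 1]
            prof *= 1.0 - cfg.staining_nonuniformity * noise
    return prof * mask


def _disk_mask(radius):
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return yy ** 2 + xx ** 2 <= radius ** 2


def _arc_mask(rng, length, width):
    """A gently curved bright bar (fold/vessel-like), r >> r_max."""
    t = np.linspace(0, 1, int(length) * 2)
    bend = rng.uniform(0.08, 0.18) * length * np.sign(rng.standard_normal())
    ang = rng.uniform(0, np.pi)
    # arc in local coords, then rotate
    x = (t - 0.5) * length
    y = bend * (4 * t * (1 - t) - 0.5)
    xr = x * np.cos(ang) - y * np.sin(ang)
    yr = x * np.sin(ang) + y * np.cos(ang)
    pts = np.stack([yr, xr], axis=1)
    rad = np.full(len(t), width / 2.0)
    mask, _ = _stamp_disks(pts, rad)
    return mask


# ---------------------------------------------------------------------------
# sample assembly

class _Placer:
    """Non-overlapping stamp placement with a safety margin."""

    def __init__(self, shape, rng, margin=_PLACEMENT_MARGIN_PX):
        self.shape = shape
        self.rng = rng
        self.margin = margin
        self.occupied = np.zeros(shape, bool)

    def place(self, mask, region=None):
        """Find a top-left offset where *mask* fits; reserve it + margin.

        With *region* = (rlo, rhi, clo, chi) the top-left corner is
        sampled inside that window first (stratified placement); after
        half the tries the whole image is used as fallback.
        """
        h, w = mask.shape
        H, W = self.shape
        if h >= H or w >= W:
            raise RuntimeError("stamp larger than image")
        m = self.margin
        # pad before dilating so the safety margin is not clipped away
        grown = ndimage.binary_dilation(
            np.pad(mask, m), structure=np.ones((3, 3), bool), iterations=m)
        for attempt in range(_MAX_PLACE_TRIES):
            if region is not None and attempt < _MAX_PLACE_TRIES // 2:
                rlo, rhi, clo, chi = region
                rhi = min(rhi, H - h)
                chi = min(chi, W - w)
                rlo = min(rlo, max(0, rhi - 1))
                clo = min(clo, max(0, chi - 1))
                r0 = int(self.rng.integers(rlo, max(rhi, rlo + 1)))
                c0 = int(self.rng.integers(clo, max(chi, clo + 1)))
            else:
                r0 = int(self.rng.integers(0, H - h))
                c0 = int(self.rng.integers(0, W - w))
            if not (self.occupied[r0:r0 + h, c0:c0 + w] & mask).any():
                gr, gc = r0 - m, c0 - m
                gh, gw = grown.shape
                sr, sc = max(0, -gr), max(0, -gc)
                er = min(gh, H - gr)
                ec = min(gw, W - gc)
                self.occupied[gr + sr:gr + er, gc + sc:gc + ec] |= \
                    grown[sr:er, sc:ec]
                return r0, c0
        raise RuntimeError("infeasible packing: could not place all objects")


def _blend_max(canvas, stamp, r0, c0):
    h, w = stamp.shape
    region = canvas[r0:r0 + h, c0:c0 + w]
    np.maximum(region, stamp, out=region)


def _cross_coords(center, shape):
    """Pixels of a 3x3 cross (5-px plus sign) clipped to the image."""
    r, c = center
    pts = [(r, c), (r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
    return [(y, x) for y, x in pts
            if 0 <= y < shape[0] and 0 <= x < shape[1]]


def synth_sample(cfg: SynthConfig) -> SynthSample:
    """Generate the (stain A, stain B, DAPI) triple with ground truth.

    All macrophages appear in channel A; a ``double_stain_rate``
    fraction is co-located in channel B as well.  Erythrocyte-like
    disks (~100 px) and elongated artifacts appear in both stain
    channels; nuclei appear in DAPI under every macrophage and
    scattered between cells.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_size
    chan_a = np.zeros((H, W), float)
    chan_b = np.zeros((H, W), float)
    dapi = np.zeros((H, W), float)
    placer = _Placer((H, W), rng)
    records = []
    tag_mask = np.zeros((H, W), bool)
    mac_a = np.zeros((H, W), bool)
    mac_b = np.zeros((H, W), bool)
    distract = np.zeros((H, W), bool)
    artifact = np.zeros((H, W), bool)

    regions = [None] * cfg.n_macrophages
    if cfg.placement == "stratified" and cfg.n_macrophages > 0:
        # jittered-grid placement: one cell per grid box, for spatially
        # homogeneous fixtures (tumor-subregion tiling experiments)
        gy = max(1, int(round(np.sqrt(cfg.n_macrophages * H / W))))
        gx = max(1, int(np.ceil(cfg.n_macrophages / gy)))
        boxes = [(int(i * H / gy), int((i + 1) * H / gy),
                  int(j * W / gx), int((j + 1) * W / gx))
                 for i in range(gy) for j in range(gx)]
        order = rng.permutation(len(boxes))[:cfg.n_macrophages]
        regions = [boxes[k] for k in order]
    elif cfg.placement != "uniform":
        raise ValueError("placement must be 'uniform' or 'stratified'")

    for region in regions:
        mask, prof, (cy, cx) = synth_macrophage(rng, cfg)
        r0, c0 = placer.place(mask, region=region)
        double = bool(rng.random() < cfg.double_stain_rate)
        _blend_max(chan_a, prof, r0, c0)
        mac_a[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] |= mask
        if double:
            prof_b = _intensity_profile(rng, mask, cfg)
            _blend_max(chan_b, prof_b, r0, c0)
            mac_b[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] |= mask
        center = (int(round(r0 + cy)), int(round(c0 + cx)))
        for y, x in _cross_coords(center, (H, W)):
            tag_mask[y, x] = True
        records.append(CellRecord(center, int(mask.sum()), double,
                                  ("A", "B") if double else ("A",)))
        # a nucleus near the macrophage center
        nuc = _disk_mask(rng.uniform(4.5, 5.5))
        nr = int(np.clip(center[0] - nuc.shape[0] // 2 + rng.integers(-3, 4),
                         0, H - nuc.shape[0]))
        nc = int(np.clip(center[1] - nuc.shape[1] // 2 + rng.integers(-3, 4),
                         0, W - nuc.shape[1]))
        _blend_max(dapi, nuc * rng.uniform(120, 230), nr, nc)

    for _ in range(cfg.n_erythrocytes):
        disk = _disk_mask(rng.uniform(5.2, 6.0))   # ~100 px area
        level = rng.uniform(*cfg.intensity_range)
        r0, c0 = placer.place(disk)
        _blend_max(chan_a, disk * level, r0, c0)
        _blend_max(chan_b, disk * level * rng.uniform(0.8, 1.0), r0, c0)
        distract[r0:r0 + disk.shape[0], c0:c0 + disk.shape[1]] |= disk
        records.append(CellRecord((r0 + disk.shape[0] // 2,
                                   c0 + disk.shape[1] // 2),
                                  int(disk.sum()), False, ("A", "B"),
                                  kind="erythrocyte"))

    for _ in range(cfg.n_elongated_artifacts):
        arc = _arc_mask(rng, rng.uniform(90, 160), rng.uniform(4, 7))
        if not (PRESETS[cfg.rule_preset].s_min <= arc.sum()):
            continue
        r0, c0 = placer.place(arc)
        level = rng.uniform(230, 255)   # hyperfluorescent
        _blend_max(chan_a, arc * level, r0, c0)
        _blend_max(chan_b, arc * level, r0, c0)
        artifact[r0:r0 + arc.shape[0], c0:c0 + arc.shape[1]] |= arc
        # folds/vessels lie in nucleated tissue: stamp nuclei along the
        # path so the evaluation region covers the artifact contiguously
        ar, ac = np.nonzero(arc)
        seen = set()
        for y, x in zip(ar, ac):
            cell = (y // 16, x // 16)
            if cell in seen:
                continue
            seen.add(cell)
            nuc = _disk_mask(rng.uniform(4.0, 5.5))
            nr = int(np.clip(r0 + y - nuc.shape[0] // 2, 0, H - nuc.shape[0]))
            nc = int(np.clip(c0 + x - nuc.shape[1] // 2, 0, W - nuc.shape[1]))
            _blend_max(dapi, nuc * rng.uniform(100, 230), nr, nc)
        records.append(CellRecord((r0 + arc.shape[0] // 2,
                                   c0 + arc.shape[1] // 2),
                                  int(arc.sum()), False, ("A", "B"),
                                  kind="artifact"))

    # nuclei between cells
    for _ in range(3 * max(cfg.n_macrophages, 1)):
        nuc = _disk_mask(rng.uniform(4.0, 5.5))
        r0 = int(rng.integers(0, H - nuc.shape[0]))
        c0 = int(rng.integers(0, W - nuc.shape[1]))
        _blend_max(dapi, nuc * rng.uniform(100, 230), r0, c0)

    out = []
    for canvas, channel in ((chan_a, "stain_A"), (chan_b, "stain_B"),
                            (dapi, "dapi")):
        if cfg.blur_sigma > 0:
            canvas = ndimage.gaussian_filter(canvas, cfg.blur_sigma)
        if cfg.background_level > 0:
            bg = ndimage.gaussian_filter(rng.standard_normal((H, W)), _BG_SMOOTH_SIGMA)
            span = bg.max() - bg.min()
            if span > 0:
                bg = (bg - bg.min()) / span * cfg.background_level
            canvas = canvas + bg
        out.append(IntensityImage(
            np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8),
            channel=channel))

    truth = GroundTruth(tag_mask=tag_mask, cell_records=records,
                        mac_mask_A=mac_a, mac_mask_B=mac_b,
                        distractor_mask=distract, artifact_mask=artifact)
    return SynthSample(out[0], out[1], out[2], truth, cfg)


def macrophage_records(truth: GroundTruth):
    return [r for r in truth.cell_records if r.kind == "macrophage"]


def write_sample(sample: SynthSample, out_dir, prefix="synth"):
    """Write the image triple, tag mask and ground-truth TSV."""
    import os
    import pandas as pd
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, img in (("A", sample.img_A), ("B", sample.img_B),
                      ("dapi", sample.img_dapi)):
        p = os.path.join(out_dir, f"{prefix}_{name}.png")
        iio.imwrite(p, img.pixels)
        paths[name] = p
    paths["tags"] = os.path.join(out_dir, f"{prefix}_tags.png")
    write_mask(sample.truth.tag_mask, paths["tags"])
    rows = [{"row": r.center[0], "col": r.center[1], "area_px": r.area_px,
             "double_stained": r.double_stained,
             "channels": "".join(r.channels), "kind": r.kind}
            for r in sample.truth.cell_records]
    paths["truth"] = os.path.join(out_dir, f"{prefix}_truth.tsv")
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
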