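"""Raster I/O, greyscale conversion, tiling and the run logfile.

Input images are 8-bit single-channel fluorescence scans (PNG or TIFF),
one per stain channel, all sharing a physical pixel edge length
(0.45 um by default).  Monochrome renderings delivered as RGB are
collapsed to greyscale with the Euclidean modulus of the RGB vector,
which reduces to the active channel's value when only one channel is
non-zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

#: physical pixel edge length of the slide scans, in micrometres
DEFAULT_PIXEL_SIZE_UM = 0.45

#: tile edge used when slicing whole-sample scans, in pixels
DEFAULT_TILE_SIZE_PX = 1000

CHANNELS = ("stain_A", "stain_B", "dapi")


def _round_half_up(x):
    """Round half-up to the nearest integer (np.round rounds half-even)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class IntensityImage:
    """An 8-bit single-channel image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Intensities in [0, 255].
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    channel : str
        One of ``stain_A``, ``stain_B``, ``dapi``.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = "stain_A"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class TileGrid:
    """Row-major, 0-based tiling of a source image.

    Edge tiles are kept at their natural (smaller) size rather than
    padded, so the tiles jointly partition the source pixels exactly.
    """

    tiles: list = field(default_factory=list)
    index: list = field(default_factory=list)  # (row, col) per tile
    tile_size_px: int = DEFAULT_TILE_SIZE_PX
    source_shape: tuple = (0, 0)


def rgb_to_grey(rgb, pixel_size_um=DEFAULT_PIXEL_SIZE_UM, channel="stain_A"):
    """Collapse an RGB rendering to greyscale via the vector modulus.

    Each pixel becomes ``|(R, G, B)|`` (Euclidean norm), rounded half-up
    and clipped to 255.  For the monochrome-rendered scans this equals
    the single active channel's value.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    norm = np.sqrt(np.sum(rgb.astype(np.float64) ** 2, axis=2))
    grey = np.clip(_round_half_up(norm), 0, 255).astype(np.uint8)
    return IntensityImage(grey, pixel_size_um=pixel_size_um, channel=channel)


def tile_image(img: IntensityImage, tile_size_px: int = DEFAULT_TILE_SIZE_PX) -> TileGrid:
    """Slice an image into row-major tiles of ``tile_size_px`` squared.

    Remainder rows/columns produce smaller edge tiles; reassembling the
    tiles reproduces the source bit-exactly (see :func:`untile`).
    """
    if tile_size_px < 1:
        raise ValueError("tile_size_px must be >= 1")
    h, w = img.shape
    grid = TileGrid(tile_size_px=tile_size_px, source_shape=(h, w))
    for ti, r0 in enumerate(range(0, h, tile_size_px)):
        for tj, c0 in enumerate(range(0, w, tile_size_px)):
            block = img.pixels[r0:r0 + tile_size_px, c0:c0 + tile_size_px]
            grid.tiles.append(
                IntensityImage(block.copy(), img.pixel_size_um, img.channel))
            grid.index.append((ti, tj))
    return grid


def untile(grid: TileGrid) -> np.ndarray:
    """Reassemble a TileGrid into the source pixel array."""
    h, w = grid.source_shape
    out = np.zeros((h, w), dtype=np.uint8)
    t = grid.tile_size_px
    for tile, (ti, tj) in zip(grid.tiles, grid.index):
        r0, c0 = ti * t, tj * t
        th, tw = tile.shape
        out[r0:r0 + th, c0:c0 + tw] = tile.pixels
    return out


# ---------------------------------------------------------------------------
# mask and result output


def read_image(path, pixel_size_um=DEFAULT_PIXEL_SIZE_UM, channel="stain_A"):
    """Read a PNG/TIFF image; RGB inputs are collapsed via :func:`rgb_to_grey`."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        return rgb_to_grey(arr[..., :3], pixel_size_um, channel)
    return IntensityImage(np.asarray(arr, dtype=np.uint8), pixel_size_um, channel)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a lossless 8-bit PNG/TIFF (255 = true)."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask`."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def write_outputs(result, out_dir, prefix="rofseg") -> dict:
    """Write the three output masks and the plain-text logfile.

    Writes ``<prefix>_eval.png``, ``<prefix>_segm.png``,
    ``<prefix>_conv.png`` and ``<prefix>_log.txt`` into *out_dir* and
    returns the path mapping.  The logfile is line-oriented
    ``key=value`` text with one ``feature=`` record per accepted
    feature.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "i_eval": os.path.join(out_dir, f"{prefix}_eval.png"),
        "i_segm": os.path.join(out_dir, f"{prefix}_segm.png"),
        "i_conv": os.path.join(out_dir, f"{prefix}_conv.png"),
        "logfile": os.path.join(out_dir, f"{prefix}_log.txt"),
    }
    write_mask(result.i_eval, paths["i_eval"])
    write_mask(result.i_segm, paths["i_segm"])
    write_mask(result.i_conv, paths["i_conv"])
    with open(paths["logfile"], "w", encoding="utf-8") as fh:
        fh.write(format_logfile(result))
    return paths


def format_logfile(result) -> str:
    """Render a SegmentationResult as line-oriented key=value text."""
    lines = [
        f"count={result.count}",
        f"eval_area_px={result.eval_area_px}",
        f"hull_area_px={result.hull_area_px}",
        f"nuclei_estimate={result.nuclei_estimate:.2f}",
        f"initial_threshold={result.initial_threshold}",
        f"s_min={result.params.s_min}",
        f"s_max={result.params.s_max}",
        f"c_min={result.params.c_min}",
        f"r_max={result.params.r_max}",
        f"p_max={result.params.p_max}",
    ]
    for k, f in enumerate(result.features):
        r0, c0, r1, c1 = f.bbox
        lines.append(
            "feature="
            f"{k};s={f.s};c={f.c};r={f.r:.4f};p1={f.p1:.1f};p2={f.p2:.4f};"
            f"bbox={r0},{c0},{r1},{c1};threshold={f.threshold}")
    for i, n, dec in result.audit_log:
        lines.append(f"threshold={i};n_features={n};decisions={dec}")
    return "\n".join(lines) + "\n"
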