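"""Normalizations, subsampling, validation statistics and size distributions.

Counts from different samples are made comparable by three
normalizations: *density* (count per evaluated mm^2), *cell percentage*
(count per estimated nucleus, x100) and *area percentage* (cumulative
hull area per evaluated area, x100).  Validation against manual tags
uses exact matching (a 3x3 px cross attributable to a detected
feature's convex hull) and Pearson correlation across images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .image_io import DEFAULT_PIXEL_SIZE_UM

DEFAULT_PROXIMITY_PX = 7  # ~3 um at 0.45 um/px; proxy for visual inspection


# ---------------------------------------------------------------------------
# unit conversions

def px_to_um2(area_px: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a pixel area to um^2 (0.2025 um^2/px at 0.45 um/px)."""
    if area_px < 0:
        raise ValueError("area must be >= 0")
    return area_px * pixel_size_um ** 2


def px_to_mm2(area_px: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a pixel area to mm^2."""
    return px_to_um2(area_px, pixel_size_um) / 1e6


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up, the convention for reported um^2/mm^2 values."""
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5) / factor


# ---------------------------------------------------------------------------
# per-sample normalizations

@dataclass
class SampleMetrics:
    count: int
    density: Optional[float]            # cells / mm^2
    cell_percentage: Optional[float]    # % of estimated nuclei
    area_percentage: Optional[float]    # % of evaluated area
    eval_area_mm2: float
    nuclei_estimate: float


def sample_metrics(result, pixel_size_um: float = None) -> SampleMetrics:
    """Compute the three normalizations for one segmentation result.

    Zero denominators leave the affected field as ``None`` rather than
    reporting a silent zero.
    """
    psz = pixel_size_um or getattr(result, "pixel_size_um", DEFAULT_PIXEL_SIZE_UM)
    eval_mm2 = px_to_mm2(result.eval_area_px, psz)
    density = result.count / eval_mm2 if eval_mm2 > 0 else None
    cell_pct = (100.0 * result.count / result.nuclei_estimate
                if result.nuclei_estimate > 0 else None)
    area_pct = (100.0 * result.hull_area_px / result.eval_area_px
                if result.eval_area_px > 0 else None)
    return SampleMetrics(result.count, density, cell_pct, area_pct,
                         eval_mm2, result.nuclei_estimate)


def metrics_table(named_results, pixel_size_um: float = None) -> pd.DataFrame:
    """One row per (sample, channel) of SampleMetrics, as a DataFrame."""
    rows = []
    for name, result in named_results:
        m = sample_metrics(result, pixel_size_um)
        rows.append({"sample": name, "count": m.count, "density": m.density,
                     "cell_percentage": m.cell_percentage,
                     "area_percentage": m.area_percentage,
                     "eval_area_mm2": m.eval_area_mm2,
                     "nuclei_estimate": m.nuclei_estimate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tile subsampling

def subsample_tiles(tile_results, rate: float, mode: str = "stride",
                    seed: int = 0):
    """Aggregate metrics over a 100 %, 50 % or 25 % subset of tiles.

    ``stride`` keeps every 2nd (rate 0.5) or 4th (rate 0.25) tile in
    row-major order; ``seeded-random`` draws the same number of tiles
    uniformly without replacement.
    """
    if rate not in (1.0, 0.5, 0.25):
        raise ValueError("rate must be 1.0, 0.5 or 0.25")
    n = len(tile_results)
    step = int(round(1.0 / rate))
    if mode == "stride":
        chosen = list(range(0, n, step))
    elif mode == "seeded-random":
        k = len(range(0, n, step))
        chosen = sorted(np.random.default_rng(seed).choice(n, size=k,
                                                           replace=False))
    else:
        raise ValueError("mode must be 'stride' or 'seeded-random'")
    if not chosen:
        raise ValueError("empty tile selection")
    sel = [tile_results[i] for i in chosen]
    agg = _Agg(count=sum(r.count for r in sel),
               hull_area_px=sum(r.hull_area_px for r in sel),
               eval_area_px=sum(r.eval_area_px for r in sel),
               nuclei_estimate=sum(r.nuclei_estimate for r in sel),
               pixel_size_um=getattr(sel[0], "pixel_size_um",
                                     DEFAULT_PIXEL_SIZE_UM))
    return sample_metrics(agg)


@dataclass
class _Agg:
    count: int
    hull_area_px: int
    eval_area_px: int
    nuclei_estimate: float
    pixel_size_um: float


# ---------------------------------------------------------------------------
# Pearson comparison

def pearson_r(x, y):
    """Sample Pearson correlation with two-sided t-distribution p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# exact-match validation against manual tags

@dataclass
class MatchReport:
    n_tags: int
    n_features: int
    n_matched: int
    pct_of_tags: float       # 100 * matched / tags
    pct_of_features: float   # 100 * matched / features


def tag_centers(tag_mask) -> np.ndarray:
    """Recover cross centers from a binary tag mask.

    Each manual tag is a small (3x3 px) cross; centers are the rounded
    centroids of the connected components.
    """
    tag_mask = np.asarray(tag_mask, bool)
    lab, n = ndimage.label(tag_mask, structure=np.ones((3, 3), bool))
    if n == 0:
        return np.zeros((0, 2), dtype=int)
    cents = ndimage.center_of_mass(tag_mask, lab, range(1, n + 1))
    return np.rint(np.asarray(cents)).astype(int)


def exact_match_validation(tag_mask, result,
                           proximity_px: int = DEFAULT_PROXIMITY_PX,
                           unique: bool = False) -> MatchReport:
    """Match manual tags to detected features' convex hulls.

    A tag matches when its center lies inside some hull, or within
    *proximity_px* (Chebyshev distance, inclusive) of one — a
    deterministic stand-in for the by-eye attribution of partly covered
    cells.  By default several tags may match the same hull (lumped
    cells); with ``unique=True`` each hull absorbs at most one tag
    (greedy, nearest tag first).
    """
    tag_mask = np.asarray(tag_mask, bool)
    if tag_mask.shape != result.i_conv.shape:
        raise ValueError("tag mask and result differ in shape")
    centers = tag_centers(tag_mask)
    conv = result.i_conv
    if conv.any():
        dist, (ir, ic) = ndimage.distance_transform_cdt(
            ~conv, metric="chessboard", return_indices=True)
    else:
        dist = np.full(conv.shape, np.iinfo(np.int32).max)
    if not unique or not conv.any():
        n_matched = int(sum(dist[r, c] <= proximity_px for r, c in centers))
    else:
        hulls, _ = ndimage.label(conv, structure=np.ones((3, 3), bool))
        cand = sorted((int(dist[r, c]), int(hulls[ir[r, c], ic[r, c]]))
                      for r, c in centers if dist[r, c] <= proximity_px)
        used, n_matched = set(), 0
        for _, hull_id in cand:
            if hull_id not in used:
                used.add(hull_id)
                n_matched += 1
    n_tags = len(centers)
    n_features = result.count
    return MatchReport(
        n_tags=n_tags, n_features=n_features, n_matched=n_matched,
        pct_of_tags=100.0 * n_matched / n_tags if n_tags else 0.0,
        pct_of_features=100.0 * n_matched / n_features if n_features else 0.0)


def match_percentages(n_tags: int, n_features: int, n_matched: int) -> dict:
    """Percentage bookkeeping for a pooled match table.

    Returns matched and detected totals relative to the tag count and
    matched relative to the feature count.
    """
    return {
        "pct_matched_of_tags": 100.0 * n_matched / n_tags,
        "pct_features_of_tags": 100.0 * n_features / n_tags,
        "pct_matched_of_features": 100.0 * n_matched / n_features,
    }


# ---------------------------------------------------------------------------
# feature-size distributions

def _nearest_rank_quantile(sorted_vals: np.ndarray, q: float) -> float:
    n = len(sorted_vals)
    rank = max(1, math.ceil(q * n))
    return float(sorted_vals[rank - 1])


def _describe(vals) -> dict:
    vals = np.sort(np.asarray(vals, float))
    if vals.size == 0:
        return {"n": 0, "min": None, "max": None, "mean": None,
                "median": None, "sd": None, "q95": None}
    return {"n": int(vals.size), "min": float(vals[0]), "max": float(vals[-1]),
            "mean": float(vals.mean()), "median": float(np.median(vals)),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "q95": _nearest_rank_quantile(vals, 0.95)}


def size_distribution(results) -> pd.DataFrame:
    """Pooled size statistics per subpopulation {all, single, double}.

    Rows are (subpopulation, measure) with measure in {feature, hull};
    features must carry double-stain flags.  q95 uses the nearest-rank
    convention.
    """
    feats = [f for r in results for f in r.features]
    if not feats:
        raise ValueError("no features pooled")
    rows = []
    subsets = {
        "all": feats,
        "single": [f for f in feats if f.double_stained is False],
        "double": [f for f in feats if f.double_stained is True],
    }
    for sub, fs in subsets.items():
        for measure, vals in (("feature", [f.s for f in fs]),
                              ("hull", [f.c for f in fs])):
            rows.append({"subpopulation": sub, "measure": measure,
                         **_describe(vals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-expression normalization (housekeeper geometric mean)

HOUSEKEEPERS = ("B2M", "MTMR14", "PGK1", "ABCF1", "EIF2B4",
                "LDHA", "CTCF", "TBP", "WDR55", "POLR2B")


def normalize_gene_expression(counts: pd.DataFrame, housekeepers=HOUSEKEEPERS,
                              pseudo: float = 1.0,
                              scale: float = 1000.0) -> pd.DataFrame:
    """Housekeeper-normalize a sample x gene count table.

    Per sample: ``(count + pseudo) / geomean_housekeepers(count + pseudo)
    * scale``.  The pseudo count enters both numerator and divisor.
    """
    missing = [g for g in housekeepers if g not in counts.columns]
    if missing:
        raise ValueError(f"housekeeper genes missing from table: {missing}")
    shifted = counts.astype(float) + pseudo
    geo = np.exp(np.log(shifted[list(housekeepers)]).mean(axis=1))
    return shifted.div(geo, axis=0) * scale
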