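"""Double-stain detection between the two antibody channels.

The channels (e.g. CD14/488 nm and CD163/555 nm) are segmented
independently; a feature from channel A is called double-stained when
at least 20 % of the area of its convex hull is covered by the union
of convex hulls of channel-B features (B's I_conv mask).  The relation
is deliberately not symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Feature

DEFAULT_FRACTION = 0.20


@dataclass
class DoubleStainSummary:
    n_features_A: int
    n_double: int
    percent_double: float  # 100 * n_double / n_features_A


def is_double_stained(f: Feature, conv_mask_B, fraction: float = DEFAULT_FRACTION) -> bool:
    """True iff >= *fraction* of the feature's hull area lies in B's hulls.

    The comparison is inclusive: exactly 20 % coverage counts.
    """
    conv_mask_B = np.asarray(conv_mask_B, bool)
    r0, c0, r1, c1 = f.bbox
    if r1 > conv_mask_B.shape[0] or c1 > conv_mask_B.shape[1]:
        raise ValueError("feature does not fit inside conv_mask_B")
    hull = f.hull_local
    overlap = int(np.count_nonzero(hull & conv_mask_B[r0:r1, c0:c1]))
    return overlap / f.c >= fraction


def double_stain_summary(result_A, result_B,
                         fraction: float = DEFAULT_FRACTION) -> DoubleStainSummary:
    """Flag every channel-A feature against channel B's I_conv.

    Sets ``double_stained`` on each feature of *result_A* and returns
    the counts; the percentage is 0 for an empty channel A.
    """
    if result_A.i_conv.shape != result_B.i_conv.shape:
        raise ValueError("results differ in image shape")
    n_double = 0
    for f in result_A.features:
        f.double_stained = is_double_stained(f, result_B.i_conv, fraction)
        n_double += int(f.double_stained)
    n_a = len(result_A.features)
    pct = 100.0 * n_double / n_a if n_a else 0.0
    return DoubleStainSummary(n_a, n_double, pct)
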