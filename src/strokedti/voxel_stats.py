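"""Voxelwise two-sample t-contrast between co-registered cohorts.

This is the VBM-style comparison: a pooled-variance Student t statistic at
every voxel between two cohorts of scalar maps that share one grid
(realignment/normalization is deliberately a no-op — synthetic subjects are
co-registered by construction), thresholded at an uncorrected height
threshold such as t = 4.025 for one-sided P < 0.001 with df = 11 (groups of
6 and 7).  No multiple-comparison correction is applied by default,
matching the uncorrected convention; a Bonferroni-adjusted threshold can be
reported on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .image_io import ImageGrid, LabelMap, ScalarMap

__all__ = ["TContrastMap", "critical_t", "voxelwise_t", "threshold_contrast"]

DIRECTIONS = ("A_greater", "B_greater", "two_sided")


@dataclass
class TContrastMap:
    """Per-voxel t statistic with its degrees of freedom and contrast
    direction.  Undefined voxels (missing data or zero pooled variance with
    unequal means) are NaN."""

    grid: ImageGrid
    t: np.ndarray
    df: int
    direction: str = "A_greater"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.t.shape != self.grid.shape:
            raise ValueError("t array must match grid shape")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.t)


def critical_t(alpha: float, df: int, sidedness: str = "one") -> float:
    """Upper critical value of Student's t.

    One-sided: the value with upper-tail probability ``alpha``; two-sided:
    upper-tail probability ``alpha / 2``.  With alpha = 0.001 and df = 11
    (cohorts of 6 and 7) the one-sided threshold is 4.025.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    tail = alpha if sidedness == "one" else alpha / 2.0
    return float(sps.t.isf(tail, df))


def voxelwise_t(
    stack_a: "list[ScalarMap]",
    stack_b: "list[ScalarMap]",
    mask: np.ndarray | None = None,
    direction: str = "A_greater",
) -> TContrastMap:
    """Pooled-variance two-sample t at every voxel, df = nA + nB - 2.

    Positive t means group A exceeds group B.  Voxels where any subject is
    undefined are NaN; zero pooled variance gives t = 0 when the group
    means agree and NaN otherwise.
    """
    if len(stack_a) < 2 or len(stack_b) < 2:
        raise ValueError("each cohort needs >= 2 subjects")
    grid = stack_a[0].grid
    for m in list(stack_a) + list(stack_b):
        if m.grid != grid:
            raise ValueError("all maps must share one grid (cohorts are co-registered)")
    a = np.stack([m.values for m in stack_a], axis=0)
    b = np.stack([m.values for m in stack_b], axis=0)
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2

    defined = np.all(np.isfinite(a), axis=0) & np.all(np.isfinite(b), axis=0)
    if mask is not None:
        defined &= np.asarray(mask, dtype=bool)

    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss = (a - mean_a).reshape(na, -1) ** 2
    ss_a = ss.sum(axis=0).reshape(grid.shape)
    ss_b = ((b - mean_b) ** 2).sum(axis=0)
    sp2 = (ss_a + ss_b) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))

    t = np.full(grid.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = mean_a - mean_b
        good = defined & (se > 0)
        t[good] = diff[good] / se[good]
        degen = defined & (se == 0) & (diff == 0)
        t[degen] = 0.0
    return TContrastMap(grid, t, df, direction)


def threshold_contrast(tmap: TContrastMap, alpha: float = 0.001) -> LabelMap:
    """Binary significance mask at an uncorrected height threshold.

    One-sided directions flag t >= critical_t(alpha) (sign-flipped for
    ``B_greater``); ``two_sided`` flags |t| >= critical_t(alpha, two-sided).
    The threshold used is recorded in the legend under key
    ``significant`` -> 1 and in the returned map's ``threshold`` attribute.
    """
    if tmap.direction == "two_sided":
        thr = critical_t(alpha, tmap.df, "two")
        sig = np.abs(tmap.t) >= thr
    else:
        thr = critical_t(alpha, tmap.df, "one")
        t = tmap.t if tmap.direction == "A_greater" else -tmap.t
        sig = t >= thr
    sig = np.where(tmap.defined, sig, False)
    out = LabelMap(tmap.grid, sig.astype(np.int32), {"significant": 1})
    out.threshold = thr  # type: ignore[attr-defined]
    out.alpha = alpha  # type: ignore[attr-defined]
    return out
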