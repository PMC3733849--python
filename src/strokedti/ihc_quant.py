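"""Glial-marker area-fraction quantification on fluorescence fields.

A field is a multichannel 2D fluorescence image (GFAP for activated
astrocytes, Iba1 for activated microglia, DAPI for nuclei) with a known
pixel size.  Each marker channel is binarized — Otsu's threshold per
channel per field by default, or a user-fixed threshold — and coverage is
reported as the percentage of (sub)region pixels above threshold.  Fields
below the minimum reportable area of 0.28 mm² are excluded from cohort
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .roi_analysis import GROUP_TABLE_COLUMNS

__all__ = ["IHCField", "BinarizationResult", "binarize_channel", "area_fraction", "field_report"]

#: smallest field area (mm^2) accepted for cohort reporting
MIN_FIELD_AREA_MM2 = 0.28

MARKERS = ("GFAP", "Iba1")


@dataclass
class IHCField:
    """One microscope field: named channel images sharing a shape, the
    pixel size in µm/pixel, and provenance labels."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    region: str = ""
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("field needs at least one channel")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1 or any(len(s) != 2 for s in shapes):
            raise ValueError("all channels must be 2D images of one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def area_mm2(self) -> float:
        h, w = self.shape
        return h * w * (self.pixel_size_um * 1e-3) ** 2


@dataclass(frozen=True)
class BinarizationResult:
    mask: np.ndarray
    threshold: float
    method: str
    channel: str


def binarize_channel(
    ihc_field: IHCField,
    channel: str,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> BinarizationResult:
    """Threshold one channel into a staining mask (intensity >= threshold).

    ``method="otsu"`` picks the threshold automatically per field;
    ``method="fixed"`` requires ``fixed_threshold``.  A constant-intensity
    image defeats Otsu and raises with advice to use a fixed threshold.
    """
    if channel not in ihc_field.channels:
        raise KeyError(f"channel {channel!r} not in field ({sorted(ihc_field.channels)})")
    img = ihc_field.channels[channel]
    if method == "otsu":
        if fixed_threshold is not None:
            raise ValueError("fixed_threshold is only valid with method='fixed'")
        if np.ptp(img) == 0:
            raise ValueError(
                "constant-intensity channel: Otsu cannot split it; use method='fixed'"
            )
        thr = float(threshold_otsu(img))
        # threshold_otsu returns a value strictly below the upper class;
        # use >= on the midpoint-style threshold for mask semantics
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"method must be 'otsu' or 'fixed', got {method!r}")
    return BinarizationResult(img >= thr, thr, method, channel)


def area_fraction(mask: np.ndarray, subregion_mask: np.ndarray | None = None) -> float:
    """Percent of (sub)region pixels that are stained.

    Returns ``100 * stained-within-subregion / subregion pixels``; the full
    field when no subregion is given.  Always in [0, 100].
    """
    mask = np.asarray(mask, dtype=bool)
    if subregion_mask is None:
        denom = mask.size
        num = int(mask.sum())
    else:
        sub = np.asarray(subregion_mask, dtype=bool)
        if sub.shape != mask.shape:
            raise ValueError("mask and subregion mask must share dimensions")
        denom = int(sub.sum())
        if denom == 0:
            raise ValueError("empty subregion")
        num = int((mask & sub).sum())
    return 100.0 * num / denom


def field_report(
    fields: "list[IHCField]",
    markers=MARKERS,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area_mm2: float = MIN_FIELD_AREA_MM2,
) -> tuple[pd.DataFrame, "list[str]"]:
    """Coverage table: one row per subject × region × marker.

    Fields below ``min_area_mm2`` are excluded; the returned second element
    lists exclusion reasons.  The output uses GroupTable columns with the
    marker recorded in ``region`` as ``<region>:<marker>`` kept separate via
    a ``marker`` column, value = percent coverage, n_voxels = pixel count.
    """
    rows = []
    excluded: list[str] = []
    for f in fields:
        if f.area_mm2 < min_area_mm2:
            excluded.append(
                f"{f.subject_id}/{f.region}: field area {f.area_mm2:.3f} mm^2 "
                f"< {min_area_mm2} mm^2"
            )
            continue
        for marker in markers:
            res = binarize_channel(f, marker, method=method, fixed_threshold=fixed_threshold)
            rows.append(
                (
                    f.subject_id,
                    f.group,
                    f.region,
                    marker,
                    area_fraction(res.mask),
                    res.mask.size,
                    res.threshold,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "region", "marker", "value", "n_voxels", "threshold"],
    )
    return df, excluded
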