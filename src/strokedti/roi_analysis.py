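"""Region-of-interest summaries of scalar maps and cohort table assembly.

Interactive ROI drawing is replaced by explicit :class:`~strokedti.image_io.
LabelMap` inputs whose legends carry side-specific region ids (for example
``hippocampus_CA23_ipsi``), so hemisphere assignment is a property of the
label map rather than a midline heuristic.  Summaries operate strictly on
the given labels and on defined (non-NaN) map values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import LabelMap, ScalarMap

__all__ = ["RegionSummary", "roi_summary", "cohort_roi_table", "GROUP_TABLE_COLUMNS"]

GROUP_TABLE_COLUMNS = ["subject_id", "group", "region", "hemisphere", "value", "n_voxels"]


@dataclass(frozen=True)
class RegionSummary:
    region: str
    mean: float
    sd: float
    n_voxels: int


def roi_summary(
    smap: ScalarMap,
    labels: LabelMap,
    region_ids: "list[str] | None" = None,
) -> dict[str, RegionSummary]:
    """Mean, SD and voxel count of a scalar map per labeled region.

    Only voxels carrying the region's label *and* a defined map value enter
    the summary.  A requested region with zero defined voxels is an error.
    """
    if labels.grid != smap.grid:
        raise ValueError("scalar map and label map must share one grid")
    if region_ids is None:
        region_ids = sorted(labels.legend)
    defined = smap.defined
    out: dict[str, RegionSummary] = {}
    for region in region_ids:
        sel = labels.region_mask(region) & defined
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"region {region!r} has no defined voxels in this map")
        vals = smap.values[sel]
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out[region] = RegionSummary(region, float(np.mean(vals)), sd, n)
    return out


def _split_side(region: str) -> tuple[str, str]:
    for side in ("ipsi", "contra"):
        suffix = "_" + side
        if region.endswith(suffix):
            return region[: -len(suffix)], side
    return region, "ipsi"


def cohort_roi_table(subjects, region_ids: "list[str] | None" = None) -> pd.DataFrame:
    """Assemble one GroupTable row per subject × region × hemisphere.

    ``subjects`` is an iterable of ``(subject_id, group, scalar_map,
    label_map)``.  ``region_ids`` selects the regions to summarize
    (default: the first subject's full legend); a subject lacking a
    requested region is an error naming both.  Legend names ending in
    ``_ipsi``/``_contra`` are split into a base region name plus hemisphere
    column.
    """
    rows = []
    seen_ids: set[str] = set()
    for subject_id, group, smap, labels in subjects:
        if subject_id in seen_ids:
            raise ValueError(f"duplicate subject id {subject_id!r}")
        seen_ids.add(subject_id)
        if region_ids is None:
            region_ids = sorted(labels.legend)
        missing = [r for r in region_ids if r not in labels.legend]
        if missing:
            raise ValueError(f"subject {subject_id!r} is missing region(s) {missing}")
        try:
            summaries = roi_summary(smap, labels, region_ids)
        except ValueError as exc:
            raise ValueError(f"subject {subject_id!r}: {exc}") from exc
        for region, s in summaries.items():
            base, side = _split_side(region)
            rows.append((subject_id, group, base, side, s.mean, s.n_voxels))
    df = pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS)
    dup = df.duplicated(subset=["subject_id", "region", "hemisphere"])
    if dup.any():
        raise ValueError("duplicate (subject, region, hemisphere) rows")
    return df
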