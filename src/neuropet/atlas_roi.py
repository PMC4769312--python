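"""Atlas label propagation and region-of-interest extraction.

An integer-labelled atlas defined on a template grid is pulled through a
chain of transforms (template → structural → PET) with nearest-neighbor
interpolation, after which region TACs and per-region statistics of
parametric maps are extracted.  Region groupings (the reporting ROIs, the
cerebellar gray matter reference, the subcortical white matter region) are
named sets of label ids supplied as an editable TSV so any labelled atlas
can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet

import numpy as np
import pandas as pd

from .core_io import DynamicImage, ParametricMap, VolumeGeometry
from .registration import TransformChain, compose_chain, warp_image
from .water_kinetics import TissueCurve, frame_weights

__all__ = [
    "LabelVolume",
    "RegionSet",
    "RegionStats",
    "DEFAULT_REPORTING_REGIONS",
    "propagate_labels",
    "region_tac",
    "region_statistics",
    "load_label_table",
    "save_label_table",
    "load_region_set",
    "save_region_set",
]

#: The 14 reporting regions (13 cortical/subcortical gray + subcortical white
#: matter) plus the cerebellar gray matter reference.  WBGM is the composite
#: average of the 13 gray-matter regions.
DEFAULT_REPORTING_REGIONS = (
    "AMY", "HIPP", "PHIP", "CAU", "PUT", "PALL", "THAL", "INS",
    "FRT", "PAR", "TEMP", "OCC", "CGM", "SWM",
)

GRAY_MATTER_REGIONS = (
    "AMY", "HIPP", "PHIP", "CAU", "PUT", "PALL", "THAL", "INS",
    "FRT", "PAR", "TEMP", "OCC", "CGM",
)


@dataclass
class LabelVolume:
    """Integer atlas labels plus an id → name table; 0 is background."""

    labels: np.ndarray
    geometry: VolumeGeometry
    table: Dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.shape != self.geometry.shape:
            raise ValueError("label shape does not match geometry")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"labels missing from table: {sorted(missing)}")

    def mask_for(self, label_ids) -> np.ndarray:
        return np.isin(self.labels, list(label_ids))


@dataclass
class RegionSet:
    """Named groups of atlas label ids (e.g. FRT, CGM, SWM)."""

    groups: Dict[str, FrozenSet[int]]

    def __post_init__(self):
        for name, ids in self.groups.items():
            if not ids:
                raise ValueError(f"region group {name!r} is empty")
            self.groups[name] = frozenset(int(i) for i in ids)

    def validate_against(self, labels: LabelVolume):
        known = set(labels.table)
        for name, ids in self.groups.items():
            unknown = set(ids) - known
            if unknown:
                raise ValueError(f"group {name!r} references unknown labels {sorted(unknown)}")


@dataclass
class RegionStats:
    """Per-region mean/SD/voxel-count table for one parametric map."""

    table: pd.DataFrame  # columns: region, n, mean, sd, units

    def mean_of(self, region: str) -> float:
        row = self.table[self.table["region"] == region]
        if row.empty:
            raise KeyError(region)
        return float(row["mean"].iloc[0])


def propagate_labels(
    atlas: LabelVolume, chain: TransformChain, target_geometry: VolumeGeometry
) -> LabelVolume:
    """Pull atlas labels into a target grid through a transform chain.

    Nearest-neighbor interpolation; out-of-domain voxels become background.
    The composed chain must map the target grid into the atlas grid.
    """
    field = compose_chain(chain, target_geometry)
    warped = warp_image(atlas.labels, field, interp="nearest")
    return LabelVolume(warped.astype(atlas.labels.dtype), target_geometry, dict(atlas.table))


def region_tac(img: DynamicImage, labels: LabelVolume, group) -> TissueCurve:
    """Per-frame unweighted mean TAC over a group of labels.

    ``group`` is an iterable of label ids (or a single id).
    """
    if np.isscalar(group):
        group = [group]
    mask = labels.mask_for(group)
    if not np.any(mask):
        raise ValueError("region group has no voxels in the label volume")
    vals = img.data[mask].mean(axis=0)
    return TissueCurve(img.schedule.mid_times_min, vals, frame_weights(img.schedule), img.schedule)


def region_statistics(
    pmap: ParametricMap, labels: LabelVolume, regions: RegionSet
) -> RegionStats:
    """Mean, SD (n−1) and voxel count of a parametric map per region group.

    The whole-brain gray matter composite (WBGM) is the unweighted mean of
    the individual gray-matter region means — an average of averages, not a
    voxel-pooled mean.  Empty groups are reported as missing rows (NaN), not
    as zeros.
    """
    if pmap.data.shape != labels.labels.shape:
        raise ValueError("map and labels are not aligned")
    rows = []
    gray_means = []
    for name, ids in regions.groups.items():
        mask = labels.mask_for(ids) & np.isfinite(pmap.data)
        n = int(np.count_nonzero(mask))
        if n == 0:
            rows.append({"region": name, "n": 0, "mean": np.nan, "sd": np.nan,
                         "units": pmap.units})
            continue
        vals = pmap.data[mask]
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append({"region": name, "n": n, "mean": float(vals.mean()), "sd": sd,
                     "units": pmap.units})
        if name in GRAY_MATTER_REGIONS and name != "CGM":
            gray_means.append(float(vals.mean()))
    if gray_means:
        gm = np.asarray(gray_means)
        rows.append({
            "region": "WBGM", "n": len(gray_means), "mean": float(gm.mean()),
            "sd": float(gm.std(ddof=1)) if gm.size > 1 else 0.0, "units": pmap.units,
        })
    return RegionStats(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# TSV round-trips
# ---------------------------------------------------------------------------

def save_label_table(table: Dict[int, str], path) -> Path:
    df = pd.DataFrame({"label_id": list(table), "name": list(table.values())})
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_label_table(path) -> Dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    return {int(r.label_id): str(r.name) for r in df.itertuples()}


def save_region_set(regions: RegionSet, path) -> Path:
    rows = [
        {"region": name, "label_ids": ",".join(str(i) for i in sorted(ids))}
        for name, ids in regions.groups.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def load_region_set(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t")
    groups = {
        str(r.region): frozenset(int(x) for x in str(r.label_ids).split(","))
        for r in df.itertuples()
    }
    return RegionSet(groups)
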