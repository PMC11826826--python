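"""Projection of sparse vessel-voxel breakpoint values into a region atlas.

Vessel voxels are sparse; regional averaging assigns the mean breakpoint of
the arterial voxels inside each atlas region to the whole region, producing
filled parametric maps that can be compared across modalities and across
pre/post vasodilation scans.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitting import MattMap

#: canonical column order of a regional table
TABLE_COLUMNS = ("region_label", "mean_matt_ms", "n_vessel_voxels",
                 "region_volume")


def project_to_regions(matt_map, atlas, min_voxels: int = 5,
                       extra_maps: dict[str, np.ndarray] | None = None
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Regional mean of defined breakpoint voxels, plus a filled map.

    Per nonzero atlas label, the unweighted mean of defined map voxels is
    computed and assigned to every voxel of that region; regions with fewer
    than ``min_voxels`` defined voxels are undefined (NaN).  ``extra_maps``
    are additional co-registered scalar volumes (e.g. a tissue arrival-time
    map) averaged over the *full* region.

    Returns
    -------
    table : DataFrame indexed by region label with columns ``mean_matt_ms``,
        ``n_vessel_voxels``, ``region_volume`` (+ ``mean_<name>`` per extra
        map).
    filled : 3D float volume; NaN for background and undefined regions.
    """
    matt = matt_map.matt if isinstance(matt_map, MattMap) else np.asarray(
        matt_map, float)
    atlas = np.asarray(atlas)
    if atlas.shape != matt.shape:
        raise ValueError(
            f"atlas grid {atlas.shape} != map grid {matt.shape}")
    labels = np.unique(atlas)
    labels = labels[labels != 0]
    defined = np.isfinite(matt)

    rows = []
    filled = np.full(matt.shape, np.nan)
    for lab in labels:
        region = atlas == lab
        sel = region & defined
        n = int(sel.sum())
        mean = float(matt[sel].mean()) if n >= min_voxels and n > 0 else np.nan
        row = {
            "region_label": int(lab),
            "mean_matt_ms": mean,
            "n_vessel_voxels": n,
            "region_volume": int(region.sum()),
        }
        if extra_maps:
            for name, vol in extra_maps.items():
                vol = np.asarray(vol, float)
                vals = vol[region]
                vals = vals[np.isfinite(vals)]
                row[f"mean_{name}"] = (
                    float(vals.mean()) if vals.size else np.nan)
        rows.append(row)
        if np.isfinite(mean):
            filled[region] = mean
    table = pd.DataFrame(rows).set_index("region_label")
    return table, filled


def regional_delta(pre: pd.DataFrame, post: pd.DataFrame,
                   atlas: np.ndarray | None = None
                   ) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Post-minus-pre regional breakpoint change.

    Vasodilation (earlier arrival) gives negative deltas.  Regions
    undefined on either side are undefined in the delta.  If ``atlas`` is
    given, a filled delta map is returned as well.
    """
    if set(pre.index) != set(post.index):
        diff = sorted(set(pre.index) ^ set(post.index))
        raise ValueError(f"region label sets differ; symmetric difference: "
                         f"{diff}")
    post = post.loc[pre.index]
    table = pd.DataFrame(
        {
            "delta_matt_ms": post["mean_matt_ms"] - pre["mean_matt_ms"],
            "n_pre": pre["n_vessel_voxels"],
            "n_post": post["n_vessel_voxels"],
        },
        index=pre.index,
    )
    if atlas is None:
        return table
    filled = np.full(atlas.shape, np.nan)
    for lab, row in table.iterrows():
        if np.isfinite(row["delta_matt_ms"]):
            filled[atlas == lab] = row["delta_matt_ms"]
    return table, filled


def apply_common_mask(pre_map: MattMap, post_map: MattMap
                      ) -> tuple[MattMap, MattMap]:
    """Restrict both maps to vessels already visible in the pre scan.

    Post-vasodilation scans typically reveal additional distal (late-
    arriving) vessels; without a common mask these newly visible voxels
    inflate regional deltas.  Both maps are restricted to the intersection
    of their defined-voxel sets with the pre-scan vessel mask.
    """
    if pre_map.matt.shape != post_map.matt.shape:
        raise ValueError("pre and post map grids differ")
    common = (pre_map.defined & post_map.defined
              & np.asarray(pre_map.mask, bool))

    def restrict(m: MattMap) -> MattMap:
        keep = common
        return MattMap(
            matt=np.where(keep, m.matt, np.nan),
            amplitude=np.where(keep, m.amplitude, np.nan),
            quality=np.where(keep, m.quality, np.nan),
            status=np.where(keep, m.status, 255).astype(np.uint8),
            mask=keep,
        )

    return restrict(pre_map), restrict(post_map)


class AtlasProjector(BaseEstimator):
    """sklearn-style transformer projecting voxel maps into atlas regions.

    ``fit(atlas)`` stores the parcellation; ``transform(matt_map)`` returns
    the filled regional map and stores the regional table as ``table_``.
    """

    def __init__(self, min_voxels: int = 5):
        self.min_voxels = min_voxels

    def fit(self, atlas, y=None):
        atlas = np.asarray(atlas)
        if not np.issubdtype(atlas.dtype, np.integer):
            raise ValueError("atlas must be an integer label volume")
        self.atlas_ = atlas
        return self

    def transform(self, matt_map, extra_maps=None) -> np.ndarray:
        if not hasattr(self, "atlas_"):
            raise RuntimeError("AtlasProjector is not fitted")
        table, filled = project_to_regions(
            matt_map, self.atlas_, min_voxels=self.min_voxels,
            extra_maps=extra_maps)
        self.table_ = table
        return filled
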