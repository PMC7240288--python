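"""Concrete brain-behavior analyses built on the PLSC engine.

Covers the study's analysis chain: the omnibus behavioral PLS of
whole-brain SD_BOLD against an 8-variable panel, group-comparison PLS
runs, the age-by-battery behavioral PLS, the post hoc MTL SD_BOLD versus
MTL-volume PLS, cross-model brain-score correlations, global white-matter
summaries, demographic t-tests, and bootstrap-ratio cluster tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .pls import (BehaviorBlock, GroupedDataBlock, PLSError, PLSResult,
                  behavioral_pls, mean_centered_pls)
from .variability import BrainMask, SDBoldMap

BEHAVIOR_PANEL_COLUMNS = ["age", "MoCA", "global_FA", "global_MD",
                          "visuospatial", "control_speed", "memory", "intelligence"]
MTL_VOLUME_COLUMNS = ["CA1", "CA2/3-DG", "subiculum", "alERC", "pmERC", "PRC", "PHC"]


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scalar summaries and simple statistics


def global_nonzero_mean(volume: np.ndarray) -> float:
    """Mean over strictly non-zero voxels (global skeleton FA/MD summary)."""
    v = np.asarray(volume, dtype=float)
    nz = v[v != 0]
    if nz.size == 0:
        raise PipelineError("volume has no non-zero voxels")
    return float(nz.mean())


def two_sample_t(a, b, welch: bool = False):
    """Pooled-variance (default) or Welch two-sample t-test.

    Each of ``a`` and ``b`` is either a raw value vector or a printed
    summary triple ``(mean, sd, n)``, so published table rows can be
    checked directly.  Returns ``(t, df, p)`` with a two-sided p.
    """
    def unpack(x):
        if isinstance(x, (tuple, list)) and len(x) == 3 and np.isscalar(x[0]):
            m, s, n = float(x[0]), float(x[1]), int(x[2])
        else:
            arr = np.asarray(x, dtype=float)
            m, s, n = arr.mean(), arr.std(ddof=1), arr.size
        if n < 2:
            raise PipelineError("each group needs n >= 2")
        if s <= 0:
            raise PipelineError("group SD must be positive")
        return m, s, n

    m1, s1, n1 = unpack(a)
    m2, s2, n2 = unpack(b)
    if welch:
        se2 = s1**2 / n1 + s2**2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((s1**2 / n1)**2 / (n1 - 1) + (s2**2 / n2)**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        if sp2 <= 0:
            raise PipelineError("zero pooled variance")
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def correlate_brain_scores(scores_a: np.ndarray, scores_b: np.ndarray,
                           group: np.ndarray) -> dict:
    """Per-group Pearson correlation between two LV1 brain-score vectors."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise PipelineError("brain-score vectors must share subjects and order")
    out = {}
    for g in pd.unique(group):
        sel = group == g
        if a[sel].std() == 0 or b[sel].std() == 0:
            raise PipelineError(f"zero-variance brain scores in group {g!r}")
        r, p = stats.pearsonr(a[sel], b[sel])
        out[str(g)] = (float(r), float(p))
    return out


# ---------------------------------------------------------------------------
# SD_BOLD stacking and PLS runs


def stack_sd_maps(sd_maps: dict, subject_ids: list) -> tuple[np.ndarray, BrainMask]:
    """Vectorize per-subject SD maps (shared mask) into subjects x voxels."""
    masks = [sd_maps[s].mask.data for s in subject_ids]
    ref = masks[0]
    if any(m.shape != ref.shape or not np.array_equal(m, ref) for m in masks):
        raise PipelineError("all SD maps must share one mask and grid")
    X = np.vstack([sd_maps[s].values() for s in subject_ids])
    return X, sd_maps[subject_ids[0]].mask


def run_whole_brain_behavior_pls(sd_maps: dict, panel: pd.DataFrame,
                                 subject_ids: list, group: np.ndarray,
                                 n_perm: int = 1000, n_boot: int = 1000,
                                 seed: int | None = None) -> PLSResult:
    """Omnibus behavioral PLS: whole-brain SD_BOLD against the 8-variable panel."""
    missing = [c for c in BEHAVIOR_PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PipelineError(f"behavior panel misses columns: {missing}")
    moca = panel["MoCA"].to_numpy(dtype=float)
    if np.any((moca < 0) | (moca > 30)):
        raise PipelineError("MoCA scores must lie in [0, 30]")
    X, mask = stack_sd_maps(sd_maps, subject_ids)
    block = GroupedDataBlock(X, group)
    behav = BehaviorBlock(panel[BEHAVIOR_PANEL_COLUMNS].to_numpy(dtype=float),
                          BEHAVIOR_PANEL_COLUMNS)
    res = behavioral_pls(block, behav, n_perm, n_boot, seed)
    res.meta["mask"] = mask
    return res


def run_group_comparison_pls(values: np.ndarray, group: np.ndarray,
                             element_ids: list | None = None,
                             n_perm: int = 1000, n_boot: int = 1000,
                             seed: int | None = None) -> PLSResult:
    """Mean-centered PLS of any subjects-by-elements block against group."""
    block = GroupedDataBlock(np.asarray(values, dtype=float), group, element_ids)
    return mean_centered_pls(block, n_perm, n_boot, seed)


def run_age_battery_pls(battery: pd.DataFrame, age: np.ndarray,
                        group: np.ndarray, n_perm: int = 1000,
                        n_boot: int = 1000, seed: int | None = None) -> PLSResult:
    """Behavioral PLS of the oriented 14-test battery against age alone."""
    X = battery.to_numpy(dtype=float)
    block = GroupedDataBlock(X, group, list(battery.columns))
    behav = BehaviorBlock(np.asarray(age, dtype=float)[:, None], ["age"])
    return behavioral_pls(block, behav, n_perm, n_boot, seed)


@dataclass
class MTLBlock:
    """MTL-restricted SD_BOLD block with write-back voxel indexing."""

    X: np.ndarray  # subjects x MTL voxels
    voxel_index: np.ndarray  # (n_vox, 3) coordinates in the source grid
    group: np.ndarray

    def to_volume(self, values: np.ndarray, shape: tuple) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[tuple(self.voxel_index.T)] = values
        return out


def extract_mtl_block(sd_maps: dict, subject_ids: list, group: np.ndarray,
                      mtl_labels: np.ndarray) -> MTLBlock:
    """Restrict stacked SD maps to MTL-labeled voxels inside the mask."""
    X, mask = stack_sd_maps(sd_maps, subject_ids)
    lab = np.asarray(mtl_labels, dtype=bool)
    if lab.shape != mask.data.shape:
        raise PipelineError("MTL label volume must match the mask grid")
    inter = lab & mask.data
    if not inter.any():
        raise PipelineError("MTL labels do not intersect the gray-matter mask")
    keep = lab[mask.data]  # columns of X are mask voxels in C order
    coords = np.argwhere(inter)
    return MTLBlock(X[:, keep], coords, np.asarray(group))


def run_mtl_volume_pls(mtl_block: MTLBlock, volumes: pd.DataFrame,
                       n_perm: int = 1000, n_boot: int = 1000,
                       seed: int | None = None) -> PLSResult:
    """Post hoc behavioral PLS: MTL SD_BOLD against 7 subregion volumes."""
    missing = [c for c in MTL_VOLUME_COLUMNS if c not in volumes.columns]
    if missing:
        raise PipelineError(f"volume panel misses columns: {missing}")
    Y = volumes[MTL_VOLUME_COLUMNS].to_numpy(dtype=float)
    if np.any(Y <= 0):
        raise PipelineError("subregion volumes must be positive")
    block = GroupedDataBlock(mtl_block.X, mtl_block.group)
    return behavioral_pls(block, BehaviorBlock(Y, MTL_VOLUME_COLUMNS),
                          n_perm, n_boot, seed)


# ---------------------------------------------------------------------------
# cluster reporting


@dataclass
class ClusterTable:
    table: pd.DataFrame  # label, peak_x/y/z, size_voxels, peak_bsr
    threshold: float
    min_size: int


def cluster_table(bsr_map: np.ndarray, threshold: float = 4.0,
                  min_size: int = 5, affine: np.ndarray | None = None) -> ClusterTable:
    """Connected suprathreshold clusters of a bootstrap-ratio map.

    Binarizes at |BSR| >= threshold, labels 26-connected components, drops
    clusters below ``min_size`` voxels, and reports each surviving
    cluster's size and peak-|BSR| voxel, sorted by size descending.  Peak
    coordinates are voxel indices; if an affine is given, world-space
    coordinates are reported alongside.
    """
    m = np.asarray(bsr_map, dtype=float)
    binary = np.abs(np.nan_to_num(m)) >= threshold
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3, 3)))
    rows = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        if idx.shape[0] < min_size:
            continue
        vals = m[tuple(idx.T)]
        peak = idx[np.argmax(np.abs(vals))]
        row = {"label": lab, "peak_x": int(peak[0]), "peak_y": int(peak[1]),
               "peak_z": int(peak[2]), "size_voxels": int(idx.shape[0]),
               "peak_bsr": float(vals[np.argmax(np.abs(vals))])}
        if affine is not None:
            world = affine @ np.append(peak, 1.0)
            row.update({"world_x": world[0], "world_y": world[1], "world_z": world[2]})
        rows.append(row)
    rows.sort(key=lambda r: (-r["size_voxels"], r["label"]))
    cols = ["label", "peak_x", "peak_y", "peak_z", "size_voxels", "peak_bsr"]
    if affine is not None:
        cols += ["world_x", "world_y", "world_z"]
    df = pd.DataFrame(rows, columns=cols)
    return ClusterTable(df, threshold, min_size)


def bsr_volume(result: PLSResult, mask: BrainMask, lv: int = 0) -> np.ndarray:
    """Map one LV's element bootstrap ratios back onto the 3-D grid."""
    out = np.full(mask.data.shape, np.nan)
    out[mask.data] = result.resampling.bootstrap_ratio[:, lv]
    return out
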