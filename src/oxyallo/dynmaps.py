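"""Per-cell slow- and fast-dynamics indices and their spatial maps.

The slow index is the Spearman rank correlation of a cell's baseline
Fslow with -pO2 (positive = hypoxia-excited).  The fast index is the
d-prime contrast of dFF between the last five minutes of hypoxia
(35-40 min of the standard paradigm) and the last five minutes of
normoxia (15-20 min).  Swim coupling is the rank correlation of dFF with
instantaneous swim vigor.  Indices are accumulated on a 10 x 10 x 20 um
voxel grid, positive and negative channels kept separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .paradigm import Paradigm
from .synthdata import rasterize_vigor

__all__ = [
    "DynamicsIndex",
    "slow_index",
    "fast_index",
    "swim_coupling",
    "normalized_fslow",
    "compute_indices",
    "VoxelMap",
    "make_map",
]


@dataclass
class DynamicsIndex:
    """Per-cell index table (one row per cell)."""

    table: pd.DataFrame  # slow_r, fast_dprime, swim_r, norm_fslow, flags


def _resample_po2(po2: np.ndarray, po2_fs: float, n_frames: int,
                  frame_rate: float) -> np.ndarray:
    t_frames = np.arange(n_frames) / frame_rate
    t_po2 = np.arange(po2.size) / po2_fs
    return np.interp(t_frames, t_po2, po2)


def slow_index(
    fslow: np.ndarray, po2: np.ndarray, po2_fs: float, frame_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman r of each cell's Fslow with -pO2.

    Returns (r, flat_flag); constant series get r = 0 with the flag set.
    """
    fslow = np.atleast_2d(np.asarray(fslow, dtype=float))
    po2_f = _resample_po2(np.asarray(po2, float), po2_fs, fslow.shape[1], frame_rate)
    if po2_f.size != fslow.shape[1]:
        raise ValueError("length mismatch after resampling")
    r = np.zeros(fslow.shape[0])
    flat = np.zeros(fslow.shape[0], dtype=bool)
    for i, row in enumerate(fslow):
        if row.std() == 0 or po2_f.std() == 0:
            flat[i] = True
        else:
            r[i] = spearmanr(row, -po2_f).statistic
    return r, flat


def fast_index(
    dff: np.ndarray,
    schedule: Paradigm,
    frame_rate: float,
    window_min: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """d-prime of dFF between the last minutes of hypoxia and of normoxia.

    d' = (mu_hyp - mu_norm) / sqrt((var_hyp + var_norm) / 2); cells with
    zero variance in both windows are flagged undefined (NaN).
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    w_norm = schedule.last_minutes("normoxia", window_min)
    w_hyp = schedule.last_minutes("hypoxia", window_min)
    t = np.arange(dff.shape[1]) / frame_rate
    m_norm = (t >= w_norm[0]) & (t < w_norm[1])
    m_hyp = (t >= w_hyp[0]) & (t < w_hyp[1])
    if not (m_norm.any() and m_hyp.any()):
        raise ValueError("schedule windows not covered by the trace")
    mu_h, mu_n = dff[:, m_hyp].mean(axis=1), dff[:, m_norm].mean(axis=1)
    va_h, va_n = dff[:, m_hyp].var(axis=1), dff[:, m_norm].var(axis=1)
    pooled = np.sqrt((va_h + va_n) / 2.0)
    undefined = pooled == 0
    d = np.where(undefined, np.nan, (mu_h - mu_n) / np.where(pooled == 0, 1, pooled))
    return d, undefined


def swim_coupling(
    dff: np.ndarray, bouts: pd.DataFrame, frame_rate: float
) -> np.ndarray:
    """Spearman r between instantaneous swim vigor (box-integrated per
    frame) and each cell's dFF."""
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    duration = dff.shape[1] / frame_rate
    vigor = rasterize_vigor(bouts, duration, 1.0 / frame_rate)[: dff.shape[1]]
    out = np.zeros(dff.shape[0])
    if vigor.std() == 0:
        return out
    for i, row in enumerate(dff):
        if row.std() > 0:
            out[i] = spearmanr(vigor, row).statistic
    return out


def normalized_fslow(
    fslow: np.ndarray, schedule: Paradigm, frame_rate: float
) -> np.ndarray:
    """Mean Fslow during hypoxia divided by mean during normoxia."""
    fslow = np.atleast_2d(np.asarray(fslow, dtype=float))
    t = np.arange(fslow.shape[1]) / frame_rate
    lab = schedule.label_at(t)
    m_h, m_n = lab == "hypoxia", lab == "normoxia"
    return fslow[:, m_h].mean(axis=1) / fslow[:, m_n].mean(axis=1)


def compute_indices(
    fslow: np.ndarray,
    dff: np.ndarray,
    po2: np.ndarray,
    po2_fs: float,
    bouts: pd.DataFrame,
    schedule: Paradigm,
    frame_rate: float,
) -> DynamicsIndex:
    r, flat = slow_index(fslow, po2, po2_fs, frame_rate)
    d, undef = fast_index(dff, schedule, frame_rate)
    return DynamicsIndex(
        table=pd.DataFrame(
            {
                "slow_r": r,
                "slow_flat": flat,
                "fast_dprime": d,
                "fast_undefined": undef,
                "swim_r": swim_coupling(dff, bouts, frame_rate),
                "norm_fslow": normalized_fslow(fslow, schedule, frame_rate),
            }
        )
    )


@dataclass
class VoxelMap:
    positive: np.ndarray  # nx x ny x nz mean positive index per voxel
    negative: np.ndarray  # nx x ny x nz mean |negative| index per voxel
    fish_counts: np.ndarray  # voxels with >= 1 contributing cell, per fish count
    grid_origin: np.ndarray
    voxel_size: tuple[float, float, float]


def make_map(
    indices: np.ndarray,
    coords: np.ndarray,
    n_fish: int = 1,
    fish_id: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 20.0),
) -> VoxelMap:
    """Average per-cell indices in a moving 10 x 10 x 20 um window.

    Each voxel averages the cells whose window covers it; positive and
    negative index values accumulate in separate channels, and per-voxel
    fish counts record how many fish contribute at least one cell.
    """
    indices = np.asarray(indices, dtype=float)
    coords = np.asarray(coords, dtype=float)
    fish_id = np.zeros(indices.size, dtype=int) if fish_id is None else fish_id
    vox = np.asarray(voxel_size, dtype=float)
    origin = coords.min(axis=0)
    shape = np.maximum(
        np.ceil((coords.max(axis=0) - origin) / vox).astype(int) + 1, 1
    )
    pos_sum = np.zeros(shape)
    pos_n = np.zeros(shape)
    neg_sum = np.zeros(shape)
    neg_n = np.zeros(shape)
    fish_sets = np.zeros((n_fish, *shape), dtype=bool)
    idx = np.floor((coords - origin) / vox).astype(int)
    for val, (ix, iy, iz), f in zip(indices, idx, fish_id):
        if not np.isfinite(val):
            continue
        if val >= 0:
            pos_sum[ix, iy, iz] += val
            pos_n[ix, iy, iz] += 1
        else:
            neg_sum[ix, iy, iz] += -val
            neg_n[ix, iy, iz] += 1
        fish_sets[f, ix, iy, iz] = True
    with np.errstate(invalid="ignore"):
        positive = np.where(pos_n > 0, pos_sum / np.maximum(pos_n, 1), 0.0)
        negative = np.where(neg_n > 0, neg_sum / np.maximum(neg_n, 1), 0.0)
    return VoxelMap(
        positive=positive,
        negative=negative,
        fish_counts=fish_sets.sum(axis=0),
        grid_origin=origin,
        voxel_size=tuple(vox),
    )
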