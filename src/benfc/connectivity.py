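"""Seed-based whole-brain functional connectivity.

The seed signal is the unweighted mean time series over a seed mask (in the
source study the seed is the cluster showing a significant entropy change);
per-voxel Pearson correlations with that signal are Fisher z-transformed
(atanh) before any group statistic, with |r| clipped at 1 - 1e-7 so
self-seed voxels stay finite.
"""

from __future__ import annotations

import numpy as np

from .types import Bold4D, BrainMask, ScalarMap, check_same_grid

__all__ = ["seed_timeseries", "fc_map", "fisher_z", "R_CLIP"]

R_CLIP = 1.0 - 1e-7


def seed_timeseries(bold: Bold4D, seed: BrainMask) -> np.ndarray:
    """Unweighted mean over seed voxels at each time point."""
    check_same_grid(bold, seed)
    return bold.data[seed.include].mean(axis=0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing atanh, with |r| clipped at 1 - 1e-7."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def fc_map(
    bold: Bold4D,
    seed_series: np.ndarray,
    mask: BrainMask | None = None,
    transform: str = "fisher_z",
) -> ScalarMap:
    """Per-voxel Pearson correlation with the seed series.

    Zero-variance voxels and out-of-mask voxels are NaN. transform is
    "fisher_z" (default) or "r" for the raw correlation.
    """
    seed_series = np.asarray(seed_series, float)
    if seed_series.shape != (bold.n_volumes,):
        raise ValueError("seed series length does not match volume count")
    s_sd = seed_series.std()
    if s_sd == 0:
        raise ValueError("seed series is constant")
    include = mask.include if mask is not None else np.ones(bold.grid.dims, bool)
    if mask is not None:
        check_same_grid(bold, mask)
    X = bold.data[include]
    Xc = X - X.mean(axis=1, keepdims=True)
    sc = seed_series - seed_series.mean()
    x_sd = Xc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ sc) / (bold.n_volumes * x_sd * s_sd)
    r[x_sd == 0] = np.nan
    vals = fisher_z(r) if transform == "fisher_z" else np.clip(r, -1.0, 1.0)
    out = np.full(bold.grid.dims, np.nan)
    out[include] = vals
    return ScalarMap(bold.grid, out, "fc_z")
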