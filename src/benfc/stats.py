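"""Group inference on voxel maps plus the scalar tests used alongside.

Voxel-wise paired and two-sample t-maps are corrected for multiple
comparisons with an AlphaSim-style cluster-level Monte Carlo procedure:
smoothness is estimated from standardized group residuals (Forman
first-difference estimator), null Gaussian fields at that smoothness are
simulated on the analysis mask, thresholded two-tailed at the
cluster-forming p, and the (1 - alpha) quantile of the null maximum cluster
size + 1 becomes the minimum cluster extent. Clusters are sign-split
26-connected components by default. Tests are two-tailed throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors
from statsmodels.stats.multitest import multipletests

from .types import BrainMask, ScalarMap, check_same_grid

__all__ = [
    "StatMapResult",
    "Cluster",
    "ClusterReport",
    "paired_t_map",
    "two_sample_t_map",
    "estimate_smoothness",
    "cluster_mc_threshold",
    "extract_clusters",
    "fdr_bh",
    "lilliefors_normality",
    "mann_whitney_u",
    "clinical_correlation",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class StatMapResult:
    """Voxel-wise t and two-tailed p maps with their degrees of freedom."""

    t: ScalarMap
    p: ScalarMap
    df: int
    direction: Literal["post_minus_pre", "mdd_minus_hc", "a_minus_b"] = "a_minus_b"
    residuals: list[ScalarMap] = field(default_factory=list)


@dataclass
class Cluster:
    voxel_count: int
    peak_index: tuple[int, int, int]
    peak_t: float
    sign: int


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    min_cluster_size: int
    voxel_p: float
    t_critical: float

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "voxel_count": c.voxel_count,
                    "peak_x": c.peak_index[0],
                    "peak_y": c.peak_index[1],
                    "peak_z": c.peak_index[2],
                    "peak_t": c.peak_t,
                    "sign": c.sign,
                }
                for c in self.clusters
            ]
        )


def _stack(maps: Sequence[ScalarMap]) -> np.ndarray:
    grid = check_same_grid(*maps)
    return np.stack([m.values for m in maps]), grid


def paired_t_map(
    maps_pre: Sequence[ScalarMap],
    maps_post: Sequence[ScalarMap],
    direction: str = "post_minus_pre",
    keep_residuals: bool = True,
) -> StatMapResult:
    """Voxel-wise paired t on d = post - pre; df = n - 1.

    Voxels undefined (NaN) in any subject, or with zero difference variance,
    are undefined in the result. Residual maps (d_i - mean(d)) are kept for
    smoothness estimation.
    """
    if len(maps_pre) != len(maps_post):
        raise ValueError("pre/post lists must be subject-aligned and equal length")
    n = len(maps_pre)
    if n < 3:
        raise ValueError("paired t needs at least 3 subjects")
    pre, grid = _stack(maps_pre)
    post, grid2 = _stack(maps_post)
    if not grid.same_as(grid2):
        raise ValueError("pre/post grids differ")
    d = post - pre
    return _one_sample_t(d, grid, n - 1, direction, keep_residuals)


def _one_sample_t(d, grid, df, direction, keep_residuals):
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / math.sqrt(n))
    t[sd == 0] = np.nan
    p = np.where(np.isfinite(t), 2.0 * sps.t.sf(np.abs(t), df), np.nan)
    res = StatMapResult(
        ScalarMap(grid, t, "t"), ScalarMap(grid, p, "p"), df, direction
    )
    if keep_residuals:
        res.residuals = [ScalarMap(grid, d[i] - mean, "t") for i in range(n)]
    return res


def two_sample_t_map(
    maps_a: Sequence[ScalarMap],
    maps_b: Sequence[ScalarMap],
    direction: str = "a_minus_b",
    keep_residuals: bool = True,
) -> StatMapResult:
    """Pooled-variance two-sample t (a - b); df = n_a + n_b - 2."""
    na, nb = len(maps_a), len(maps_b)
    if na < 2 or nb < 2:
        raise ValueError("two-sample t needs at least 2 maps per group")
    a, grid = _stack(maps_a)
    b, grid2 = _stack(maps_b)
    if not grid.same_as(grid2):
        raise ValueError("group grids differ")
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[sp2 == 0] = np.nan
    p = np.where(np.isfinite(t), 2.0 * sps.t.sf(np.abs(t), df), np.nan)
    res = StatMapResult(
        ScalarMap(grid, t, "t"), ScalarMap(grid, p, "p"), df, direction
    )
    if keep_residuals:
        res.residuals = [
            ScalarMap(grid, a[i] - ma, "t") for i in range(na)
        ] + [ScalarMap(grid, b[i] - mb, "t") for i in range(nb)]
    return res


def estimate_smoothness(
    residual_maps: Sequence[ScalarMap], mask: BrainMask
) -> tuple[float, float, float]:
    """Per-axis FWHM (mm) of the residual noise field, Forman estimator.

    Each residual map is standardized over the mask; the lag-1 spatial
    autocorrelation per axis comes from the variance of first differences,
    rho = 1 - var(diff)/2. For a field produced by Gaussian-kernel smoothing
    the ACF is exp(-d^2 / (4 sigma_k^2)), so the equivalent kernel width is
    sigma_k = sqrt(-1 / (4 ln rho)) voxels and FWHM = 2.355 sigma_k * voxel.
    Floored at one voxel width per axis (white noise hits the floor).
    """
    if len(residual_maps) < 2:
        raise ValueError("need at least 2 residual maps")
    grid = check_same_grid(*residual_maps, mask)
    fwhm = []
    for axis in range(3):
        num = 0.0
        den = 0
        for m in residual_maps:
            v = np.where(mask.include, m.values, np.nan)
            sd = np.nanstd(v)
            if not sd > 0:
                raise ValueError("constant residual map")
            z = (v - np.nanmean(v)) / sd
            d = np.diff(z, axis=axis)
            ok = np.isfinite(d)
            num += np.nansum(d[ok] ** 2)
            den += int(ok.sum())
        if den == 0:
            raise ValueError(f"mask too thin along axis {axis} for smoothness")
        vdiff = num / den
        rho = 1.0 - vdiff / 2.0
        w = grid.voxel_size_mm[axis]
        if rho <= 0:
            fwhm.append(w)  # floor: at/below one voxel width
            continue
        sigma_vox = math.sqrt(-1.0 / (4.0 * math.log(rho)))
        fwhm.append(max(w, sigma_vox * w / _FWHM_TO_SIGMA))
    return tuple(fwhm)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def _max_cluster(binary: np.ndarray, structure: np.ndarray) -> int:
    lab, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_mc_threshold(
    mask: BrainMask,
    fwhm_mm: tuple[float, float, float] | float,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
) -> int:
    """Minimum cluster extent for corrected significance (AlphaSim-style).

    Simulates n_sim Gaussian fields smoothed to fwhm_mm on the mask's grid,
    re-standardized over the mask, thresholded two-tailed at voxel_p with
    sign-split components; the (1 - alpha) order statistic of the null
    maximum cluster size + 1 is the minimum size an observed cluster must
    reach.
    """
    if not (0 < voxel_p < 1 and 0 < alpha <= 1):
        raise ValueError("voxel_p in (0,1) and alpha in (0,1] required")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives an unstable tail quantile", stacklevel=2)
    if np.isscalar(fwhm_mm):
        fwhm_mm = (float(fwhm_mm),) * 3
    sigma_vox = [
        f * _FWHM_TO_SIGMA / w for f, w in zip(fwhm_mm, mask.grid.voxel_size_mm)
    ]
    zc = sps.norm.isf(voxel_p / 2.0)
    structure = _structure(connectivity)
    rng = np.random.default_rng(seed)
    inc = mask.include
    null_max = np.empty(n_sim, dtype=int)
    for s in range(n_sim):
        field = rng.standard_normal(mask.grid.dims)
        if any(sv > 1e-3 for sv in sigma_vox):
            field = ndimage.gaussian_filter(field, sigma_vox, mode="constant")
        v = field[inc]
        field = (field - v.mean()) / v.std()
        supra_pos = inc & (field > zc)
        supra_neg = inc & (field < -zc)
        null_max[s] = max(
            _max_cluster(supra_pos, structure), _max_cluster(supra_neg, structure)
        )
    k = math.ceil((1.0 - alpha) * n_sim)
    if k <= 0:
        return 1
    return int(np.sort(null_max)[k - 1]) + 1


def extract_clusters(
    stat: StatMapResult,
    voxel_p: float = 0.001,
    min_cluster_size: int = 1,
    connectivity: int = 26,
) -> ClusterReport:
    """Sign-split supra-threshold components of |t| > t_crit(voxel_p, df),
    filtered at min_cluster_size; peaks reported per cluster."""
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    tcrit = float(sps.t.isf(voxel_p / 2.0, stat.df))
    t = stat.t.values
    structure = _structure(connectivity)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        supra = np.isfinite(t) & ((t > tcrit) if sign > 0 else (t < -tcrit))
        lab, n = ndimage.label(supra, structure=structure)
        for ci in range(1, n + 1):
            idx = np.argwhere(lab == ci)
            if len(idx) < min_cluster_size:
                continue
            tv = t[tuple(idx.T)]
            peak = idx[np.argmax(np.abs(tv))]
            clusters.append(
                Cluster(len(idx), tuple(int(i) for i in peak),
                        float(tv[np.argmax(np.abs(tv))]), sign)
            )
    clusters.sort(key=lambda c: -c.voxel_count)
    return ClusterReport(clusters, min_cluster_size, voxel_p, tcrit)


def cluster_mask(stat: StatMapResult, report: ClusterReport,
                 sign: int | None = None, connectivity: int = 26) -> np.ndarray:
    """Boolean union of the surviving clusters (optionally one sign)."""
    t = stat.t.values
    structure = _structure(connectivity)
    out = np.zeros(t.shape, bool)
    for s in (1, -1):
        if sign is not None and s != sign:
            continue
        supra = np.isfinite(t) & ((t > report.t_critical) if s > 0 else (t < -report.t_critical))
        lab, n = ndimage.label(supra, structure=structure)
        if n == 0:
            continue
        counts = np.bincount(lab.ravel())
        for ci in range(1, n + 1):
            if counts[ci] >= report.min_cluster_size:
                out |= lab == ci
    return out


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    reject, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj


def lilliefors_normality(sample) -> tuple[float, float]:
    """Kolmogorov-Smirnov-Lilliefors test of normality with estimated
    mean/SD; returns (statistic, p)."""
    x = np.asarray(sample, float)
    if x.size < 5:
        raise ValueError("Lilliefors test needs n >= 5")
    if x.std() == 0:
        raise ValueError("constant sample")
    stat, p = _sm_lilliefors(x, dist="norm")
    return float(stat), float(p)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Rank-sum U with two-tailed p: exact enumeration when n_a + n_b <= 12
    and tie-free, tie-corrected normal approximation otherwise."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def clinical_correlation(
    deltas_measure: dict[str, np.ndarray],
    deltas_clinical: dict[str, np.ndarray],
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-tailed p for every (measure, clinical) pair of
    per-subject change scores, FDR-BH corrected across the family.

    Change vs. percent-change is the caller's choice of inputs; use
    `percent_change` to build the latter (zero-baseline subjects dropped
    with a warning there).
    """
    rows = []
    for mname, mv in deltas_measure.items():
        for cname, cv in deltas_clinical.items():
            mv_, cv_ = np.asarray(mv, float), np.asarray(cv, float)
            if mv_.shape != cv_.shape:
                raise ValueError(f"unaligned subjects for ({mname}, {cname})")
            if mv_.size < 4:
                raise ValueError("need n >= 4 subjects")
            r, p = sps.pearsonr(mv_, cv_)
            rows.append({"measure": mname, "clinical": cname,
                         "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    _, out["fdr_q"] = fdr_bh(out["p"].to_numpy(), q)
    return out


def percent_change(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """100 * (post - pre) / pre; zero-baseline entries become NaN with a
    warning and should be dropped pairwise by the caller."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    out = np.full(pre.shape, np.nan)
    nz = pre != 0
    if (~nz).any():
        warnings.warn(f"{int((~nz).sum())} zero-baseline subject(s) dropped",
                      stacklevel=2)
    out[nz] = 100.0 * (post[nz] - pre[nz]) / pre[nz]
    return out
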