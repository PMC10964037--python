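"""Temporal/spatial preprocessing of already-aligned resting-state volumes.

The chain (order fixed, recorded in the manifest) is:

    discard initial volumes -> spatial Gaussian smoothing -> temporal
    band-pass -> nuisance regression -> motion scrubbing with cubic-spline
    interpolation

Defaults follow common resting-state practice: drop 10 volumes, 8 mm FWHM,
0.01-0.1 Hz pass band, Friston-24 motion expansion plus global/WM/CSF mean
regressors, and per-volume framewise displacement (Power formulation,
50 mm head radius) flagging at 0.2 mm. Scrubbed volumes are replaced by a
per-voxel cubic spline through the unflagged time points and re-enter the
entropy/connectivity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import CubicSpline

from .types import Bold4D, BrainMask, MotionParams, check_same_grid

__all__ = [
    "PreprocConfig",
    "discard_initial",
    "smooth_gaussian",
    "bandpass",
    "framewise_displacement",
    "scrub_interpolate",
    "friston24",
    "regress_nuisance",
    "preprocess_session",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PreprocConfig:
    n_discard: int = 10
    fwhm_mm: float = 8.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    fd_threshold_mm: float = 0.2
    confound_set: Literal["friston24", "basic6", "none"] = "friston24"
    regress_global: bool = True
    regress_wm: bool = True
    regress_csf: bool = True
    head_radius_mm: float = 50.0
    max_flagged_frac: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 <= lo < hi):
            raise ValueError(f"need 0 <= lo < hi, got band {self.band_hz}")
        if not self.fd_threshold_mm > 0:
            raise ValueError("fd_threshold_mm must be > 0")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")


def discard_initial(
    bold: Bold4D, k: int, motion: MotionParams | None = None
) -> Bold4D | tuple[Bold4D, MotionParams]:
    """Drop the first k volumes; the motion table, if given, is trimmed in
    lockstep and returned alongside."""
    if k >= bold.n_volumes:
        raise ValueError(f"cannot discard {k} of {bold.n_volumes} volumes")
    out = bold.with_data(bold.data[..., k:])
    if motion is None:
        return out
    if motion.n_volumes != bold.n_volumes:
        raise ValueError("motion rows do not match volume count")
    return out, motion.drop_initial(k)


def smooth_gaussian(bold: Bold4D, fwhm_mm: float) -> Bold4D:
    """Per-volume Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per
    axis in mm. fwhm 0 is the identity; interior impulses keep unit mass."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return bold.with_data(bold.data.copy())
    sigma_vox = [
        fwhm_mm * _FWHM_TO_SIGMA / vs for vs in bold.grid.voxel_size_mm
    ]
    out = ndimage.gaussian_filter(
        bold.data, sigma=[*sigma_vox, 0.0], mode="reflect"
    )
    return bold.with_data(out)


def bandpass(bold_or_series, lo_hz: float, hi_hz: float, tr_s: float | None = None):
    """Zero-phase Butterworth (order 2 per pass, forward-backward) band-pass.

    Accepts a Bold4D or a plain array with time on the last axis (then tr_s
    is required). The mean is removed before filtering, so constant series
    come back as (numerical) zeros.
    """
    if isinstance(bold_or_series, Bold4D):
        data, tr = bold_or_series.data, bold_or_series.tr_s
    else:
        if tr_s is None:
            raise ValueError("tr_s required for plain-array input")
        data, tr = np.asarray(bold_or_series, float), float(tr_s)
    nyq = 0.5 / tr
    if not (0 < lo_hz < hi_hz):
        raise ValueError(f"need 0 < lo < hi, got ({lo_hz}, {hi_hz})")
    if hi_hz >= nyq:
        raise ValueError(f"high cut {hi_hz} Hz >= Nyquist {nyq:.4g} Hz")
    sos = signal.butter(2, [lo_hz / nyq, hi_hz / nyq], btype="band", output="sos")
    centered = data - data.mean(axis=-1, keepdims=True)
    out = signal.sosfiltfilt(sos, centered, axis=-1)
    if isinstance(bold_or_series, Bold4D):
        return bold_or_series.with_data(out)
    return out


def framewise_displacement(
    motion: MotionParams, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Power FD: sum of absolute backward differences of the 3 translations
    (mm) plus head_radius times those of the 3 rotations (rad); FD[0] = 0."""
    if motion.n_volumes < 2:
        raise ValueError("FD needs at least 2 volumes")
    dt = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    return np.concatenate([[0.0], dt + head_radius_mm * dr])


def scrub_interpolate(
    bold: Bold4D,
    fd: np.ndarray,
    threshold_mm: float = 0.2,
    max_flagged_frac: float = 0.5,
) -> tuple[Bold4D, list[int]]:
    """Replace volumes with FD > threshold by per-voxel cubic-spline values
    fitted through the unflagged time points.

    Returns the scrubbed session and the flagged volume indices. Sessions
    with more than max_flagged_frac flagged volumes are rejected; at least 4
    unflagged volumes are required for the cubic spline.
    """
    fd = np.asarray(fd, float)
    if fd.shape[0] != bold.n_volumes:
        raise ValueError("FD length does not match volume count")
    flagged = np.flatnonzero(fd > threshold_mm)
    if len(flagged) == 0:
        return bold.with_data(bold.data.copy()), []
    if len(flagged) > max_flagged_frac * bold.n_volumes:
        raise ValueError(
            f"{len(flagged)}/{bold.n_volumes} volumes flagged "
            f"(> {max_flagged_frac:.0%}); session rejected"
        )
    keep = np.setdiff1d(np.arange(bold.n_volumes), flagged)
    if len(keep) < 4:
        raise ValueError("cubic-spline scrubbing needs at least 4 unflagged volumes")
    data = bold.data.copy()
    series = data.reshape(-1, bold.n_volumes)
    cs = CubicSpline(keep, series[:, keep], axis=1)
    series[:, flagged] = cs(flagged)
    return bold.with_data(data), [int(i) for i in flagged]


def friston24(motion: MotionParams) -> np.ndarray:
    """Friston-24 expansion: the 6 rigid-body parameters, their one-lag
    copies (zero-padded first row), and both sets squared -> t x 24."""
    p = np.hstack([motion.translations_mm, motion.rotations_rad])
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lag, p**2, lag**2])


def _mask_mean(bold: Bold4D, mask: BrainMask) -> np.ndarray:
    check_same_grid(bold, mask)
    return bold.data[mask.include].mean(axis=0)


def build_confounds(
    bold: Bold4D,
    motion: MotionParams | None,
    cfg: PreprocConfig,
    global_mask: BrainMask | None = None,
    wm_mask: BrainMask | None = None,
    csf_mask: BrainMask | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the named confound matrix (no intercept; regress_nuisance
    adds it)."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    if motion is not None and cfg.confound_set != "none":
        if cfg.confound_set == "friston24":
            x = friston24(motion)
            names += [f"friston24_{i}" for i in range(24)]
        else:
            x = np.hstack([motion.translations_mm, motion.rotations_rad])
            names += [f"motion_{i}" for i in range(6)]
        cols.append(x)
    for flag, msk, nm in (
        (cfg.regress_global, global_mask, "global_signal"),
        (cfg.regress_wm, wm_mask, "wm_signal"),
        (cfg.regress_csf, csf_mask, "csf_signal"),
    ):
        if flag and msk is not None:
            cols.append(_mask_mean(bold, msk)[:, None])
            names.append(nm)
    if not cols:
        return np.empty((bold.n_volumes, 0)), []
    return np.hstack(cols), names


def regress_nuisance(
    bold: Bold4D, confounds: np.ndarray
) -> tuple[Bold4D, list[int]]:
    """Per-voxel least-squares residuals after regressing the confound
    columns (an intercept is always included).

    Rank-deficient designs keep going: numerically dependent columns are
    dropped and their indices (into the supplied matrix) returned so the
    manifest can record them. Residuals are orthogonal to the retained
    columns to ~1e-8.
    """
    confounds = np.atleast_2d(np.asarray(confounds, float))
    if confounds.size and confounds.shape[0] != bold.n_volumes:
        raise ValueError("confound rows do not match volume count")
    t = bold.n_volumes
    design = np.ones((t, 1))
    dropped: list[int] = []
    for j in range(confounds.shape[1] if confounds.size else 0):
        cand = np.hstack([design, confounds[:, j : j + 1]])
        if np.linalg.matrix_rank(cand, tol=1e-10) > design.shape[1]:
            design = cand
        else:
            dropped.append(j)
    series = bold.data.reshape(-1, t)
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    resid = (series.T - design @ beta).T
    return bold.with_data(resid.reshape(bold.data.shape)), dropped


def preprocess_session(
    bold: Bold4D,
    motion: MotionParams | None = None,
    cfg: PreprocConfig = PreprocConfig(),
    global_mask: BrainMask | None = None,
    wm_mask: BrainMask | None = None,
    csf_mask: BrainMask | None = None,
) -> tuple[Bold4D, dict]:
    """Run the full fixed-order chain on one session; returns the cleaned
    session and a manifest (parameters, flagged volumes, dropped columns,
    mean FD)."""
    manifest: dict = {
        "order": ["discard", "smooth", "bandpass", "nuisance", "scrub"],
        "n_discard": cfg.n_discard,
        "fwhm_mm": cfg.fwhm_mm,
        "band_hz": list(cfg.band_hz),
        "fd_threshold_mm": cfg.fd_threshold_mm,
        "confound_set": cfg.confound_set,
    }
    if cfg.n_discard:
        if motion is not None:
            bold, motion = discard_initial(bold, cfg.n_discard, motion)
        else:
            bold = discard_initial(bold, cfg.n_discard)
    bold = smooth_gaussian(bold, cfg.fwhm_mm)
    bold = bandpass(bold, *cfg.band_hz)
    confounds, names = build_confounds(
        bold, motion, cfg, global_mask, wm_mask, csf_mask
    )
    bold, dropped = regress_nuisance(bold, confounds)
    manifest["confound_names"] = names
    manifest["dropped_columns"] = [names[j] for j in dropped]
    if motion is not None:
        fd = framewise_displacement(motion, cfg.head_radius_mm)
        bold, flagged = scrub_interpolate(
            bold, fd, cfg.fd_threshold_mm, cfg.max_flagged_frac
        )
        manifest["mean_fd_mm"] = float(fd.mean())
        manifest["flagged_volumes"] = flagged
    else:
        manifest["mean_fd_mm"] = None
        manifest["flagged_volumes"] = []
    return bold, manifest
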