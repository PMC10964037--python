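"""Synthetic paired cohorts, molecular atlases and interaction graphs with
known ground truth.

The generators emulate the shape of a paired-design ECT study — pre/post
resting-state sessions for every subject, motion tables with displacement
spikes, HAMD/MMSE scores dropping after treatment, a parcels x genes
expression matrix, a set of named receptor density maps, and a gene
interaction edge list — while staying fully seeded and desk-scale.

Planted effects:

* entropy effect — post sessions mix a common narrow-band oscillation
  (default 0.03 Hz, inside the 0.01-0.1 Hz pass band so filtering preserves
  it) into the voxels of a compact ROI as the variance-preserving mixture
  sqrt(1-g) x + sqrt(g) sigma osc, so the weight g = `regularity_gain` is
  the fraction of signal variance carried by the oscillation and total
  variance is unchanged; more regularity means lower fuzzy entropy. The
  oscillation is shared across the ROI while the voxel noise is spatially
  independent, so spatial smoothing concentrates rather than dilutes the
  planted regularity — mirroring how coherent physiological signal survives
  smoothing in real data while thermal noise averages away.
* coupling effect — post sessions add one shared band-limited latent signal
  to a seed ROI and a target ROI with weight a = sqrt(dr / (1 - dr)) times
  the noise SD, which raises the voxel-to-seed correlation by ~dr.
* expression / receptor plantings — selected columns/maps are Gaussian
  mixtures with a reference profile at an analytically chosen weight so the
  expected Pearson (or, via the rank-to-normal copula, Spearman) correlation
  equals the requested target.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy import stats as sps

from .types import (
    Bold4D,
    BrainMask,
    ClinicalTable,
    ExpressionMatrix,
    MotionParams,
    ParcelAtlas,
    ScalarMap,
    VolumeGrid,
)

__all__ = [
    "BoxROI",
    "SynthConfig",
    "GroundTruth",
    "PairedCohort",
    "make_paired_cohort",
    "make_brain_mask",
    "make_parcel_atlas",
    "make_expression_matrix",
    "make_receptor_set",
    "make_ppi_edges",
    "make_map_cohort",
    "dice",
    "RECEPTOR_NAMES",
    "DEFAULT_PLANTED_GENES",
]

RECEPTOR_NAMES = (
    "5HT1a", "5HT1b", "5HT2a", "5HT4", "5HT6", "5HTT",
    "D1", "D2", "DAT", "NAT",
    "GABAa", "NMDA", "mGluR5",
    "M1", "A4B2", "VAChT",
    "H3", "CB1", "MOR",
)

# plausible symbols for planted expression columns (glucocorticoid receptor,
# MAP kinases, synaptic and immune signalling genes)
DEFAULT_PLANTED_GENES = (
    "NR3C1", "MAPK1", "MAPK3", "SNAP25", "PTPN11",
    "SYK", "HRAS", "NFKBIA", "HSP90AA1", "CYCS",
)


@dataclass(frozen=True)
class BoxROI:
    """Axis-aligned voxel box [lo, hi) on a grid."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def mask_array(self, dims: tuple[int, int, int]) -> np.ndarray:
        if any(l < 0 or h > d or l >= h for l, h, d in zip(self.lo, self.hi, dims)):
            raise ValueError(f"ROI {self} does not fit inside grid {dims}")
        out = np.zeros(dims, bool)
        out[self.lo[0]:self.hi[0], self.lo[1]:self.hi[1], self.lo[2]:self.hi[2]] = True
        return out

    @classmethod
    def centered(cls, dims, frac_center, size) -> "BoxROI":
        lo, hi = [], []
        for d, f, s in zip(dims, frac_center, size):
            c = int(round(f * d))
            lo.append(max(0, c - s // 2))
            hi.append(min(d, max(0, c - s // 2) + s))
        return cls(tuple(lo), tuple(hi))


def _frac_box(dims, spans) -> BoxROI:
    lo, hi = [], []
    for d, (a, b) in zip(dims, spans):
        l = int(round(a * d))
        h = max(l + 1, int(round(b * d)))
        lo.append(min(l, d - 1))
        hi.append(min(h, d))
    return BoxROI(tuple(lo), tuple(hi))


def _default_rois(dims):
    # entropy ROI in the low-x half, coupling seed/target in the high-x half
    # (disjoint by construction at any grid size)
    entropy = _frac_box(dims, ((0.15, 0.45), (0.33, 0.67), (0.35, 0.65)))
    seed = _frac_box(dims, ((0.55, 0.75), (0.17, 0.38), (0.35, 0.55)))
    target = _frac_box(dims, ((0.55, 0.75), (0.62, 0.83), (0.35, 0.55)))
    return entropy, seed, target


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the synthetic paired cohort.

    Defaults mirror the emulated study: 46 subjects, 217 volumes at
    TR 2.4 s, 3 mm voxels. The grid (20x24x20) is roughly 10x smaller than
    an MNI 3 mm bounding box to keep full-pipeline runs desk-scale; all
    downstream operations are grid-agnostic. Effect sizes
    (regularity_gain = 0.3, delta_r = 0.3) are stated choices — the emulated
    study reports none.
    """

    n_subjects: int = 46
    grid_dims: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: float = 3.0
    n_volumes: int = 217
    tr_s: float = 2.4
    # entropy effect
    entropy_roi: BoxROI | None = None
    regularity_gain: float = 0.3
    oscillation_hz: float = 0.03
    # coupling effect
    seed_roi: BoxROI | None = None
    target_roi: BoxROI | None = None
    delta_r: float = 0.3
    # noise model
    ar1_phi: float = 0.3
    sigma: float = 1.0
    n_slow_components: int = 3
    slow_amp: float = 0.05
    global_amp: float = 0.1
    # motion model: white positional jitter plus displacement spikes
    spike_prob: float = 0.05
    spike_amp_mm: float = 0.5
    jitter_sd_mm: float = 0.02
    jitter_sd_rad: float = 2e-4
    # clinical effect
    hamd_pre_mean: float = 25.0
    hamd_drop_mean: float = 15.0
    mmse_pre_mean: float = 27.0
    mmse_drop_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_volumes < 8:
            raise ValueError("need >= 1 subject and >= 8 volumes")
        if not (0 <= self.regularity_gain < 1):
            raise ValueError("regularity_gain must be in [0, 1)")
        if not (-1 < self.delta_r < 1):
            raise ValueError("delta_r must be in (-1, 1)")
        if not (0 <= self.ar1_phi < 1) or not self.sigma > 0:
            raise ValueError("need 0 <= ar1_phi < 1 and sigma > 0")

    def grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.grid_dims, self.voxel_mm)

    def rois(self) -> tuple[BoxROI, BoxROI, BoxROI]:
        ent, seed, tgt = _default_rois(self.grid_dims)
        ent = self.entropy_roi or ent
        seed = self.seed_roi or seed
        tgt = self.target_roi or tgt
        masks = [r.mask_array(self.grid_dims) for r in (ent, seed, tgt)]
        for i in range(3):
            for j in range(i + 1, 3):
                if (masks[i] & masks[j]).any():
                    raise ValueError(
                        "entropy/seed/target ROIs must be pairwise disjoint"
                    )
        return ent, seed, tgt


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    entropy_roi_mask: BrainMask
    seed_roi_mask: BrainMask
    target_roi_mask: BrainMask
    planted_genes: list[str] = field(default_factory=list)
    gene_rho_target: float = float("nan")
    planted_receptors: list[str] = field(default_factory=list)
    receptor_rho_target: float = float("nan")


@dataclass
class SubjectSessions:
    subject_id: str
    pre: Bold4D
    post: Bold4D
    motion_pre: MotionParams
    motion_post: MotionParams


@dataclass
class PairedCohort:
    subjects: list[SubjectSessions]
    clinical: ClinicalTable
    mask: BrainMask

    def __len__(self) -> int:
        return len(self.subjects)


def make_brain_mask(grid: VolumeGrid, fill: float = 0.9) -> BrainMask:
    """Ellipsoidal 'brain' filling `fill` of each grid extent."""
    dims = np.asarray(grid.dims)
    c = (dims - 1) / 2.0
    semi = np.maximum(1.0, fill * dims / 2.0)
    xx, yy, zz = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    r2 = sum(((g - ci) / si) ** 2 for g, ci, si in zip((xx, yy, zz), c, semi))
    return BrainMask(grid, r2 <= 1.0)


def _ar1(rng, shape_spatial, t, phi, sigma):
    e = rng.standard_normal((*shape_spatial, t)) * sigma
    if phi == 0:
        return e
    x = signal.lfilter([1.0], [1.0, -phi], e, axis=-1)
    # start the recursion at stationarity
    x[..., 0] = e[..., 0] / np.sqrt(1.0 - phi**2)
    return x


def _band_limited(rng, t, tr_s, lo=0.01, hi=0.1):
    """Unit-variance band-limited noise (survives the analysis band-pass)."""
    nyq = 0.5 / tr_s
    hi = min(hi, 0.95 * nyq)
    sos = signal.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    z = signal.sosfiltfilt(sos, rng.standard_normal(t + 200))[100:-100]
    return (z - z.mean()) / z.std()


def _session_noise(rng, cfg: SynthConfig, comps_spatial, comps_time):
    x = _ar1(rng, cfg.grid_dims, cfg.n_volumes, cfg.ar1_phi, cfg.sigma)
    for sp, tc in zip(comps_spatial, comps_time):
        x += sp[..., None] * tc[None, None, None, :]
    # spatially uniform physiological fluctuation: dominates the global mean
    # (so global-signal regression removes it, not focal effects)
    if cfg.global_amp > 0:
        g0 = _band_limited(rng, cfg.n_volumes, cfg.tr_s)
        x += cfg.global_amp * cfg.sigma * g0[None, None, None, :]
    return x


def _motion(rng, cfg: SynthConfig) -> MotionParams:
    """White positional jitter with occasional one-volume displacement
    spikes. Slow drift is deliberately absent: at demo series lengths the
    Friston-24 expansion of drifting motion would span much of the 0.01-0.1
    Hz band and regress out any in-band signal — a short-series artifact,
    not a property of full-length acquisitions."""
    t = cfg.n_volumes
    trans = rng.normal(0, cfg.jitter_sd_mm, (t, 3))
    rot = rng.normal(0, cfg.jitter_sd_rad, (t, 3))
    spikes = rng.random(t) < cfg.spike_prob
    spikes[0] = False
    for i in np.flatnonzero(spikes):
        trans[i, rng.integers(3)] += cfg.spike_amp_mm * rng.choice([-1.0, 1.0])
    return MotionParams(trans, rot)


def make_paired_cohort(cfg: SynthConfig) -> tuple[PairedCohort, GroundTruth]:
    """Generate the paired pre/post cohort with planted entropy and coupling
    effects (post sessions only) plus motion tables and clinical scores."""
    grid = cfg.grid()
    mask = make_brain_mask(grid)
    ent_roi, seed_roi, tgt_roi = cfg.rois()
    ent_m = ent_roi.mask_array(cfg.grid_dims)
    seed_m = seed_roi.mask_array(cfg.grid_dims)
    tgt_m = tgt_roi.mask_array(cfg.grid_dims)

    root = np.random.SeedSequence(cfg.seed)
    sub_seeds = root.spawn(cfg.n_subjects)
    clin_rng = np.random.default_rng(root.spawn(1)[0])

    ar_sd = cfg.sigma / np.sqrt(1.0 - cfg.ar1_phi**2)
    a_couple = np.sqrt(abs(cfg.delta_r) / (1.0 - abs(cfg.delta_r))) * ar_sd
    a_couple *= np.sign(cfg.delta_r) if cfg.delta_r != 0 else 0.0
    g = cfg.regularity_gain
    tt = np.arange(cfg.n_volumes) * cfg.tr_s

    subjects = []
    for s, ss in enumerate(sub_seeds):
        rng = np.random.default_rng(ss)
        sid = f"sub-{s + 1:03d}"
        # spatially smooth slow components (band-limited noise time courses)
        # shared by the subject's two sessions
        comps_spatial, comps_time = [], []
        for _ in range(cfg.n_slow_components):
            sp = ndimage.gaussian_filter(
                rng.standard_normal(cfg.grid_dims), 2.0, mode="constant"
            )
            sp = cfg.slow_amp * cfg.sigma * sp / sp.std()
            comps_spatial.append(sp)
            comps_time.append(_band_limited(rng, cfg.n_volumes, cfg.tr_s))
        pre_data = _session_noise(rng, cfg, comps_spatial, comps_time)
        post_data = _session_noise(rng, cfg, comps_spatial, comps_time)
        if g > 0:
            osc = np.sqrt(2.0) * np.sin(
                2 * np.pi * cfg.oscillation_hz * tt + rng.uniform(0, 2 * np.pi)
            )
            post_data[ent_m] = (
                np.sqrt(1.0 - g) * post_data[ent_m]
                + np.sqrt(g) * ar_sd * osc[None, :]
            )
        if cfg.delta_r != 0:
            z = _band_limited(rng, cfg.n_volumes, cfg.tr_s)
            post_data[seed_m] += a_couple * z[None, :]
            post_data[tgt_m] += a_couple * z[None, :]
        subjects.append(
            SubjectSessions(
                sid,
                Bold4D(grid, pre_data, cfg.tr_s, sid, "pre"),
                Bold4D(grid, post_data, cfg.tr_s, sid, "post"),
                _motion(rng, cfg),
                _motion(rng, cfg),
            )
        )

    hamd_pre = np.clip(clin_rng.normal(cfg.hamd_pre_mean, 4.0, cfg.n_subjects), 8, 52)
    hamd_post = np.clip(
        hamd_pre - clin_rng.normal(cfg.hamd_drop_mean, 3.0, cfg.n_subjects), 0, 52
    )
    mmse_pre = np.clip(clin_rng.normal(cfg.mmse_pre_mean, 1.5, cfg.n_subjects), 10, 30)
    mmse_post = np.clip(
        mmse_pre - clin_rng.normal(cfg.mmse_drop_mean, 1.0, cfg.n_subjects), 0, 30
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "hamd_pre": np.round(hamd_pre),
                "hamd_post": np.round(hamd_post),
                "mmse_pre": np.round(mmse_pre),
                "mmse_post": np.round(mmse_post),
            }
        )
    )
    gt = GroundTruth(
        BrainMask(grid, ent_m), BrainMask(grid, seed_m), BrainMask(grid, tgt_m)
    )
    return PairedCohort(subjects, clinical, mask), gt


def make_parcel_atlas(
    grid: VolumeGrid, mask: BrainMask, n_parcels: int = 100, seed: int = 0
) -> ParcelAtlas:
    """Voronoi parcellation of the mask around random in-mask seed voxels
    (labels 1..n_parcels); hemispheres derived from parcel centroids."""
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask.include)
    if n_parcels > len(coords):
        raise ValueError("more parcels than in-mask voxels")
    centers = coords[rng.choice(len(coords), n_parcels, replace=False)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    labels = np.zeros(grid.dims, dtype=np.int32)
    labels[tuple(coords.T)] = nearest + 1
    return ParcelAtlas(grid, labels)


def make_expression_matrix(
    reference_profile,
    n_genes: int = 1000,
    n_planted: int = 10,
    rho_target: float = 0.6,
    seed: int = 0,
    planted_symbols=None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Parcels x genes matrix in which `n_planted` columns correlate with the
    reference profile at expected Pearson r = rho_target; the rest are
    independent noise.

    With rho_target = +-1 the planted columns are exact affine transforms of
    the profile (sample r = +-1).
    """
    ref = np.asarray(
        reference_profile.values
        if hasattr(reference_profile, "values")
        else reference_profile,
        float,
    )
    ref = ref[np.isfinite(ref)]
    if ref.size < 10:
        raise ValueError("reference profile needs >= 10 defined parcels")
    if not (0 <= n_planted <= n_genes):
        raise ValueError("need 0 <= n_planted <= n_genes")
    if abs(rho_target) > 1:
        raise ValueError("|rho_target| must be <= 1")
    if ref.std() == 0:
        raise ValueError("reference profile is constant")
    rng = np.random.default_rng(seed)
    z = (ref - ref.mean()) / ref.std()
    P = ref.size
    X = rng.standard_normal((P, n_genes))
    for j in range(n_planted):
        eps = rng.standard_normal(P)
        eps = (eps - eps.mean()) / eps.std()
        X[:, j] = rho_target * z + np.sqrt(1.0 - rho_target**2) * eps
    if planted_symbols is None:
        planted_symbols = list(DEFAULT_PLANTED_GENES)
    if n_planted > len(planted_symbols):
        planted_symbols = list(planted_symbols) + [
            f"PLANTED{j:04d}" for j in range(len(planted_symbols), n_planted)
        ]
    planted = list(planted_symbols[:n_planted])
    symbols = planted + [f"GENE{j:05d}" for j in range(n_genes - n_planted)]
    parcel_ids = getattr(reference_profile, "parcel_ids", None) or list(
        range(1, P + 1)
    )
    return ExpressionMatrix(list(parcel_ids)[:P], symbols, X), planted


def make_receptor_set(
    reference_map: ScalarMap,
    mask: BrainMask,
    names=RECEPTOR_NAMES,
    planted=(),
    rho_target: float = 0.7,
    seed: int = 0,
    smooth_sigma_vox: float = 1.5,
) -> dict[str, ScalarMap]:
    """Named receptor density maps on the reference grid; `planted` names get
    expected Spearman rho = rho_target with the reference map (Gaussian
    copula: Pearson weight 2 sin(pi rho / 6) on normal scores), the rest are
    independent smooth fields. rho_target = +-1 uses an exact monotone
    transform of the reference.
    """
    planted = list(planted)
    if len(planted) > len(names):
        raise ValueError("names list shorter than planted list")
    unknown = set(planted) - set(names)
    if unknown:
        raise ValueError(f"planted names not in names: {sorted(unknown)}")
    if abs(rho_target) > 1:
        raise ValueError("|rho_target| must be <= 1")
    grid = reference_map.grid
    inc = mask.include
    ref = reference_map.values[inc]
    if not np.isfinite(ref).all():
        raise ValueError("reference map must be defined on the whole mask")
    # rank -> normal scores of the reference, for copula mixing
    zref = sps.norm.ppf((sps.rankdata(ref) - 0.5) / ref.size)
    rho_p = 2.0 * np.sin(np.pi * rho_target / 6.0)
    rng = np.random.default_rng(seed)
    out: dict[str, ScalarMap] = {}
    for name in names:
        vals = np.full(grid.dims, np.nan)
        if name in planted:
            if abs(rho_target) == 1.0:
                y = np.sign(rho_target) * np.exp(0.5 * zref)  # monotone
            else:
                eps = rng.standard_normal(ref.size)
                y = rho_p * zref + np.sqrt(1.0 - rho_p**2) * eps
        else:
            f = ndimage.gaussian_filter(
                rng.standard_normal(grid.dims), smooth_sigma_vox, mode="constant"
            )[inc]
            y = (f - f.mean()) / f.std()
        vals[inc] = y
        out[name] = ScalarMap(grid, vals, "density")
    return out


def make_ppi_edges(
    gene_symbols,
    hub_spec: dict[str, int],
    seed: int = 0,
    background_p: float = 0.01,
    confidence_range: tuple[float, float] = (0.9, 0.99),
) -> pd.DataFrame:
    """Undirected edge list (gene_a, gene_b, confidence) whose designated
    hubs end up with degrees above mean + 1 SD of the degree sequence."""
    genes = list(gene_symbols)
    n = len(genes)
    for h, deg in hub_spec.items():
        if h not in genes:
            raise ValueError(f"hub {h!r} not in gene list")
        if deg >= n:
            raise ValueError(f"requested degree {deg} >= n_genes {n}")
    rng = np.random.default_rng(seed)
    edges: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < background_p:
                edges.add(tuple(sorted((genes[i], genes[j]))))
    deg_of = {g: 0 for g in genes}
    for a, b in edges:
        deg_of[a] += 1
        deg_of[b] += 1
    for h, target in hub_spec.items():
        others = [g for g in genes if g != h]
        rng.shuffle(others)
        for o in others:
            if deg_of[h] >= target:
                break
            e = tuple(sorted((h, o)))
            if e not in edges:
                edges.add(e)
                deg_of[e[0]] += 1
                deg_of[e[1]] += 1
    rows = sorted(edges)
    conf = rng.uniform(*confidence_range, len(rows))
    df = pd.DataFrame(
        {"gene_a": [a for a, _ in rows], "gene_b": [b for _, b in rows],
         "confidence": conf}
    )
    d = np.array([deg_of[g] for g in genes], float)
    cut = d.mean() + d.std()
    low = [h for h in hub_spec if deg_of[h] <= cut]
    if low:
        raise ValueError(f"hub degrees not above mean + 1 SD: {low}")
    return df


def make_map_cohort(
    mask: BrainMask,
    n_subjects: int = 20,
    effect: ScalarMap | None = None,
    effect_scale: float = 1.0,
    noise_sd: float = 1.0,
    smooth_sigma_vox: float = 1.0,
    seed: int = 0,
) -> tuple[list[ScalarMap], list[ScalarMap]]:
    """Per-subject pre/post scalar-map pairs: independent smooth noise
    fields, plus `effect_scale * effect` added to every post map. A light
    stand-in for a full cohort when only map-level statistics are under
    test."""
    rng = np.random.default_rng(seed)
    grid = mask.grid
    pre, post = [], []
    for _ in range(n_subjects):
        maps = []
        for _s in range(2):
            f = ndimage.gaussian_filter(
                rng.standard_normal(grid.dims), smooth_sigma_vox, mode="constant"
            )
            f = noise_sd * f / f[mask.include].std()
            v = np.full(grid.dims, np.nan)
            v[mask.include] = f[mask.include]
            maps.append(v)
        if effect is not None:
            maps[1][mask.include] += effect_scale * effect.values[mask.include]
        pre.append(ScalarMap(grid, maps[0], "ben"))
        post.append(ScalarMap(grid, maps[1], "ben"))
    return pre, post


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks; 0 when either is empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    if s == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / s)
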