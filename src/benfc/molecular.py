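"""Spatial association of statistical maps with molecular atlases.

Covers: parcel-mean profiles of a t-map, per-gene spatial Pearson
correlation against an expression matrix with BH-FDR, the |r| >= 0.15 gene
selection, hub genes on a confidence-filtered interaction graph
(degree > mean + 1 SD), atlas ranking of a gene's regional expression, and
Spearman correlation of t-maps with receptor density maps assessed by a
paired-label permutation null (within-subject pre/post exchange, i.e. sign
flips of the paired differences) with Bonferroni correction over the map
family.

No spatial-autocorrelation-preserving ("spin") null is implemented; the
permutation scheme here exchanges pre/post labels, matching the paired
t-statistic it wraps. A callable hook on `receptor_permutation_test` allows
plugging an alternative null later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import fdr_bh
from .types import ParcelAtlas, ParcelProfile, ScalarMap, check_same_grid

__all__ = [
    "parcel_profile",
    "gene_map_correlation",
    "select_associated_genes",
    "hub_genes",
    "rank_regions_by_expression",
    "receptor_spearman",
    "PermutationResult",
    "receptor_permutation_test",
]


def parcel_profile(
    m: ScalarMap, atlas: ParcelAtlas, hemisphere_filter: str = "both"
) -> ParcelProfile:
    """Unweighted mean of defined voxels per retained parcel.

    Parcels with no defined voxel get NaN and are excluded downstream;
    raises if the hemisphere filter retains nothing.
    """
    check_same_grid(m, atlas)
    keep = atlas.parcels_in(hemisphere_filter)
    if not keep:
        raise ValueError(f"no parcels retained for filter {hemisphere_filter!r}")
    vals = np.empty(len(keep))
    nvox = np.empty(len(keep), dtype=int)
    for i, pid in enumerate(keep):
        v = m.values[atlas.labels == pid]
        v = v[np.isfinite(v)]
        nvox[i] = v.size
        vals[i] = v.mean() if v.size else np.nan
    return ParcelProfile(keep, vals, nvox)


def _align(expr_parcels: list[int], profile: ParcelProfile) -> tuple[np.ndarray, np.ndarray]:
    """Inner join on parcel id, dropping undefined profile parcels."""
    pv = dict(zip(profile.parcel_ids, profile.values))
    rows, y = [], []
    for i, pid in enumerate(expr_parcels):
        if pid in pv and np.isfinite(pv[pid]):
            rows.append(i)
            y.append(pv[pid])
    return np.asarray(rows, int), np.asarray(y, float)


def gene_map_correlation(expr, profile: ParcelProfile, q: float = 0.05) -> pd.DataFrame:
    """Per-gene spatial Pearson correlation of expression with a parcel
    profile; columns gene, r, p, q (BH-FDR across all tested genes).

    Requires >= 10 shared defined parcels; constant expression columns are
    excluded with a warning (their r is undefined).
    """
    rows, y = _align(expr.parcel_ids, profile)
    if rows.size < 10:
        raise ValueError(f"only {rows.size} shared parcels (< 10)")
    X = expr.values[rows]
    yc = y - y.mean()
    ysd = yc.std()
    if ysd == 0:
        raise ValueError("profile is constant over shared parcels")
    Xc = X - X.mean(axis=0)
    xsd = Xc.std(axis=0)
    const = xsd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant expression column(s) excluded",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (rows.size * xsd * ysd)
    r = np.clip(r, -1.0, 1.0)
    n = rows.size
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = np.finfo(float).tiny  # exact fit: p underflows
    out = pd.DataFrame({"gene": expr.gene_symbols, "r": r, "p": p})
    out = out[~const].reset_index(drop=True)
    _, out["q"] = fdr_bh(out["p"].to_numpy(), q)
    return out


def select_associated_genes(
    assocs: pd.DataFrame, r_min: float = 0.15, require_q: bool = True, q: float = 0.05
) -> list[str]:
    """Genes with |r| >= r_min (boundary inclusive) and, optionally,
    FDR q < 0.05."""
    if assocs.empty:
        return []
    keep = assocs["r"].abs() >= r_min
    if require_q:
        keep &= assocs["q"] < q
    return assocs.loc[keep, "gene"].tolist()


def hub_genes(
    edges: pd.DataFrame,
    confidence_min: float = 0.9,
    nodes: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Degree table and hub list on the confidence-filtered undirected graph.

    Hubs have degree strictly greater than mean + 1 population SD over all
    nodes; an optional node list adds isolated (degree-0) genes to the
    denominator.
    """
    kept = edges[edges["confidence"] >= confidence_min]
    if kept.empty:
        raise ValueError(f"no edges at confidence >= {confidence_min}")
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(zip(kept["gene_a"], kept["gene_b"]))
    deg = pd.DataFrame(
        sorted(g.degree(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "degree"],
    )
    d = deg["degree"].to_numpy(float)
    cutoff = d.mean() + d.std()  # population SD
    hubs = deg.loc[deg["degree"] > cutoff, "gene"].tolist()
    return deg, hubs


def rank_regions_by_expression(expr, gene_symbol: str, k: int = 10) -> pd.DataFrame:
    """Top-k parcels by descending mean expression of one gene; ties break
    toward the lower parcel id. k beyond the parcel count returns the full
    ranking."""
    col = expr.column(gene_symbol)  # raises KeyError for unknown genes
    df = pd.DataFrame({"parcel_id": expr.parcel_ids, "expression": col})
    df = df.sort_values(
        ["expression", "parcel_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df.head(min(k, len(df)))


def receptor_spearman(a, b) -> float:
    """Spearman rho with average-rank ties over shared defined entries of
    two profiles/vectors (>= 10 required)."""
    av = a.values if isinstance(a, ParcelProfile) else np.asarray(a, float)
    bv = b.values if isinstance(b, ParcelProfile) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError("inputs differ in length")
    ok = np.isfinite(av) & np.isfinite(bv)
    if ok.sum() < 10:
        raise ValueError(f"only {int(ok.sum())} shared defined locations (< 10)")
    if av[ok].std() == 0 or bv[ok].std() == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho, _ = sps.spearmanr(av[ok], bv[ok])
    return float(rho)


@dataclass
class PermutationResult:
    """One receptor map's observed Spearman rho against the paired t-map,
    its permutation null draws, and raw/Bonferroni p."""

    map_name: str
    observed_rho: float
    null_rhos: np.ndarray
    p_raw: float
    p_bonferroni: float
    B: int
    seed: int


def _paired_t_from_signs(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t-vectors for many sign assignments at once.

    d is (n_subjects, n_units); signs is (B, n_subjects) of +-1. Flipping a
    subject's pre/post labels negates its difference, leaving sum(d^2)
    untouched, so every permuted t-map is a closed form of signs @ d.
    """
    n = d.shape[0]
    mean = signs @ d / n
    ssq = (d * d).sum(axis=0)
    var = np.maximum(0.0, (ssq - n * mean**2) / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    return t


def _spearman_many(T: np.ndarray, ref_rank: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of T against a pre-ranked reference."""
    R = sps.rankdata(T, axis=1)
    Rc = R - R.mean(axis=1, keepdims=True)
    rc = ref_rank - ref_rank.mean()
    denom = np.sqrt((Rc**2).sum(axis=1) * (rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Rc @ rc) / denom


def receptor_permutation_test(
    maps_pre,
    maps_post,
    receptor_maps: dict[str, ScalarMap],
    atlas: ParcelAtlas | None = None,
    mask=None,
    B: int = 5000,
    seed: int = 0,
    hemisphere_filter: str = "both",
    chunk: int = 500,
) -> list[PermutationResult]:
    """Spearman association of the paired (post - pre) t-map with each
    receptor map, with a within-subject label-permutation null.

    Each null draw independently relabels every subject's two sessions
    (equivalently flips the sign of that subject's difference map), rebuilds
    the paired t-map and its Spearman rho with the receptor map.
    p_raw = (1 + #{|null| >= |observed|}) / (B + 1); Bonferroni multiplies
    by the number of maps tested. With an atlas, correlations run on parcel
    profiles (default spatial unit); otherwise voxel-wise over `mask`.
    """
    if len(maps_pre) != len(maps_post):
        raise ValueError("unpaired inputs: pre/post lists differ in length")
    if not receptor_maps:
        raise ValueError("receptor map set is empty")
    if B < 100:
        warnings.warn("B < 100 permutations gives a coarse p-value", stacklevel=2)
    n = len(maps_pre)
    grid = check_same_grid(*maps_pre, *maps_post, *receptor_maps.values())

    if atlas is not None:
        check_same_grid(maps_pre[0], atlas)
        labels = atlas.labels
        keep = atlas.parcels_in(hemisphere_filter)
        unit_of_voxel = np.searchsorted(np.asarray(keep), labels)
        in_unit = np.isin(labels, keep)
        K = len(keep)
    else:
        in_unit = mask.include if mask is not None else np.ones(grid.dims, bool)
        K = None

    pre = np.stack([m.values for m in maps_pre])
    post = np.stack([m.values for m in maps_post])
    d_vox = (post - pre)[:, in_unit]  # (n, V)
    ok_vox = np.isfinite(d_vox).all(axis=0)
    d_vox = d_vox[:, ok_vox]

    if atlas is not None:
        # voxel -> parcel averaging matrix applied after the t-map
        uidx = unit_of_voxel[in_unit][ok_vox]
        counts = np.bincount(uidx, minlength=K).astype(float)
        def to_units(tv):  # (B, V) -> (B, K), NaN for empty parcels
            sums = np.stack([np.bincount(uidx, w, minlength=K) for w in tv])
            with np.errstate(invalid="ignore", divide="ignore"):
                out = sums / counts
            out[:, counts == 0] = np.nan
            return out
    else:
        def to_units(tv):
            return tv

    obs_t = _paired_t_from_signs(d_vox, np.ones((1, n)))
    obs_units = to_units(obs_t)[0]
    defined = np.isfinite(obs_units)
    if defined.sum() < 10:
        raise ValueError("fewer than 10 defined spatial units")

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(B, n))

    results = []
    K_maps = len(receptor_maps)
    for name, rmap in receptor_maps.items():
        if atlas is not None:
            rprof = parcel_profile(rmap, atlas, hemisphere_filter).values
        else:
            rprof = rmap.values[in_unit][ok_vox]
        ok = defined & np.isfinite(rprof)
        ref_rank = sps.rankdata(rprof[ok])
        observed = receptor_spearman(obs_units[ok], rprof[ok])
        null = np.empty(B)
        for start in range(0, B, chunk):
            s = signs[start : start + chunk]
            tv = _paired_t_from_signs(d_vox, s)
            units = to_units(tv)[:, ok]
            null[start : start + len(s)] = _spearman_many(units, ref_rank)
        p_raw = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (B + 1.0)
        results.append(
            PermutationResult(
                name, observed, null, float(p_raw),
                float(min(1.0, K_maps * p_raw)), B, seed,
            )
        )
    return results
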