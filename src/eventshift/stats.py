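"""Permutation inference for anticipation maps.

Null datasets are built by independently shuffling each subject's viewing
order, which destroys any systematic first-vs-repeated asymmetry while
preserving everything else about the data.  The full searchlight pipeline
(including alignment) is re-run per null replicate.  Voxelwise one-tailed
p-values come from a normal fit to the null values, followed by
Benjamini-Hochberg FDR control; a Spearman test against a spatial axis
(posterior-to-anterior by default) probes for a gradient of anticipation
timescales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pipeline import (
    AnticipationMap,
    Searchlight,
    aggregate_voxel_map,
    searchlight_anticipation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "permuted_viewing_orders",
    "run_null_pipeline",
    "normal_fit_pvalue",
    "normal_fit_pvalue_map",
    "bh_fdr",
    "axis_gradient_test",
    "attach_significance",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class NullEnsemble:
    """Real and permuted-viewing-order results of the searchlight pipeline."""

    real_values: np.ndarray  # per-searchlight anticipation (s)
    null_values: np.ndarray  # (n_null, n_searchlights)
    real_map: AnticipationMap
    null_maps: np.ndarray  # (n_null, x, y, z)
    permutations: np.ndarray  # (n_null, n_subjects, n_viewings)
    searchlights: list
    seed: int | None = None


def permuted_viewing_orders(
    n_subjects: int, n_viewings: int, n_null: int = 99, seed: int = 0
) -> np.ndarray:
    """Independent uniform viewing-order permutations per subject per replicate."""
    rng = np.random.default_rng(seed)
    table = np.empty((n_null, n_subjects, n_viewings), dtype=int)
    for r in range(n_null):
        for s in range(n_subjects):
            table[r, s] = rng.permutation(n_viewings)
    return table


def run_null_pipeline(
    bold: Sequence[Sequence[np.ndarray]],
    searchlights: Sequence[Searchlight],
    permutations: np.ndarray,
    volume_shape: tuple[int, int, int] | None = None,
    seed: int | None = None,
    **pipeline_kwargs,
) -> NullEnsemble:
    """Run the searchlight pipeline once on the real data and once per null.

    Each null replicate relabels every subject's viewings according to the
    permutation table before alignment and model fitting, so the null
    preserves all within-viewing structure.
    """
    if volume_shape is None:
        volume_shape = bold[0][0].shape[:3]
    real_values = searchlight_anticipation(bold, searchlights, **pipeline_kwargs)
    real_map = aggregate_voxel_map(real_values, searchlights, volume_shape)

    n_null = permutations.shape[0]
    null_values = np.full((n_null, len(searchlights)), np.nan)
    null_maps = np.full((n_null,) + tuple(volume_shape), np.nan)
    for r in range(n_null):
        permuted = [
            [bold[s][v] for v in permutations[r, s]] for s in range(len(bold))
        ]
        try:
            vals = searchlight_anticipation(permuted, searchlights, **pipeline_kwargs)
        except Exception as exc:  # noqa: BLE001 - drop the replicate, keep the run
            logger.warning("null replicate %d failed (%s); dropped", r, exc)
            continue
        null_values[r] = vals
        null_maps[r] = aggregate_voxel_map(vals, searchlights, volume_shape).values
    return NullEnsemble(
        real_values,
        null_values,
        real_map,
        null_maps,
        permutations,
        list(searchlights),
        seed,
    )


def normal_fit_pvalue(real: float, nulls: Sequence[float]) -> float:
    """One-tailed p from a normal fit to the null values: P(null > real)."""
    nulls = np.asarray(nulls, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size < 2:
        raise ValueError("need at least two finite null values")
    mu = nulls.mean()
    sd = nulls.std(ddof=1)
    if sd == 0:
        logger.warning("normal_fit_pvalue: zero null variance")
        return 0.0 if real > mu else 1.0
    return float(sps.norm.sf((real - mu) / sd))


def normal_fit_pvalue_map(
    real_map: np.ndarray, null_stack: np.ndarray
) -> np.ndarray:
    """Voxelwise one-tailed normal-fit p-values (NaN where undefined)."""
    real = np.asarray(real_map, dtype=float)
    nulls = np.asarray(null_stack, dtype=float)
    n_fin = np.isfinite(nulls).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(nulls, axis=0)
        sd = np.nanstd(nulls, axis=0, ddof=1)
    p = np.full(real.shape, np.nan)
    ok = np.isfinite(real) & (n_fin >= 2) & (sd > 0)
    p[ok] = sps.norm.sf((real[ok] - mu[ok]) / sd[ok])
    degen = np.isfinite(real) & (n_fin >= 2) & (sd == 0)
    if degen.any():
        logger.warning("normal_fit_pvalue_map: %d voxels with zero null variance", degen.sum())
        p[degen] = np.where(real[degen] > mu[degen], 0.0, 1.0)
    return p


def bh_fdr(
    p: np.ndarray, q_threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the FDR.

    NaN entries are excluded from the family.  Returns the significance mask
    (False where NaN) and monotone-adjusted q-values (NaN preserved).
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    finite = np.isfinite(flat)
    sig = np.zeros(flat.size, dtype=bool)
    q = np.full(flat.size, np.nan)
    if finite.any():
        rej, qv, _, _ = multipletests(
            flat[finite], alpha=q_threshold, method="fdr_bh"
        )
        sig[finite] = rej
        q[finite] = qv
    return sig.reshape(p.shape), q.reshape(p.shape)


def axis_gradient_test(
    amap: AnticipationMap,
    axis: str = "y",
    voxel_set: str = "significant",
    null_maps: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    q_threshold: float = 0.05,
) -> tuple[float, float]:
    """Spearman correlation of anticipation with position along a spatial axis.

    ``voxel_set`` selects either all voxels with coverage ('all_covered') or
    only those significant after FDR ('significant'; requires ``amap.q``).
    The permutation p-value compares the observed correlation to the same
    correlation computed on each null map over the identical voxel set, with
    add-one smoothing.  Coordinates are world-space (via ``affine``) so the
    axis has an anatomical meaning; with no affine, voxel indices are used.
    """
    ax = _AXES[axis]
    values = amap.values
    sel = np.isfinite(values)
    if voxel_set == "significant":
        if amap.q is None:
            raise ValueError("voxel_set='significant' requires q-values on the map")
        sel &= np.nan_to_num(amap.q, nan=1.0) < q_threshold
    elif voxel_set != "all_covered":
        raise ValueError(f"unknown voxel_set {voxel_set!r}")
    idx = np.argwhere(sel)
    if idx.shape[0] < 3:
        raise ValueError(f"fewer than 3 voxels in voxel_set {voxel_set!r}")
    if affine is not None:
        homog = np.c_[idx, np.ones(idx.shape[0])]
        coords = (homog @ np.asarray(affine).T)[:, ax]
    else:
        coords = idx[:, ax].astype(float)
    obs = values[sel]
    rho = float(sps.spearmanr(coords, obs).statistic)
    if null_maps is None:
        return rho, float("nan")
    null_rhos = []
    for nm in np.asarray(null_maps):
        nv = nm[sel]
        fin = np.isfinite(nv)
        if fin.sum() < 3:
            continue
        null_rhos.append(sps.spearmanr(coords[fin], nv[fin]).statistic)
    null_rhos = np.asarray(null_rhos, dtype=float)
    p = (1.0 + np.sum(null_rhos >= rho)) / (1.0 + null_rhos.size)
    return rho, float(p)


def attach_significance(ens: NullEnsemble, q_threshold: float = 0.05) -> AnticipationMap:
    """Fill voxelwise p and q maps into the ensemble's real map and return it."""
    p = normal_fit_pvalue_map(ens.real_map.values, ens.null_maps)
    _, q = bh_fdr(p, q_threshold)
    ens.real_map.p = p
    ens.real_map.q = q
    return ens.real_map
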