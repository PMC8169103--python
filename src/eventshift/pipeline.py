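"""Whole-volume orchestration of the anticipation analysis.

Spherical searchlights are tiled on a regular grid over the brain mask; in
each searchlight all valid subjects are hyperaligned into a shared
low-dimensional space (jointly over viewings), averaged, and the shared
response of every viewing is fed to the ordered-event HMM.  The upward
shift of the repeated-viewing expected-event curves relative to the first
viewing, expressed in seconds, is the searchlight's anticipation; voxel
maps are the mean over covering searchlights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boundaries import BoundaryTimecourse, LagEstimate, optimal_lag
from .hmm import (
    ExpectedEventCurve,
    ViewingSeries,
    expected_event_curve,
    fit_event_model,
    select_n_events,
)
from .srm import fit_srm, group_shared_response

logger = logging.getLogger(__name__)

__all__ = [
    "Searchlight",
    "AnticipationMap",
    "sphere_offsets",
    "build_searchlights",
    "anticipation_seconds",
    "searchlight_anticipation",
    "aggregate_voxel_map",
    "crosscorr_baseline",
    "timescale_map",
]


@dataclass
class Searchlight:
    """A sphere of in-mask voxels around a grid center."""

    center: tuple[int, int, int]
    voxel_ids: np.ndarray  # (n, 3) integer voxel indices
    valid_subjects: np.ndarray  # indices of subjects with valid data here

    @property
    def n_voxels(self) -> int:
        return self.voxel_ids.shape[0]

    @property
    def n_valid_subjects(self) -> int:
        return len(self.valid_subjects)


@dataclass
class AnticipationMap:
    """Voxelwise anticipation in seconds with optional inference maps."""

    values: np.ndarray  # 3D, seconds; NaN outside searchlight coverage
    n_covering: np.ndarray  # 3D int, searchlights covering each voxel
    p: np.ndarray | None = None
    q: np.ndarray | None = None


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius (inclusive)."""
    r = int(radius)
    g = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r * r
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def build_searchlights(
    mask: np.ndarray,
    radius: int = 5,
    stride: int = 5,
    min_voxels: int = 20,
    subject_validity: Sequence[np.ndarray] | None = None,
    min_subjects: int = 1,
) -> list[Searchlight]:
    """Tile spherical searchlights on a regular grid over the mask.

    Centers lie on a grid with the given stride anchored at the mask
    bounding-box minimum corner.  A subject counts as valid for a
    searchlight only if every voxel of the searchlight is valid (nonzero
    variance in every viewing) for that subject.  Searchlights with fewer
    than ``min_voxels`` in-mask voxels or fewer than ``min_subjects`` valid
    subjects are dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius < 0 or stride < 1:
        raise ValueError("radius must be >= 0 and stride >= 1")
    if not mask.any():
        raise ValueError("empty mask")
    nz = np.argwhere(mask)
    lo = nz.min(axis=0)
    hi = nz.max(axis=0)
    offsets = sphere_offsets(radius)

    centers = [
        (x, y, z)
        for x in range(lo[0], hi[0] + 1, stride)
        for y in range(lo[1], hi[1] + 1, stride)
        for z in range(lo[2], hi[2] + 1, stride)
    ]
    n_small = n_invalid = 0
    out: list[Searchlight] = []
    for c in centers:
        vox = offsets + np.asarray(c)
        in_bounds = np.all((vox >= 0) & (vox < mask.shape), axis=1)
        vox = vox[in_bounds]
        vox = vox[mask[vox[:, 0], vox[:, 1], vox[:, 2]]]
        if vox.shape[0] < min_voxels:
            n_small += 1
            continue
        if subject_validity is None:
            valid = None  # caller uses all subjects
        else:
            valid = np.array(
                [
                    i
                    for i, sv in enumerate(subject_validity)
                    if bool(sv[vox[:, 0], vox[:, 1], vox[:, 2]].all())
                ],
                dtype=int,
            )
            if len(valid) < min_subjects:
                n_invalid += 1
                continue
        out.append(
            Searchlight(tuple(int(v) for v in c), vox, valid)
        )
    if not out:
        raise ValueError(
            f"no searchlights retained: {n_small} dropped by min_voxels="
            f"{min_voxels}, {n_invalid} dropped by min_subjects={min_subjects}"
        )
    return out


def anticipation_seconds(
    curves: Sequence[ExpectedEventCurve], mode: str = "first_vs_rest"
) -> float:
    """Anticipation in seconds from per-viewing expected-event curves.

    Computes the area under each viewing's curve (rectangle rule at TR
    spacing), takes the mean AUC of repeated viewings (all of 2..n for
    ``first_vs_rest``, the last only for ``first_vs_last``) minus the
    first-viewing AUC, and rescales by tr / (K - 1) so the result is in
    seconds of temporal shift.
    """
    if len(curves) < 2:
        raise ValueError("need at least two viewings")
    k = curves[0].n_events
    if k < 2:
        raise ValueError("anticipation undefined for a single event (K=1)")
    if any(c.n_events != k or len(c.values) != len(curves[0].values) for c in curves):
        raise ValueError("curves must share K and T")
    aucs = np.array([float(np.sum(c.values)) for c in curves])
    if mode == "first_vs_rest":
        repeated = aucs[1:].mean()
    elif mode == "first_vs_last":
        repeated = aucs[-1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float((repeated - aucs[0]) / (k - 1) * curves[0].tr)


def _extract(
    bold: Sequence[Sequence[np.ndarray]], sl: Searchlight, subjects: np.ndarray
) -> list[np.ndarray]:
    """Per-subject voxel-by-(viewings * T) matrices for one searchlight."""
    ix, iy, iz = sl.voxel_ids[:, 0], sl.voxel_ids[:, 1], sl.voxel_ids[:, 2]
    out = []
    for s in subjects:
        mats = [np.asarray(v[ix, iy, iz, :], dtype=float) for v in bold[s]]
        out.append(np.concatenate(mats, axis=1))
    return out


def searchlight_anticipation(
    bold: Sequence[Sequence[np.ndarray]],
    searchlights: Sequence[Searchlight],
    tr: float = 1.5,
    n_events: int = 7,
    n_features: int = 10,
    mode: str = "first_vs_rest",
    srm_iter: int = 30,
    hmm_max_iter: int = 100,
    hmm_tol: float = 1e-4,
) -> np.ndarray:
    """Anticipation in seconds for each searchlight.

    ``bold`` is indexed [subject][viewing] and holds 4D (x, y, z, T) arrays
    with voxel timecourses already z-scored per viewing.  Each searchlight
    runs SRM alignment (joint over viewings), group averaging in shared
    space, the joint event-model fit, and the AUC-based anticipation
    measure.  Failures yield NaN and the run continues.
    """
    n_subjects = len(bold)
    n_viewings = len(bold[0])
    t_len = bold[0][0].shape[-1]
    values = np.full(len(searchlights), np.nan)
    for i, sl in enumerate(searchlights):
        subjects = (
            sl.valid_subjects if sl.valid_subjects is not None else np.arange(n_subjects)
        )
        try:
            data = _extract(bold, sl, subjects)
            bases, _ = fit_srm(data, n_features, max_iter=srm_iter)
            viewings = group_shared_response(
                bases, data, [t_len] * n_viewings, tr=tr
            )
            _, posts = fit_event_model(
                viewings, n_events, max_iter=hmm_max_iter, tol=hmm_tol
            )
            curves = [
                expected_event_curve(p, tr, v + 1) for v, p in enumerate(posts)
            ]
            values[i] = anticipation_seconds(curves, mode)
        except Exception as exc:  # noqa: BLE001 - one bad searchlight must not kill the run
            logger.warning(
                "searchlight %s failed (%s); recording NaN", sl.center, exc
            )
    return values


def aggregate_voxel_map(
    values: np.ndarray,
    searchlights: Sequence[Searchlight],
    volume_shape: tuple[int, int, int],
) -> AnticipationMap:
    """Mean searchlight value per voxel (NaN values excluded; NaN outside coverage)."""
    if len(searchlights) == 0:
        raise ValueError("no searchlights to aggregate")
    sums = np.zeros(volume_shape)
    counts = np.zeros(volume_shape, dtype=int)
    covering = np.zeros(volume_shape, dtype=int)
    for val, sl in zip(values, searchlights):
        ix, iy, iz = sl.voxel_ids[:, 0], sl.voxel_ids[:, 1], sl.voxel_ids[:, 2]
        covering[ix, iy, iz] += 1
        if np.isfinite(val):
            sums[ix, iy, iz] += val
            counts[ix, iy, iz] += 1
    out = np.full(volume_shape, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return AnticipationMap(out, covering)


def crosscorr_baseline(
    viewing_timecourses: Sequence[np.ndarray],
    tr: float = 1.5,
    max_lag_trs: int = 10,
) -> LagEstimate:
    """Fixed-lag cross-correlation alternative to the event-model measure.

    Correlates the first viewing's mean timecourse with the average
    repeated-viewing timecourse at integer lags, refining the peak with the
    quadratic rule.  Positive lag means the repeated-viewing response leads
    (occurs earlier than) the first viewing's.
    """
    if len(viewing_timecourses) < 2:
        raise ValueError("need at least two viewings")
    first = np.asarray(viewing_timecourses[0], dtype=float)
    repeated = np.mean([np.asarray(v, float) for v in viewing_timecourses[1:]], axis=0)
    # Shifting the repeated timecourse later by +lag aligns it with the first
    # viewing exactly when the repeated response leads, so the sign works out
    # through the same machinery as the annotation lag.
    return optimal_lag(
        BoundaryTimecourse(first, tr, "hmm"),
        BoundaryTimecourse(repeated, tr, "hmm"),
        max_lag_trs,
    )


def timescale_map(
    bold: Sequence[Sequence[np.ndarray]],
    searchlights: Sequence[Searchlight],
    tr: float = 1.5,
    k_range=range(2, 11),
    split_seed: int = 0,
    hmm_max_iter: int = 100,
    hmm_tol: float = 1e-4,
) -> np.ndarray:
    """Optimal event count per searchlight from viewing-1 data alone.

    Runs split-half model selection on each searchlight's voxel-space data
    (no hyperalignment, so the halves stay independent).  Returns the
    per-searchlight best K (NaN on failure).
    """
    n_subjects = len(bold)
    best = np.full(len(searchlights), np.nan)
    for i, sl in enumerate(searchlights):
        subjects = (
            sl.valid_subjects if sl.valid_subjects is not None else np.arange(n_subjects)
        )
        ix, iy, iz = sl.voxel_ids[:, 0], sl.voxel_ids[:, 1], sl.voxel_ids[:, 2]
        try:
            series = [
                ViewingSeries(np.asarray(bold[s][0][ix, iy, iz, :], float), tr)
                for s in subjects
            ]
            k, _ = select_n_events(
                series, k_range, split_seed, max_iter=hmm_max_iter, tol=hmm_tol
            )
            best[i] = k
        except Exception as exc:  # noqa: BLE001
            logger.warning("timescale searchlight %s failed (%s)", sl.center, exc)
    return best
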