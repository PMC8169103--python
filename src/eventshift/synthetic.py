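"""Synthetic multi-viewing fMRI-like data with known event structure.

Emulates the structure of a repeated-naturalistic-viewing experiment: each
viewing of a 90 s clip evokes a fixed sequence of K spatial event patterns;
on repeated viewings the pattern transitions occur earlier by a controlled
amount (the injected "anticipation").  Subject-specific orthogonal mixing
exercises functional alignment, and jittered multi-rater annotations
exercise the boundary-comparison path.  Everything is seeded and
deterministic so downstream estimates can be checked against ground truth.

Noise is i.i.d. white Gaussian; physiological noise structure (drift,
motion, temporal autocorrelation) is deliberately not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._utils import zscore_rows
from .boundaries import AnnotationSet, RaterAnnotation
from .hmm import ViewingSeries

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "SyntheticVolume",
    "make_event_labels",
    "shift_boundaries",
    "make_ground_truth",
    "generate_subject_viewings",
    "generate_volume_dataset",
    "generate_annotations",
]


@dataclass
class GroundTruth:
    """True generative parameters behind a synthetic dataset."""

    n_events: int
    boundaries_by_viewing: list  # per viewing, strictly increasing TR indices (K-1 each)
    shift_seconds: np.ndarray  # per viewing, intended anticipation vs viewing 1 (s)
    patterns: np.ndarray  # (K, V)
    noise_sd: float
    tr: float = 1.5
    n_timepoints: int = 60

    def __post_init__(self) -> None:
        self.shift_seconds = np.asarray(self.shift_seconds, dtype=float)
        if self.shift_seconds[0] != 0:
            raise ValueError("shift_seconds[0] must be 0 (first viewing is reference)")
        for b in self.boundaries_by_viewing:
            b = np.asarray(b)
            if len(b) != self.n_events - 1:
                raise ValueError("each viewing needs K-1 boundaries")
            if np.any(np.diff(b) <= 0):
                raise ValueError("boundaries must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_viewings(self) -> int:
        return len(self.boundaries_by_viewing)


@dataclass
class SyntheticVolume:
    """A volumetric multi-subject synthetic dataset."""

    bold: list  # [subject][viewing] -> 4D (x, y, z, T) array, z-scored per voxel
    mask: np.ndarray  # 3D bool
    truth: GroundTruth
    anticipation_field: np.ndarray  # 3D, intended shift in seconds per voxel
    tr: float = 1.5
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def make_event_labels(
    n_events: int, n_timepoints: int, boundaries: Sequence[int]
) -> np.ndarray:
    """Event label per timepoint given the K-1 event-onset boundaries."""
    boundaries = np.asarray(boundaries, dtype=int)
    if len(boundaries) != n_events - 1:
        raise ValueError(
            f"expected {n_events - 1} boundaries for {n_events} events, got {len(boundaries)}"
        )
    if len(boundaries) and (
        boundaries[0] <= 0
        or boundaries[-1] >= n_timepoints
        or np.any(np.diff(boundaries) <= 0)
    ):
        raise ValueError("boundaries must be strictly increasing within (0, T)")
    labels = np.zeros(n_timepoints, dtype=int)
    for b in boundaries:
        labels[b:] += 1
    return labels


def shift_boundaries(
    boundaries: Sequence[int], shift_seconds: float, tr: float
) -> np.ndarray:
    """Move boundaries earlier by round(shift_seconds / tr) TRs, clipped to >= 1."""
    boundaries = np.asarray(boundaries, dtype=int)
    shift_trs = int(round(shift_seconds / tr))
    shifted = boundaries - shift_trs
    if np.any(shifted < 1):
        logger.warning(
            "shift_boundaries: shift of %g s pushes a boundary before TR 1; clipping",
            shift_seconds,
        )
    shifted = np.maximum(shifted, 1)
    # preserve strict ordering after clipping
    for i in range(1, len(shifted)):
        shifted[i] = max(shifted[i], shifted[i - 1] + 1)
    return shifted


def make_ground_truth(
    n_events: int,
    n_timepoints: int,
    n_voxels: int,
    shift_seconds: Sequence[float],
    noise_sd: float,
    tr: float = 1.5,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth with evenly spaced viewing-1 boundaries and i.i.d. normal
    event patterns (z-scored across voxels), shifted per viewing."""
    rng = np.random.default_rng(seed)
    base = np.round(
        np.arange(1, n_events) * n_timepoints / n_events
    ).astype(int)
    boundaries = [shift_boundaries(base, s, tr) for s in shift_seconds]
    patterns = zscore_rows(rng.standard_normal((n_events, n_voxels)))
    return GroundTruth(
        n_events,
        boundaries,
        np.asarray(shift_seconds, float),
        patterns,
        noise_sd,
        tr,
        n_timepoints,
    )


def generate_subject_viewings(
    truth: GroundTruth,
    n_subjects: int,
    latent_dim: int | None = None,
    mixing: str = "none",
    seed: int = 0,
) -> list[list[ViewingSeries]]:
    """Per-subject, per-viewing feature-by-time series from the ground truth.

    With ``mixing='orthogonal'`` each subject observes the latent event
    timecourse through its own random orthonormal map (QR of a Gaussian
    matrix), the regime the shared response model assumes; with ``'none'``
    all subjects observe the latent patterns directly.  White Gaussian noise
    of SD ``truth.noise_sd`` is added and each feature is z-scored over time.
    """
    if truth.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_vox = truth.patterns.shape[1]
    if latent_dim is None:
        latent_dim = n_vox
    if latent_dim > n_vox:
        raise ValueError("latent_dim cannot exceed the pattern dimension")
    if mixing not in ("none", "orthogonal"):
        raise ValueError("mixing must be 'none' or 'orthogonal'")
    if mixing == "none" and latent_dim != n_vox:
        raise ValueError("mixing='none' requires latent_dim == pattern dimension")
    rng = np.random.default_rng(seed)
    subjects = []
    latent_patterns = truth.patterns[:, :latent_dim]  # (K, latent_dim)
    for _s in range(n_subjects):
        if mixing == "orthogonal":
            q, _ = np.linalg.qr(rng.standard_normal((n_vox, latent_dim)))
            w = q
        else:
            w = np.eye(n_vox)
        viewings = []
        for v, bnd in enumerate(truth.boundaries_by_viewing):
            labels = make_event_labels(truth.n_events, truth.n_timepoints, bnd)
            latent = latent_patterns[labels].T  # (latent_dim, T)
            data = w @ latent
            # scale the signal to unit RMS so noise_sd is a noise-to-signal
            # ratio independent of the voxel count
            rms = np.sqrt((data**2).mean())
            if rms > 0:
                data = data / rms
            if truth.noise_sd > 0:
                data = data + truth.noise_sd * rng.standard_normal(data.shape)
            viewings.append(
                ViewingSeries(zscore_rows(data), truth.tr, viewing_index=v + 1)
            )
        subjects.append(viewings)
    return subjects


def generate_volume_dataset(
    grid_shape: tuple[int, int, int],
    gradient_axis: str = "y",
    max_shift_seconds: float = 4.5,
    n_events: int = 7,
    n_timepoints: int = 60,
    n_viewings: int = 6,
    n_subjects: int = 5,
    noise_sd: float = 0.5,
    tr: float = 1.5,
    radius: int = 2,
    stride: int = 3,
    seed: int = 0,
) -> SyntheticVolume:
    """Volumetric dataset whose intended anticipation increases linearly along
    one axis, from 0 to ``max_shift_seconds``.

    Every voxel carries its own event-pattern timecourse; on viewings 2..n
    the voxel's boundaries are moved earlier by its anticipation-field value
    (quantized to whole TRs).  All subjects share the signal and receive
    independent white noise; voxel timecourses are z-scored per viewing.
    """
    axis = {"x": 0, "y": 1, "z": 2}[gradient_axis]
    grid_shape = tuple(int(g) for g in grid_shape)
    min_extent = 2 * radius + stride + 1
    if grid_shape[axis] < min_extent or min(grid_shape) < 2 * radius + 1:
        raise ValueError(
            f"grid {grid_shape} too small for radius={radius}, stride={stride}: "
            f"needs >= {2 * radius + 1} per axis and >= {min_extent} along the "
            f"gradient axis to hold two searchlights"
        )
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(grid_shape))
    base = np.round(np.arange(1, n_events) * n_timepoints / n_events).astype(int)
    patterns = zscore_rows(rng.standard_normal((n_events, n_vox)))

    coord = np.arange(grid_shape[axis], dtype=float)
    frac = coord / max(grid_shape[axis] - 1, 1)
    shape_ones = [1, 1, 1]
    shape_ones[axis] = grid_shape[axis]
    anticipation_field = np.zeros(grid_shape) + (max_shift_seconds * frac).reshape(
        shape_ones
    )

    shift_trs_field = np.round(anticipation_field / tr).astype(int)  # per voxel
    flat_shift = shift_trs_field.reshape(-1)
    unique_shifts = np.unique(flat_shift)
    labels_by_shift = {}
    for s_trs in unique_shifts:
        bnd = shift_boundaries(base, s_trs * tr, tr)
        labels_by_shift[int(s_trs)] = make_event_labels(n_events, n_timepoints, bnd)
    base_labels = make_event_labels(n_events, n_timepoints, base)

    # signal per viewing: (V, T); patterns[labels].T broadcasts a label vector
    # to every voxel, so shifted voxels are filled group-by-group
    signals = []
    for v in range(n_viewings):
        if v == 0:
            sig = patterns[base_labels].T
        else:
            sig = np.empty((n_vox, n_timepoints))
            for s_trs in unique_shifts:
                vox = flat_shift == s_trs
                sig[vox] = patterns[labels_by_shift[int(s_trs)]].T[vox]
        signals.append(sig)

    # per-viewing shifts are voxel-dependent here; the field records them,
    # and shift_seconds stays 0 (viewing-level summary undefined)
    truth = GroundTruth(
        n_events,
        [base for _ in range(n_viewings)],
        np.zeros(n_viewings),
        patterns,
        noise_sd,
        tr,
        n_timepoints,
    )

    bold = []
    for _s in range(n_subjects):
        viewings = []
        for v in range(n_viewings):
            data = signals[v]
            if noise_sd > 0:
                data = data + noise_sd * rng.standard_normal(data.shape)
            data = zscore_rows(data)
            viewings.append(
                np.ascontiguousarray(
                    data.reshape(grid_shape + (n_timepoints,)), dtype=np.float32
                )
            )
        bold.append(viewings)

    mask = np.ones(grid_shape, dtype=bool)
    return SyntheticVolume(bold, mask, truth, anticipation_field, tr)


def generate_annotations(
    true_boundary_seconds: Sequence[float],
    n_raters: int = 14,
    jitter_sd: float = 1.0,
    miss_prob: float = 0.1,
    seed: int = 0,
    clip_duration_s: float = 90.0,
) -> AnnotationSet:
    """Jittered multi-rater annotations of the true boundary times.

    Each rater keeps each true boundary independently with probability
    1 - miss_prob and reports it with Gaussian jitter of SD ``jitter_sd``
    seconds, clipped to the clip duration.
    """
    if not (0 <= miss_prob < 1):
        raise ValueError("miss_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    true_times = np.asarray(true_boundary_seconds, dtype=float)
    raters = []
    for r in range(n_raters):
        keep = rng.random(true_times.size) >= miss_prob
        times = true_times[keep]
        if jitter_sd > 0:
            times = times + jitter_sd * rng.standard_normal(times.size)
        times = np.clip(np.sort(times), 0.0, clip_duration_s)
        # drop collisions so per-rater times stay strictly increasing
        if len(times) > 1:
            keep_mask = np.concatenate([[True], np.diff(times) > 0])
            times = times[keep_mask]
        labels = [f"event {i + 1}" for i in range(len(times))]
        raters.append(RaterAnnotation(f"rater{r + 1:02d}", times, labels))
    return AnnotationSet(raters, clip_duration_s)
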