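"""Deterministic shared response model (functional hyperalignment).

Learns, for each subject i, an orthonormal basis W_i (voxels x features)
and a single shared timecourse S (features x time) minimizing
sum_i ||X_i - W_i S||_F^2 with W_i' W_i = I, by block-coordinate descent:
W_i via orthogonal Procrustes, S as the mean of the back-projections.
Fitting is joint over all viewings by concatenating them in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._utils import zscore_rows
from .hmm import ViewingSeries

__all__ = ["SubjectBasis", "SharedResponse", "fit_srm", "group_shared_response"]


@dataclass
class SubjectBasis:
    """Per-subject orthonormal map from voxel space to the shared space."""

    w: np.ndarray  # (V_s, F), orthonormal columns
    subject_id: int = 0


@dataclass
class SharedResponse:
    """Shared feature-by-time response, viewings concatenated in time."""

    s: np.ndarray  # (F, T_total)
    objective_history: list = field(default_factory=list)


def _procrustes(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Orthonormal W minimizing ||X - W S||^2: polar factor of X S'."""
    u, _, vt = np.linalg.svd(x @ s.T, full_matrices=False)
    return u @ vt


def _objective(
    data: Sequence[np.ndarray], bases: Sequence[np.ndarray], s: np.ndarray
) -> float:
    return float(sum(((x - w @ s) ** 2).sum() for x, w in zip(data, bases)))


def fit_srm(
    subject_data: Sequence[np.ndarray],
    n_features: int,
    max_iter: int = 30,
    seed: int | None = None,
) -> tuple[list[SubjectBasis], SharedResponse]:
    """Fit the deterministic SRM by alternating minimization.

    ``subject_data`` holds one (V_s, T_total) matrix per subject (viewings
    concatenated in time; voxel counts may differ across subjects).  The
    shared timecourse is initialized from the first subject's top
    ``n_features`` principal component timecourses, making the fit fully
    deterministic; ``seed`` is accepted for interface symmetry but unused.
    """
    if not subject_data:
        raise ValueError("need at least one subject")
    data = [np.asarray(x, dtype=float) for x in subject_data]
    t_total = data[0].shape[1]
    if any(x.shape[1] != t_total for x in data):
        raise ValueError("all subjects must share the number of timepoints")
    for i, x in enumerate(data):
        if n_features > x.shape[0]:
            raise ValueError(
                f"n_features={n_features} exceeds subject {i}'s voxel count {x.shape[0]}"
            )

    u, _, _ = np.linalg.svd(data[0], full_matrices=False)
    s = u[:, :n_features].T @ data[0]

    history: list[float] = []
    bases = [np.zeros((x.shape[0], n_features)) for x in data]
    for _ in range(max_iter):
        bases = [_procrustes(x, s) for x in data]
        s = np.mean([w.T @ x for w, x in zip(bases, data)], axis=0)
        history.append(_objective(data, bases, s))

    out = [SubjectBasis(w, i) for i, w in enumerate(bases)]
    return out, SharedResponse(s, history)


def group_shared_response(
    bases: Sequence[SubjectBasis],
    subject_data: Sequence[np.ndarray],
    viewing_lengths: Sequence[int],
    tr: float = 1.5,
) -> list[ViewingSeries]:
    """Average subjects in shared space and split into per-viewing series.

    Returns one feature-by-time :class:`ViewingSeries` per viewing, each
    feature z-scored over time (the form the event model consumes).
    """
    data = [np.asarray(x, dtype=float) for x in subject_data]
    t_total = data[0].shape[1]
    if sum(viewing_lengths) != t_total:
        raise ValueError(
            f"viewing_lengths sum to {sum(viewing_lengths)}, expected {t_total}"
        )
    s_mean = np.mean([b.w.T @ x for b, x in zip(bases, data)], axis=0)
    out = []
    start = 0
    for v, t_len in enumerate(viewing_lengths):
        chunk = s_mean[:, start : start + t_len]
        out.append(ViewingSeries(zscore_rows(chunk), tr, viewing_index=v + 1))
        start += t_len
    return out
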