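"""Comparison of model-derived event boundaries with human annotations.

Human raters mark boundary times (in seconds) while watching the clip.  The
per-second count of annotations is convolved with a canonical double-gamma
hemodynamic response function to predict a continuous BOLD-domain boundary
timecourse.  The model-side analogue is the temporal derivative of the
expected-event curve ("boundary strength").  Cross-correlating the two at
integer-TR lags and refining the peak with a quadratic fit yields a
continuous optimal lag per viewing; shifts of that lag between the first
and repeated viewings quantify how the brain's boundaries move relative to
subjective ones.

Sign convention (locked by tests): positive lag means the annotation
timecourse is shifted later in time relative to the brain timecourse.
Hence a brain timecourse that leads the annotations yields a negative
optimal lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from ._utils import pearson
from .hmm import ExpectedEventCurve

logger = logging.getLogger(__name__)

__all__ = [
    "RaterAnnotation",
    "AnnotationSet",
    "BoundaryTimecourse",
    "LagEstimate",
    "hrf",
    "annotation_timecourse",
    "boundary_strength",
    "optimal_lag",
    "quadratic_vertex",
    "lag_shift",
    "bootstrap_rater_ci",
]


@dataclass
class RaterAnnotation:
    rater_id: str
    times_s: np.ndarray  # strictly increasing, within [0, clip_duration]
    labels: list = field(default_factory=list)


@dataclass
class AnnotationSet:
    """Boundary annotations from a panel of raters for one clip."""

    raters: list  # of RaterAnnotation
    clip_duration_s: float

    def __post_init__(self) -> None:
        for r in self.raters:
            r.times_s = np.asarray(r.times_s, dtype=float)
            if np.any(r.times_s < 0) or np.any(r.times_s > self.clip_duration_s):
                raise ValueError(f"rater {r.rater_id}: times outside clip")
            if np.any(np.diff(r.times_s) <= 0):
                raise ValueError(f"rater {r.rater_id}: times not strictly increasing")


@dataclass
class BoundaryTimecourse:
    values: np.ndarray
    tr: float
    kind: str = "annotation"  # "annotation" | "hmm"


@dataclass
class LagEstimate:
    lag_s: float
    peak_corr: float
    viewing_index: int = 1
    at_boundary: bool = False  # peak at the edge of the lag range (unrefined)


@lru_cache(maxsize=8)
def _hrf_peak(peak_s: float, undershoot_s: float, undershoot_ratio: float) -> float:
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, 40.0, 0.01)
    y = gamma_dist.pdf(t, peak_s + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_s + 1.0
    )
    return float(y.max())


def hrf(
    t,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    The positive lobe is a gamma density with mode at ``peak_s`` seconds
    (unit scale), the undershoot a gamma density with mode at
    ``undershoot_s`` scaled by ``undershoot_ratio``.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    y = gamma_dist.pdf(t, peak_s + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_s + 1.0
    )
    return y / _hrf_peak(peak_s, undershoot_s, undershoot_ratio)


def annotation_timecourse(
    ann: AnnotationSet,
    tr: float = 1.5,
    n_timepoints: int | None = None,
    hrf_kwargs: dict | None = None,
) -> BoundaryTimecourse:
    """HRF-convolved boundary-count timecourse on the TR grid.

    Boundary counts are pooled across raters into 1 s bins, convolved with
    the HRF sampled at 1 s, then linearly interpolated onto the TR grid.
    """
    n_sec = int(np.ceil(ann.clip_duration_s))
    if n_timepoints is None:
        n_timepoints = int(round(ann.clip_duration_s / tr))
    counts = np.zeros(n_sec)
    total = 0
    for r in ann.raters:
        for t_s in r.times_s:
            counts[min(int(t_s), n_sec - 1)] += 1
            total += 1
    if total == 0:
        logger.warning("annotation_timecourse: no annotations; returning zeros")
        return BoundaryTimecourse(np.zeros(n_timepoints), tr, "annotation")
    kernel = hrf(np.arange(0.0, 33.0, 1.0), **(hrf_kwargs or {}))
    conv = np.convolve(counts, kernel)[:n_sec]
    tr_grid = np.arange(n_timepoints) * tr
    values = np.interp(tr_grid, np.arange(n_sec, dtype=float), conv)
    return BoundaryTimecourse(values, tr, "annotation")


def boundary_strength(curve: ExpectedEventCurve) -> BoundaryTimecourse:
    """Forward-difference derivative of the expected-event curve (length T-1)."""
    values = np.asarray(curve.values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two timepoints")
    return BoundaryTimecourse(np.diff(values), curve.tr, "hmm")


def _lagged_corrs(
    x: np.ndarray, y: np.ndarray, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of x[t] with y[t - lag] over the overlap, per lag.

    Positive lag shifts ``y`` later in time.  Lags whose overlap has fewer
    than 3 samples are NaN.
    """
    n = len(x)
    lags = np.arange(-max_lag, max_lag + 1)
    corrs = np.full(lags.size, np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[lag:], y[: n - lag]
        else:
            xs, ys = x[: n + lag], y[-lag:]
        if len(xs) < 3:
            continue
        corrs[i] = pearson(xs, ys)
    return lags, corrs


def quadratic_vertex(c_minus: float, c_0: float, c_plus: float) -> float:
    """Sub-sample peak offset from three equally spaced correlations.

    Fits the parabola through (-1, c_minus), (0, c_0), (+1, c_plus) and
    returns its vertex position in units of the lag spacing, e.g.
    (0.2, 0.9, 0.6) -> +0.2.
    """
    denom = c_minus - 2.0 * c_0 + c_plus
    if denom == 0:
        return 0.0
    return 0.5 * (c_minus - c_plus) / denom


def optimal_lag(
    brain_tc: BoundaryTimecourse,
    annot_tc: BoundaryTimecourse,
    max_lag_trs: int = 10,
    viewing_index: int = 1,
) -> LagEstimate:
    """Continuous lag maximizing the brain/annotation cross-correlation.

    Correlations are computed at integer-TR lags over the overlapping
    segment only; among local maxima the one nearest lag 0 is chosen (ties
    break toward smaller |lag|, then negative), and the continuous peak is
    the vertex of the parabola through the maximum and its two neighbors.
    A peak at the edge of the lag range is returned unrefined with
    ``at_boundary=True``.
    """
    x = np.asarray(brain_tc.values, dtype=float)
    y = np.asarray(annot_tc.values, dtype=float)
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    tr = brain_tc.tr
    lags, corrs = _lagged_corrs(x, y, max_lag_trs)
    if not np.any(np.isfinite(corrs)):
        raise ValueError("cross-correlation undefined (constant timecourse?)")

    maxima = []
    for i in range(lags.size):
        c = corrs[i]
        if not np.isfinite(c):
            continue
        left = corrs[i - 1] if i > 0 else -np.inf
        right = corrs[i + 1] if i < lags.size - 1 else -np.inf
        if c >= left and c >= right:
            maxima.append(i)
    if not maxima:
        raise ValueError("no local maximum in the cross-correlation")
    # nearest to lag 0; ties -> smaller |lag|, then negative
    best = min(maxima, key=lambda i: (abs(lags[i]), lags[i]))

    if best == 0 or best == lags.size - 1 or not (
        np.isfinite(corrs[best - 1]) and np.isfinite(corrs[best + 1])
    ):
        return LagEstimate(float(lags[best] * tr), float(corrs[best]), viewing_index, True)

    offset = quadratic_vertex(corrs[best - 1], corrs[best], corrs[best + 1])
    return LagEstimate(
        float((lags[best] + offset) * tr), float(corrs[best]), viewing_index, False
    )


def lag_shift(first_viewing: LagEstimate, repeated: Sequence[LagEstimate]) -> float:
    """First-viewing optimal lag minus the mean repeated-viewing optimal lag (s)."""
    if not repeated:
        raise ValueError("need at least one repeated viewing")
    lags = [r.lag_s for r in repeated]
    if np.isnan(first_viewing.lag_s) or np.any(np.isnan(lags)):
        logger.warning("lag_shift: NaN input lag")
        return float("nan")
    return float(first_viewing.lag_s - np.mean(lags))


def bootstrap_rater_ci(
    ann: AnnotationSet,
    brain_tcs: Sequence[BoundaryTimecourse],
    max_lag_trs: int = 10,
    n_boot: int = 100,
    seed: int = 0,
    n_timepoints: int | None = None,
) -> dict:
    """95% bootstrap CIs over raters for first- and repeated-viewing lags.

    Raters are resampled with replacement ``n_boot`` times; each replicate
    rebuilds the annotation timecourse and recomputes optimal lags for every
    viewing's brain timecourse.  Returns percentile (2.5, 97.5) intervals
    for the first-viewing lag and for the mean lag over repeated viewings.
    """
    if len(ann.raters) < 2:
        raise ValueError("need at least two raters to bootstrap")
    rng = np.random.default_rng(seed)
    tr = brain_tcs[0].tr
    firsts, repeats = [], []
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, len(ann.raters), size=len(ann.raters))
            raters = [ann.raters[i] for i in idx]
            if sum(len(r.times_s) for r in raters) > 0:
                break
            logger.warning("bootstrap_rater_ci: empty replicate redrawn")
        else:
            raise RuntimeError("could not draw a non-empty bootstrap replicate")
        boot = AnnotationSet(
            [RaterAnnotation(f"b{j}", r.times_s, r.labels) for j, r in enumerate(raters)],
            ann.clip_duration_s,
        )
        tc = annotation_timecourse(boot, tr, n_timepoints)
        lags = [
            optimal_lag(btc, tc, max_lag_trs, viewing_index=v + 1).lag_s
            for v, btc in enumerate(brain_tcs)
        ]
        firsts.append(lags[0])
        repeats.append(float(np.mean(lags[1:])) if len(lags) > 1 else np.nan)
    return {
        "first_viewing_ci": tuple(np.percentile(firsts, [2.5, 97.5])),
        "repeated_viewing_ci": tuple(np.percentile(repeats, [2.5, 97.5])),
        "first_viewing_lags": np.asarray(firsts),
        "repeated_viewing_lags": np.asarray(repeats),
    }
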