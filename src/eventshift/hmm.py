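"""Ordered-event hidden Markov model for neural event segmentation.

The latent state is a narrative event index that starts at 0, can only stay
or advance by one per timestep, and must reach the final event by the last
timepoint.  Each event is represented by a single spatial activity pattern
(z-scored across features); observations are compared to the patterns under
an isotropic Gaussian emission with a single shared variance.  Fitting the
model jointly to several viewings of the same stimulus yields per-viewing
posteriors over events under one shared sequence of event patterns, which is
what makes between-viewing timing shifts measurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._utils import zscore_cols, zscore_rows

logger = logging.getLogger(__name__)

__all__ = [
    "ViewingSeries",
    "EventModel",
    "EventPosterior",
    "ExpectedEventCurve",
    "emission_loglik",
    "forward_backward",
    "fit_event_model",
    "expected_event_curve",
    "select_n_events",
]


@dataclass
class ViewingSeries:
    """One viewing's feature-by-time response matrix.

    ``data`` has shape (F, T) with each feature (row) z-scored over time.
    ``tr`` is the sampling interval in seconds; ``viewing_index`` is 1-based.
    """

    data: np.ndarray
    tr: float
    viewing_index: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ViewingSeries.data must be 2D (features x time)")

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class EventModel:
    """K ordered event patterns plus a shared isotropic noise variance."""

    n_events: int
    event_patterns: np.ndarray  # (K, F), each pattern z-scored across features
    noise_variance: float
    advance_prob: float

    def __post_init__(self) -> None:
        self.event_patterns = np.asarray(self.event_patterns, dtype=float)
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.event_patterns.shape[0] != self.n_events:
            raise ValueError("event_patterns must have n_events rows")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")
        if self.n_events > 1 and not (0 < self.advance_prob < 1):
            raise ValueError("advance_prob must lie in (0, 1)")


@dataclass
class EventPosterior:
    """Timepoint-by-event posterior probabilities for one viewing."""

    gamma: np.ndarray  # (T, K), rows sum to 1
    log_likelihood: float


@dataclass
class ExpectedEventCurve:
    """Expected (0-based) event index at each timepoint."""

    values: np.ndarray  # (T,), in [0, K-1]
    tr: float
    n_events: int
    viewing_index: int = 1


def emission_loglik(series: ViewingSeries, model: EventModel) -> np.ndarray:
    """Per-timepoint, per-event Gaussian log-likelihoods.

    Each observation vector is z-scored across features and compared to each
    event pattern under N(m_k, sigma^2 I); returns a (T, K) matrix.
    """
    if model.noise_variance <= 0:
        raise ValueError("noise_variance must be positive")
    x = series.data
    if x.shape[0] != model.event_patterns.shape[1]:
        raise ValueError(
            f"feature mismatch: series has {x.shape[0]} features, "
            f"model patterns have {model.event_patterns.shape[1]}"
        )
    z = zscore_cols(x)  # (F, T)
    m = model.event_patterns  # (K, F)
    f = x.shape[0]
    # ||z_t - m_k||^2 expanded; both are z-scored so norms are ~F, but compute exactly.
    sq = (
        (z**2).sum(axis=0)[:, None]
        + (m**2).sum(axis=1)[None, :]
        - 2.0 * (z.T @ m.T)
    )
    s2 = model.noise_variance
    return -0.5 * sq / s2 - 0.5 * f * np.log(2.0 * np.pi * s2)


def _transition_logs(n_events: int, advance_prob: float) -> tuple[np.ndarray, float]:
    """Log stay-probability (shared by every state) and log advance-probability.

    With a uniform stay probability every admissible path through K events in
    T steps carries the same transition weight, so the posterior over
    segmentations is purely emission-driven and time-reversal symmetric; the
    end-state conditioning in the backward pass supplies the normalization.
    """
    log_stay = np.full(n_events, np.log1p(-advance_prob))
    return log_stay, float(np.log(advance_prob))


def forward_backward(series: ViewingSeries, model: EventModel) -> EventPosterior:
    """Exact posterior over events under the monotone left-to-right chain.

    The chain starts in event 0, may only stay or advance by one per step,
    and is conditioned on occupying event K-1 at the final timepoint, so all
    K events are traversed.  Computed in log space.
    """
    e = emission_loglik(series, model)  # (T, K)
    t_len, k = e.shape
    if k == 1:
        return EventPosterior(np.ones((t_len, 1)), float(e.sum()))
    if t_len < k:
        raise ValueError(f"T={t_len} < K={k}: no admissible event path")

    log_stay, log_adv = _transition_logs(k, model.advance_prob)

    alpha = np.full((t_len, k), -np.inf)
    alpha[0, 0] = e[0, 0]
    for t in range(1, t_len):
        stay = alpha[t - 1] + log_stay
        adv = np.full(k, -np.inf)
        adv[1:] = alpha[t - 1, :-1] + log_adv
        alpha[t] = e[t] + np.logaddexp(stay, adv)

    beta = np.full((t_len, k), -np.inf)
    beta[-1, -1] = 0.0
    for t in range(t_len - 2, -1, -1):
        stay = log_stay + e[t + 1] + beta[t + 1]
        adv = np.full(k, -np.inf)
        adv[:-1] = log_adv + e[t + 1, 1:] + beta[t + 1, 1:]
        beta[t] = np.logaddexp(stay, adv)

    log_lik = float(alpha[-1, -1])
    with np.errstate(under="ignore"):
        gamma = np.exp(alpha + beta - log_lik)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return EventPosterior(gamma, log_lik)


def _init_patterns(
    z_data: Sequence[np.ndarray], n_events: int
) -> tuple[np.ndarray, float]:
    """Deterministic init: event patterns from a uniform segmentation of time."""
    f = z_data[0].shape[0]
    sums = np.zeros((n_events, f))
    counts = np.zeros(n_events)
    for z in z_data:
        t_len = z.shape[1]
        labels = (np.arange(t_len) * n_events) // t_len
        for kk in range(n_events):
            cols = z[:, labels == kk]
            sums[kk] += cols.sum(axis=1)
            counts[kk] += cols.shape[1]
    patterns = zscore_rows(sums / counts[:, None])
    resid = 0.0
    n_obs = 0
    for z in z_data:
        t_len = z.shape[1]
        labels = (np.arange(t_len) * n_events) // t_len
        resid += ((z - patterns[labels].T) ** 2).sum()
        n_obs += t_len
    sigma2 = max(resid / (n_obs * f), 1e-12)
    return patterns, sigma2


def _m_step(
    z_data: Sequence[np.ndarray], gammas: Sequence[np.ndarray]
) -> tuple[np.ndarray, float]:
    f = z_data[0].shape[0]
    k = gammas[0].shape[1]
    num = np.zeros((k, f))
    den = np.zeros(k)
    for z, g in zip(z_data, gammas):
        num += g.T @ z.T
        den += g.sum(axis=0)
    patterns = zscore_rows(num / np.maximum(den, 1e-300)[:, None])
    resid = 0.0
    n_obs = 0
    for z, g in zip(z_data, gammas):
        # sum_{t,k} gamma[t,k] ||z_t - m_k||^2
        sq = (
            (z**2).sum(axis=0)[:, None]
            + (patterns**2).sum(axis=1)[None, :]
            - 2.0 * (z.T @ patterns.T)
        )
        resid += float((g * sq).sum())
        n_obs += z.shape[1]
    sigma2 = max(resid / (n_obs * f), 1e-12)
    return patterns, sigma2


def fit_event_model(
    viewings: Sequence[ViewingSeries],
    n_events: int,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int | None = None,
    loglik_history: list | None = None,
) -> tuple[EventModel, list[EventPosterior]]:
    """Fit the shared event model jointly to all viewings by EM.

    The E-step runs the constrained forward--backward pass per viewing; the
    M-step re-estimates the shared event patterns as the posterior-weighted
    average of the (observation-z-scored) data pooled across viewings,
    re-z-scored across features, and the shared noise variance as the pooled
    weighted residual variance.  Initialization is deterministic (uniform
    segmentation), so ``seed`` is accepted for interface symmetry but unused.
    """
    if not viewings:
        raise ValueError("need at least one viewing")
    f = viewings[0].n_features
    if any(v.n_features != f for v in viewings):
        raise ValueError("all viewings must share the feature dimension")
    min_t = min(v.n_timepoints for v in viewings)
    if n_events > min_t:
        raise ValueError(f"n_events={n_events} exceeds shortest viewing T={min_t}")

    z_data = [zscore_cols(v.data) for v in viewings]
    mean_t = float(np.mean([v.n_timepoints for v in viewings]))
    advance = min(max(n_events / mean_t, 1e-6), 1 - 1e-6)
    patterns, sigma2 = _init_patterns(z_data, n_events)

    prev_ll = -np.inf
    model = EventModel(n_events, patterns, sigma2, advance)
    posts: list[EventPosterior] = []
    converged = False
    for _ in range(max_iter):
        model = EventModel(n_events, patterns, sigma2, advance)
        posts = [forward_backward(v, model) for v in viewings]
        total_ll = sum(p.log_likelihood for p in posts)
        if loglik_history is not None:
            loglik_history.append(total_ll)
        if total_ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = total_ll
        patterns, sigma2 = _m_step(z_data, [p.gamma for p in posts])
    if not converged:
        logger.warning(
            "fit_event_model: EM did not converge in %d iterations (K=%d); "
            "returning best-so-far fit",
            max_iter,
            n_events,
        )
        model = EventModel(n_events, patterns, sigma2, advance)
        posts = [forward_backward(v, model) for v in viewings]
    return model, posts


def expected_event_curve(
    post: EventPosterior, tr: float = 1.5, viewing_index: int = 1
) -> ExpectedEventCurve:
    """Expectation of the (0-based) event index at each timepoint."""
    gamma = np.asarray(post.gamma, dtype=float)
    row_sums = gamma.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    k = gamma.shape[1]
    values = gamma @ np.arange(k, dtype=float)
    return ExpectedEventCurve(values, tr, k, viewing_index)


def select_n_events(
    subject_series: Sequence[ViewingSeries],
    k_range: Iterable[int] = range(2, 11),
    split_seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[int, dict[int, float]]:
    """Split-half model selection for the number of events.

    Subjects are split into two halves; for each K the model is trained on
    the mean response of one half and its log-likelihood evaluated on the
    mean of the other half, in both directions, and the two log-likelihoods
    averaged.  Returns the argmax K (ties resolved toward smaller K) along
    with the full K -> log-likelihood curve.
    """
    n_sub = len(subject_series)
    if n_sub < 2:
        raise ValueError("need at least two subjects for split-half selection")
    tr = subject_series[0].tr
    perm = np.random.default_rng(split_seed).permutation(n_sub)
    half_a = perm[: n_sub // 2]
    half_b = perm[n_sub // 2 :]

    def mean_series(idx: np.ndarray) -> ViewingSeries:
        stack = np.mean([subject_series[i].data for i in idx], axis=0)
        return ViewingSeries(zscore_rows(stack), tr)

    series_a = mean_series(half_a)
    series_b = mean_series(half_b)
    t_len = series_a.n_timepoints

    logliks: dict[int, float] = {}
    for k in k_range:
        if k > t_len:
            logger.warning("select_n_events: skipping K=%d > T=%d", k, t_len)
            continue
        ll = 0.0
        for train, test in ((series_a, series_b), (series_b, series_a)):
            model, _ = fit_event_model([train], k, max_iter=max_iter, tol=tol)
            ll += forward_backward(test, model).log_likelihood
        logliks[k] = ll / 2.0
    if not logliks:
        raise ValueError("no admissible K in k_range")
    best_k = max(sorted(logliks), key=lambda k: (logliks[k], -k))
    return best_k, logliks
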