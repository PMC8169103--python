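import itertools

import numpy as np
import pytest

from eventshift.hmm import EventModel, ViewingSeries, emission_loglik


def brute_force_posterior(series: ViewingSeries, model: EventModel):
    """Independent oracle: enumerate every monotone segmentation of T
    timepoints into K ordered events and weight it by its likelihood
    (emissions plus per-step stay/advance probabilities)."""
    e = emission_loglik(series, model)
    t_len, k = e.shape
    p = model.advance_prob
    log_weights, paths = [], []
    for bnd in itertools.combinations(range(1, t_len), k - 1):
        labels = np.zeros(t_len, dtype=int)
        for b in bnd:
            labels[b:] += 1
        w = e[np.arange(t_len), labels].sum()
        for t in range(t_len - 1):
            w += np.log(p) if labels[t + 1] > labels[t] else np.log1p(-p)
        log_weights.append(w)
        paths.append(labels)
    log_weights = np.array(log_weights)
    shift = log_weights.max()
    weights = np.exp(log_weights - shift)
    gamma = np.zeros((t_len, k))
    for w, labels in zip(weights, paths):
        gamma[np.arange(t_len), labels] += w
    gamma /= weights.sum()
    log_lik = shift + np.log(weights.sum())
    return gamma, float(log_lik)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
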