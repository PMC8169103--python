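"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def zscore_rows(x: np.ndarray) -> np.ndarray:
    """Z-score each row of a 2D array (population SD). Constant rows map to zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = x - mu
    np.divide(out, sd, out=out, where=sd > 0)
    return out


def zscore_cols(x: np.ndarray) -> np.ndarray:
    """Z-score each column of a 2D array (population SD). Constant columns map to zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    out = x - mu
    np.divide(out, sd, out=out, where=sd > 0)
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = x.std()
    ys = y.std()
    if xs == 0 or ys == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (xs * ys))
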