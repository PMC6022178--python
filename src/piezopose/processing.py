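"""Offline signal preprocessing and time-domain feature extraction.

The recorded count trace is denoised with a centered moving-average filter,
cut into consecutive non-overlapping 100-sample (2 s) windows, and each
window is summarized by four time-domain features: mean, standard deviation,
maximum and minimum.  Feature vectors are min-max normalized before
classification; the default convention rescales the four elements of each
vector by that vector's own min and max, with a dataset-wide per-feature
alternative available.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProcessingError",
    "moving_average",
    "window_features",
    "normalize_vector",
    "normalize_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ("mean", "std", "max", "min")


class ProcessingError(ValueError):
    """Invalid filter configuration or input sequence."""


def moving_average(x: Sequence[float], n: int = 5) -> np.ndarray:
    """Centered moving average over ``n = 2k + 1`` successive samples.

    Each output sample is the mean of the input over the window
    ``[i - k, i + k]``.  At the boundaries the window truncates to the
    available samples and the divisor shrinks accordingly, so the output has
    the same length as the input.  ``n`` must be odd.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ProcessingError("input must be a non-empty 1-D sequence")
    if n < 1 or n % 2 == 0:
        raise ProcessingError(f"window length must be odd and >= 1, got {n}")
    k = n // 2
    s = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(len(x))
    lo = np.maximum(idx - k, 0)
    hi = np.minimum(idx + k, len(x) - 1)
    return (s[hi + 1] - s[lo]) / (hi - lo + 1)


def _majority_label(labels: np.ndarray) -> object:
    """Most frequent label; ties go to the label appearing earliest."""
    uniq, first, counts = np.unique(labels, return_index=True, return_counts=True)
    best = np.lexsort((first, -counts))[0]
    return uniq[best]


def window_features(values: Sequence[float], labels: Sequence,
                    window: int = 100) -> pd.DataFrame:
    """Summarize consecutive non-overlapping windows by four features.

    Returns a DataFrame with columns ``mean, std, max, min, label,
    window_index``; ``std`` is the population standard deviation.  An
    incomplete tail window is dropped; a trace shorter than one window yields
    an empty frame with a warning.  Window labels are the majority per-sample
    label, ties broken toward the earlier posture.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if window < 2:
        raise ProcessingError("window must be >= 2 samples")
    if len(values) != len(labels):
        raise ProcessingError("values and labels must have equal length")
    n_win = len(values) // window
    if n_win == 0:
        warnings.warn(
            f"trace of {len(values)} samples is shorter than one {window}-sample "
            "window; no features produced", stacklevel=2)
        return pd.DataFrame(columns=[*FEATURE_COLUMNS, "label", "window_index"])
    v = values[: n_win * window].reshape(n_win, window)
    lab = labels[: n_win * window].reshape(n_win, window)
    return pd.DataFrame({
        "mean": v.mean(axis=1),
        "std": v.std(axis=1),       # population (divisor n)
        "max": v.max(axis=1),
        "min": v.min(axis=1),
        "label": [_majority_label(row) for row in lab],
        "window_index": np.arange(n_win),
    })


def normalize_vector(fv: Sequence[float]) -> np.ndarray:
    """Min-max rescale the four elements of one feature vector to [0, 1].

    f'_k = (f_k - f_min) / (f_max - f_min) where f_min and f_max are the
    smallest and largest of the vector's own four elements, so every
    non-degenerate output contains an exact 0 and an exact 1.  A degenerate
    all-equal vector maps to all zeros with a warning.
    """
    f = np.asarray(fv, dtype=float)
    f_min, f_max = f.min(), f.max()
    if f_max == f_min:
        warnings.warn("degenerate feature vector (all elements equal); "
                      "normalized to zeros", stacklevel=2)
        return np.zeros_like(f)
    return (f - f_min) / (f_max - f_min)


def normalize_features(features: pd.DataFrame,
                       mode: str = "per_vector") -> pd.DataFrame:
    """Normalize a feature table, adding ``*_norm`` columns.

    ``mode="per_vector"`` rescales each row by its own element range (the
    default convention; ADC gain and offset cancel row-wise).
    ``mode="dataset"`` rescales each feature column by its min and max over
    the whole table, preserving between-feature structure instead.
    """
    cols = list(FEATURE_COLUMNS)
    X = features[cols].to_numpy(dtype=float)
    if mode == "per_vector":
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
    elif mode == "dataset":
        lo = X.min(axis=0, keepdims=True)
        hi = X.max(axis=0, keepdims=True)
    else:
        raise ProcessingError(f"unknown normalization mode {mode!r}")
    span = hi - lo
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn("degenerate min-max span; affected values set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = np.where(span == 0, 0.0, (X - lo) / np.where(span == 0, 1.0, span))
    out = features.copy()
    for j, c in enumerate(cols):
        out[f"{c}_norm"] = Xn[:, j]
    return out
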