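"""Small numeric helpers used throughout the pipeline."""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def fit_length(signal: np.ndarray, length: int) -> np.ndarray:
    """Return ``signal`` center-cropped or mean-padded to exactly ``length``.

    Longer signals keep their central portion; shorter ones are padded on
    both sides with the signal mean (the same mu-padding convention the
    shift augmentation uses), so a fixed-length encoder can consume
    recordings of any duration.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValidationError("fit_length expects a 1-D signal")
    if length < 1:
        raise ValidationError("target length must be >= 1")
    n = signal.shape[0]
    if n == length:
        return signal.copy()
    if n > length:
        start = (n - length) // 2
        return signal[start : start + length].copy()
    mu = float(signal.mean()) if n else 0.0
    left = (length - n) // 2
    right = length - n - left
    return np.concatenate(
        [np.full(left, mu), signal, np.full(right, mu)]
    )


def standardize(signal: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Z-score a 1-D segment (zero mean, unit variance; constant -> zeros)."""
    signal = np.asarray(signal, dtype=float)
    mu = signal.mean()
    sd = signal.std()
    if sd < eps:
        return np.zeros_like(signal)
    return (signal - mu) / sd


def cosine_similarity_raw(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two raw (not unit-norm) vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))
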