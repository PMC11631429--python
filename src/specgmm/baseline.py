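"""Distance-matrix comparison method: median-length normalization + PCC distances.

The comparison pipeline normalizes every signal to the median training length
(truncation for longer, anti-symmetric padding for shorter), takes a single
whole-sequence magnitude spectrum, and represents each sequence by its vector
of Pearson-correlation distances d = (1 - r) / 2 to every training sequence.
Feature dimension therefore equals the number of training sequences, which is
the scaling limitation the supervector approach removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_signal import GenomicSignal, magnitude_spectrum, next_power_of_two

__all__ = [
    "DistanceFeatureSet",
    "normalize_length",
    "lower_median_length",
    "pcc_distance",
    "whole_sequence_spectrum",
    "baseline_features",
]


@dataclass
class DistanceFeatureSet:
    """Pairwise-distance features: rows are sequences, columns training refs."""

    train_matrix: np.ndarray  # (n_train, n_train), symmetric, zero diagonal
    test_matrix: np.ndarray   # (n_test, n_train)
    reference_ids: list[str]


def lower_median_length(lengths) -> int:
    """Median sequence length; even counts resolve to the lower middle value."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))
    if arr.size == 0:
        raise ValueError("no lengths given")
    return int(arr[(arr.size - 1) // 2])


def normalize_length(signal: GenomicSignal, target_len: int) -> GenomicSignal:
    """Force a signal to exactly ``target_len`` samples.

    Longer signals keep their first ``target_len`` samples.  Shorter signals
    are extended anti-symmetrically: the negated, time-reversed signal is
    appended (values -x[L-1], -x[L-2], ...), repeating the reflection of the
    growing signal as often as needed.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    x = signal.values
    if x.shape[0] == 0:
        raise ValueError(f"signal {signal.id!r} is empty")
    if x.shape[0] >= target_len:
        return GenomicSignal(id=signal.id, values=x[:target_len].copy())
    y = x.copy()
    while y.shape[0] < target_len:
        y = np.concatenate([y, -y[::-1]])
    return GenomicSignal(id=signal.id, values=y[:target_len])


def pcc_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson-correlation distance d = (1 - r) / 2, bounded in [0, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1 or u.shape[0] < 2:
        raise ValueError("u and v must be 1-D of equal length >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    su = np.sqrt(du @ du)
    sv = np.sqrt(dv @ dv)
    if su == 0.0 or sv == 0.0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(du @ dv / (su * sv))
    r = min(1.0, max(-1.0, r))
    return (1.0 - r) / 2.0


def whole_sequence_spectrum(
    signal: GenomicSignal, target_len: int, fft_order: int | None = None
) -> np.ndarray:
    """Length-normalize a signal and return its single magnitude spectrum.

    The FFT order defaults to the next power of two >= target_len.
    """
    if fft_order is None:
        fft_order = next_power_of_two(target_len)
    norm = normalize_length(signal, target_len)
    return magnitude_spectrum(norm.values, fft_order)


def _pairwise_pcc_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Distance matrix (1 - r)/2 between rows of A and rows of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("correlation undefined for a zero-variance vector")
    r = (A @ B.T) / np.outer(na, nb)
    np.clip(r, -1.0, 1.0, out=r)
    return (1.0 - r) / 2.0


def baseline_features(
    train_spectra: np.ndarray,
    test_spectra: np.ndarray,
    reference_ids: list[str] | None = None,
) -> DistanceFeatureSet:
    """Distance-matrix features relative to the training sequences.

    Each sequence is represented by its distances to every training spectrum;
    the feature dimension equals n_train for both splits.
    """
    train_spectra = np.asarray(train_spectra, dtype=np.float64)
    test_spectra = np.asarray(test_spectra, dtype=np.float64)
    if train_spectra.ndim != 2:
        raise ValueError("train_spectra must be 2-D (n_train, D)")
    if test_spectra.size and test_spectra.shape[1] != train_spectra.shape[1]:
        raise ValueError("train and test spectra must share dimensionality")
    train_matrix = _pairwise_pcc_distance(train_spectra, train_spectra)
    np.fill_diagonal(train_matrix, 0.0)
    if test_spectra.size:
        test_matrix = _pairwise_pcc_distance(test_spectra, train_spectra)
    else:
        test_matrix = np.zeros((0, train_spectra.shape[0]))
    if reference_ids is None:
        reference_ids = [str(i) for i in range(train_spectra.shape[0])]
    return DistanceFeatureSet(
        train_matrix=train_matrix,
        test_matrix=test_matrix,
        reference_ids=list(reference_ids),
    )
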